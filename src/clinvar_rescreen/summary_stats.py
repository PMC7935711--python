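"""Summary tables and predictor statistics over filter decisions.

Given the excluded set and post-review labels (which excluded variants a
clinical panel judged plausibly diagnostic), these operations reproduce the
reason-by-reason exclusion table and test candidate predictors of a variant
being diagnostic - reference-population allele frequency, catalog gold-star
review status, parent of origin - with a two-sided Fisher's exact test
(chi-square with continuity correction reported alongside). Percentages use
half-up rounding to match conventional printed tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .clinical_filter import FilterDecision, Status
from .cohort_match import Inheritance


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class ReviewLabel:
    """Post-review outcome for one excluded observation."""

    proband: str
    key: str  # chrom:pos:ref:alt
    reported_after_review: bool


def labels_index(labels: Iterable[ReviewLabel]) -> dict[tuple[str, str], bool]:
    return {(l.proband, l.key): l.reported_after_review for l in labels}


@dataclass(frozen=True)
class TwoByTwo:
    """Contingency table: rows = stratum (in/out), cols = reported (yes/no)."""

    a: int  # stratum yes
    b: int  # stratum no
    c: int  # other yes
    d: int  # other no

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def rows(self) -> tuple[int, int]:
        return self.a + self.b, self.c + self.d

    @property
    def cols(self) -> tuple[int, int]:
        return self.a + self.c, self.b + self.d

    def percentages(self) -> tuple[int, int]:
        """Percent reported within each stratum, half-up rounded."""
        r1, r2 = self.rows
        p1 = round_half_up(100 * self.a / r1) if r1 else 0
        p2 = round_half_up(100 * self.c / r2) if r2 else 0
        return p1, p2


def fisher_exact_two_sided(t: TwoByTwo) -> float:
    """Two-sided Fisher's exact p for a 2x2 table.

    Sums hypergeometric probabilities of all tables with the observed margins
    whose probability does not exceed the observed table's (with a relative
    tolerance guarding floating-point ties). Zero margins make the test
    undefined and raise.
    """
    r1, r2 = t.rows
    c1, c2 = t.cols
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("Fisher's exact test undefined for a zero margin")
    n = r1 + r2
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[t.a - lo]
    p = pmf[pmf <= p_obs * (1 + 1e-7)].sum()
    return min(1.0, float(p))


def chi_square_p(t: TwoByTwo) -> float:
    """Chi-square p with Yates continuity correction, for transparency."""
    _, p, _, _ = sps.chi2_contingency([[t.a, t.b], [t.c, t.d]], correction=True)
    return float(p)


def _label_for(
    decision: FilterDecision, labels: Mapping[tuple[str, str], bool]
) -> Optional[bool]:
    return labels.get((decision.observation.proband.id, str(decision.observation.key)))


def tabulate_reasons(
    decisions: Iterable[FilterDecision],
    labels: Mapping[tuple[str, str], bool],
) -> pd.DataFrame:
    """Reason-by-reason exclusion table with post-review reported percentages.

    One row per primary exclusion reason (n excluded, n reported after
    review, percent) plus a total row. Labels may only reference excluded
    decisions; a label on a standard-reported decision is an error.
    """
    decisions = list(decisions)
    for d in decisions:
        if d.status is Status.REPORTED_STANDARD and _label_for(d, labels) is not None:
            raise ValueError(
                f"review label present for standard-reported decision "
                f"{d.observation.key} in {d.observation.proband.id}"
            )
    rows = []
    total_n = total_rep = 0
    by_reason: dict[str, list[FilterDecision]] = {}
    for d in decisions:
        if d.status is Status.EXCLUDED:
            by_reason.setdefault(d.primary_reason.value, []).append(d)
    for reason in sorted(by_reason):
        group = by_reason[reason]
        n = len(group)
        n_rep = sum(1 for d in group if _label_for(d, labels))
        rows.append(
            {
                "reason": reason,
                "n_excluded": n,
                "n_reported_after_review": n_rep,
                "pct_reported": round_half_up(100 * n_rep / n) if n else 0,
            }
        )
        total_n += n
        total_rep += n_rep
    rows.append(
        {
            "reason": "TOTAL",
            "n_excluded": total_n,
            "n_reported_after_review": total_rep,
            "pct_reported": round_half_up(100 * total_rep / total_n) if total_n else 0,
        }
    )
    return pd.DataFrame(rows, columns=["reason", "n_excluded", "n_reported_after_review",
                                       "pct_reported"])


@dataclass
class StratifiedResult:
    table: TwoByTwo
    pct_in_stratum: int
    pct_out_stratum: int
    n_unstratified: int

    @property
    def fisher_p(self) -> float:
        return fisher_exact_two_sided(self.table)


Stratifier = Callable[[FilterDecision], Optional[bool]]


def maf_below(threshold: float = 0.000005, missing_is_low: bool = True) -> Stratifier:
    """Stratify on reference-population MAF below threshold.

    A variant absent from the reference population has no recorded frequency;
    by default that counts as below threshold (absence is the strongest form
    of rarity). Observations without any annotation are unstratifiable.
    """

    def strat(decision: FilterDecision) -> Optional[bool]:
        ann = decision.observation.annotation
        if ann is None:
            return None if not missing_is_low else True
        return ann.population_maf < threshold

    return strat


def stars_at_least(minimum: int = 2) -> Stratifier:
    def strat(decision: FilterDecision) -> Optional[bool]:
        stars = decision.observation.stars
        return None if stars is None else stars >= minimum

    return strat


def inherited_from_father() -> Stratifier:
    """Paternal (True) vs maternal (False); other inheritance unstratifiable."""

    def strat(decision: FilterDecision) -> Optional[bool]:
        inh = decision.observation.inheritance
        if inh is Inheritance.PATERNAL:
            return True
        if inh is Inheritance.MATERNAL:
            return False
        return None

    return strat


def proportion_reported(
    decisions: Iterable[FilterDecision],
    labels: Mapping[tuple[str, str], bool],
    stratifier: Stratifier,
) -> StratifiedResult:
    """2x2 of stratum membership x reported-after-review over excluded decisions.

    Unstratifiable decisions (stratifier returns None) are counted and
    surfaced rather than forced into a stratum.
    """
    a = b = c = d = unstratified = 0
    for decision in decisions:
        if decision.status is not Status.EXCLUDED:
            continue
        in_stratum = stratifier(decision)
        if in_stratum is None:
            unstratified += 1
            continue
        reported = bool(_label_for(decision, labels))
        if in_stratum:
            a, b = a + (1 if reported else 0), b + (0 if reported else 1)
        else:
            c, d = c + (1 if reported else 0), d + (0 if reported else 1)
    table = TwoByTwo(a, b, c, d)
    p1, p2 = table.percentages()
    return StratifiedResult(table, p1, p2, unstratified)


def from_counts(reported_in: int, n_in: int, reported_out: int, n_out: int) -> TwoByTwo:
    """Build the 2x2 from per-stratum (reported, total) counts."""
    if reported_in > n_in or reported_out > n_out:
        raise ValueError("reported count exceeds stratum size")
    return TwoByTwo(reported_in, n_in - reported_in, reported_out, n_out - reported_out)
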
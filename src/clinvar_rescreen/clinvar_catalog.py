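"""Catalog eligibility: restrict raw ClinVar-style assertions to the usable set.

The re-screening pipeline only considers catalog variants that are germline,
on GRCh37, classified pathogenic or likely pathogenic without conflicting
interpretations, carry at least one gold star of review support, and fall in
a panel gene with a robust disease association. Everything else is rejected
with a named reason so that input counts are conserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .io_formats import AllelicRequirement, VariantKey

# ClinVar's public review-status -> gold-star mapping. Unrecognized strings
# raise rather than silently scoring 0.
_STAR_MAP = {
    "practice guideline": 4,
    "reviewed by expert panel": 3,
    "criteria provided, multiple submitters, no conflicts": 2,
    "criteria provided, single submitter": 1,
    "criteria provided, conflicting interpretations": 1,
    "no assertion criteria provided": 0,
    "no assertion provided": 0,
}

# Accepted pathogenic significance vocabulary (case-insensitive, exact).
# Free-text qualifiers such as ", low penetrance" disqualify.
_PLP_SIGNIFICANCES = {
    "pathogenic",
    "likely pathogenic",
    "pathogenic/likely pathogenic",
}

DEFAULT_PANEL_CONFIDENCE = frozenset({"confirmed", "probable"})


def stars_from_review_status(review_status: str) -> int:
    """Map a ClinVar review-status string to its gold-star count (0-4)."""
    key = review_status.strip().lower()
    if key not in _STAR_MAP:
        raise ValueError(
            f"unrecognized review status {review_status!r}; known: {sorted(_STAR_MAP)}"
        )
    return _STAR_MAP[key]


@dataclass(frozen=True)
class CatalogRecord:
    """One ClinVar-style assertion for a variant."""

    key: VariantKey
    significance: str
    review_status: str
    origin: str
    assembly: str
    gene: str
    variation_id: str

    @property
    def stars(self) -> int:
        return stars_from_review_status(self.review_status)


@dataclass(frozen=True)
class PanelEntry:
    """One gene-disease pair from the curated developmental-disorder panel."""

    gene: str
    requirement: AllelicRequirement
    mutation_consequence: str
    imprinted: bool
    mosaic: bool
    confidence: str


def _has_conflict(record: CatalogRecord) -> bool:
    return (
        "conflicting" in record.significance.lower()
        or "conflicting" in record.review_status.lower()
    )


def is_eligible(
    record: CatalogRecord,
    panel: Mapping[str, PanelEntry],
    confidence: Iterable[str] = DEFAULT_PANEL_CONFIDENCE,
) -> tuple[bool, Optional[str]]:
    """Decide catalog eligibility; on rejection return the first failing criterion.

    Criteria, in order: germline origin, GRCh37 assembly, no conflicting
    interpretations, P/LP significance, >= 1 gold star, panel gene with
    robust (confirmed/probable by default) confidence.
    """
    if "germline" not in record.origin.lower():
        return False, "origin"
    if record.assembly != "GRCh37":
        return False, "assembly"
    if _has_conflict(record):
        return False, "conflict"
    if record.significance.strip().lower() not in _PLP_SIGNIFICANCES:
        return False, "significance"
    if record.stars < 1:
        return False, "stars"
    entry = panel.get(record.gene)
    if entry is None:
        return False, "panel_gene"
    if entry.confidence not in set(confidence):
        return False, "panel_confidence"
    return True, None


@dataclass
class EligibleCatalog:
    """Deduplicated eligible records plus the gene panel they were matched to."""

    records: dict[VariantKey, CatalogRecord]
    panel_index: dict[str, PanelEntry]
    tally: dict[str, int] = field(default_factory=dict)
    n_raw: int = 0
    n_eligible_raw: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, key: VariantKey) -> bool:
        return key in self.records


def build_catalog(
    records: Iterable[CatalogRecord],
    panel: Iterable[PanelEntry],
    confidence: Iterable[str] = DEFAULT_PANEL_CONFIDENCE,
) -> EligibleCatalog:
    """Filter raw records to the eligible set, deduplicating by variant key.

    Duplicate submissions of one key keep the max-stars record. Every
    surviving duplicate is P/LP by construction; a post-filter duplicate
    whose significance fell outside that vocabulary would indicate catalog
    inconsistency and raises.
    """
    panel_index = {e.gene: e for e in panel}
    tally: dict[str, int] = {}
    kept: dict[VariantKey, CatalogRecord] = {}
    n_raw = 0
    n_eligible_raw = 0
    for record in records:
        n_raw += 1
        ok, reason = is_eligible(record, panel_index, confidence)
        if not ok:
            tally[reason] = tally.get(reason, 0) + 1
            continue
        n_eligible_raw += 1
        prev = kept.get(record.key)
        if prev is None:
            kept[record.key] = record
            continue
        if prev.significance.strip().lower() not in _PLP_SIGNIFICANCES or (
            record.significance.strip().lower() not in _PLP_SIGNIFICANCES
        ):  # pragma: no cover - unreachable for the accepted vocabulary
            raise ValueError(f"contradictory significance for duplicate key {record.key}")
        if record.stars > prev.stars:
            kept[record.key] = record
    tally["eligible"] = n_eligible_raw
    return EligibleCatalog(
        records=kept,
        panel_index=panel_index,
        tally=tally,
        n_raw=n_raw,
        n_eligible_raw=n_eligible_raw,
    )
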
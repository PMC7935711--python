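"""Pipeline thresholds with their published defaults.

Every threshold the prefilter and the clinical filter use lives here so a run
can be reproduced from a single YAML snapshot. Defaults are the values the
original automated filter applied; the `revised` profile switches off the two
rules (imprinted-gene and X-linked-overdominance exclusions) that were later
relaxed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class Config:
    # cohort prefilter
    internal_maf_mono: float = 0.0005   # monoallelic and X-linked genes
    internal_maf_biallelic: float = 0.005
    min_gq: int = 30
    recurrent_indel_families: int = 8   # drop indels in > this many unrelated probands
    # inheritance calling (confident parental hom-ref for de novo status)
    parent_min_gq: int = 30
    parent_min_dp: int = 7
    # clinical-filter rules
    pop_maf_unknown_inheritance: float = 0.0001
    pop_allele_count_max: int = 5
    mosaic_parent_vaf: float = 0.4
    mosaic_child_vaf: float = 0.4
    denovo_min_depth: int = 10
    denovo_ab: tuple[float, float] = (0.3, 0.7)
    denovo_ab_hom: float = 0.85
    denovo_parent_alt_max: int = 1
    # summary statistics
    stratifier_maf: float = 0.000005
    # catalog
    panel_confidence: tuple[str, ...] = ("confirmed", "probable")
    # rules disabled by profile (exclusion-reason code names)
    disabled_rules: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name in ("internal_maf_mono", "internal_maf_biallelic",
                     "pop_maf_unknown_inheritance", "mosaic_parent_vaf",
                     "mosaic_child_vaf", "stratifier_maf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("min_gq", "recurrent_indel_families", "parent_min_gq",
                     "parent_min_dp", "pop_allele_count_max", "denovo_min_depth",
                     "denovo_parent_alt_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.denovo_ab
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValueError("denovo_ab must be an ordered pair in [0, 1]")

    def rule_enabled(self, code: str) -> bool:
        return code not in self.disabled_rules

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["denovo_ab"] = list(self.denovo_ab)
        d["panel_confidence"] = list(self.panel_confidence)
        d["disabled_rules"] = list(self.disabled_rules)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, data: dict) -> "Config":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data = dict(data)
        for key in ("denovo_ab", "panel_confidence", "disabled_rules"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)


# Exclusion rules switched off by the revised-profile filter.
REVISED_PROFILE_DISABLED = ("IMPRINTED_NOT_INHERITED", "XL_OVERDOMINANCE_INHERITED")


def profile_config(profile: str = "default", **overrides) -> Config:
    if profile == "default":
        return Config(**overrides)
    if profile == "revised":
        overrides.setdefault("disabled_rules", REVISED_PROFILE_DISABLED)
        return Config(**overrides)
    raise ValueError(f"unknown profile {profile!r}; expected 'default' or 'revised'")
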
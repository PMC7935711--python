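"""Fully synthetic cohort generator with planted ground truth.

The real inputs of a catalog re-screen - a live ClinVar release, a curated
gene panel, and consented patient genotypes - cannot ship with a package, so
this module fabricates all five input files (cohort VCF, PED, catalog TSV,
panel CSV, annotation TSV) together with a truth table. Every exclusion and
drop class the pipeline can assign is planted as the minimal genotype /
annotation / panel configuration that triggers exactly that class, one gene
per plant so truth labels are unambiguous. Read depths follow a negative
binomial model and allele depths are binomial around the true allele
fraction; with ``sequencing_noise=False`` depths and allele counts are set
deterministically so plant recovery is exact.

Internal-MAF thresholds do not transfer across cohort scales: one het
carrier among N probands has cohort frequency 1/(2N), which already exceeds
the published 0.0005 threshold for any N < 1000. The generator therefore
writes a run config alongside the cohort whose internal-MAF thresholds are
scaled to the simulated cohort size (at the original study's scale the
formula reproduces the published defaults exactly); see docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .config import Config
from .io_formats import Sex, VariantKey

EXCLUSION_CLASSES = [
    "DENOVO_LOW_QUALITY",
    "INHERITED_UNAFFECTED_PARENT",
    "POP_ALLELE_COUNT_GT5",
    "MAF_INHERITANCE_UNKNOWN",
    "MALE_X_HET",
    "FEMALE_HET_HEMIZYGOUS_GENE",
    "XL_OVERDOMINANCE_INHERITED",
    "UNIPARENTAL_HOMOZYGOUS",
    "MISSENSE_PREDICTED_BENIGN",
    "NONCODING_CONSEQUENCE",
    "IMPRINTED_NOT_INHERITED",
    "MOSAIC_MECHANISM_NOT_DENOVO",
    "COMPOUND_HET_PARTNER_FAILED",
]
DROP_CLASSES = ["LOW_GQ", "INTERNAL_MAF", "RECURRENT_INDEL", "SINGLETON_DOUBLE_HET"]
REPORTED_CLASS = "REPORTED_STANDARD"
BACKGROUND_CLASS = "BENIGN_BACKGROUND"
ALL_CLASSES = EXCLUSION_CLASSES + DROP_CLASSES + [REPORTED_CLASS, BACKGROUND_CLASS]

# classes that require inheritance to be unknowable (singleton probands)
_SINGLETON_CLASSES = frozenset(
    {
        "MAF_INHERITANCE_UNKNOWN",
        "MISSENSE_PREDICTED_BENIGN",
        "MOSAIC_MECHANISM_NOT_DENOVO",
        "SINGLETON_DOUBLE_HET",
    }
)

EXPECTED_STATUS = {
    **{c: "EXCLUDED" for c in EXCLUSION_CLASSES},
    **{c: "DROPPED" for c in DROP_CLASSES},
    REPORTED_CLASS: "REPORTED_STANDARD",
    BACKGROUND_CLASS: "NOT_MATCHED",
}


def default_class_counts() -> dict[str, int]:
    counts = {c: 3 for c in EXCLUSION_CLASSES}
    counts.update({c: 1 for c in DROP_CLASSES})
    counts[REPORTED_CLASS] = 10
    counts[BACKGROUND_CLASS] = 25
    return counts


@dataclass
class DepthModel:
    """Negative-binomial read-depth model (variance = mean + mean^2/overdispersion)."""

    mean: float = 40.0
    overdispersion: float = 10.0


@dataclass
class SimulationConfig:
    n_trios: int = 200
    n_singletons: int = 50
    class_counts: dict[str, int] = field(default_factory=default_class_counts)
    seed: int = 0
    depth_model: DepthModel = field(default_factory=DepthModel)
    mosaic_fraction: float = 0.1  # inherited plants given a mosaic (VAF<0.4) parent
    sequencing_noise: bool = True
    recurrent_indel_families: int = 9  # carriers of the recurrent indel plant

    def __post_init__(self) -> None:
        if self.n_trios < 0 or self.n_singletons < 0:
            raise ValueError("cohort sizes must be >= 0")
        unknown = set(self.class_counts) - set(ALL_CLASSES)
        if unknown:
            raise ValueError(f"unknown planted classes: {sorted(unknown)}")
        if any(v < 0 for v in self.class_counts.values()):
            raise ValueError("class counts must be >= 0")
        if not 0.0 <= self.mosaic_fraction <= 1.0:
            raise ValueError("mosaic_fraction must be in [0, 1]")


def scaled_run_config(config: SimulationConfig) -> Config:
    """Run config whose internal-MAF thresholds fit the simulated cohort size."""
    n_probands = config.n_trios + config.n_singletons
    if n_probands == 0:
        return Config()
    mono = min(0.5, max(0.0005, (config.recurrent_indel_families + 2) / (2 * n_probands)))
    return Config(
        internal_maf_mono=mono,
        internal_maf_biallelic=min(0.5, 10 * mono),
    )


@dataclass(frozen=True)
class TruthRecord:
    key: VariantKey
    proband: str
    planted_class: str
    expected_status: str


@dataclass
class GTSpec:
    """Genotype assignment for one sample at one site."""

    alleles: tuple[int, ...]  # e.g. (0,1) het, (1,1) hom, (1,) hemi
    gq: int = 99
    dp: Optional[int] = None  # force a depth (bypasses the depth model)
    vaf: Optional[float] = None  # true allele fraction (default 0.5 het / 1.0 hom)


@dataclass
class PlantedVariant:
    key: VariantKey
    gene: str
    panel_requirement: Optional[str]  # None = gene absent from panel
    mechanism: str
    consequence: str
    predictor: str
    population_maf: float
    allele_count: int
    significance: str
    review_status: str
    genotypes: dict[str, GTSpec]
    truth: list[TruthRecord]
    origin: str = "germline"
    assembly: str = "GRCh37"
    panel_confidence: str = "confirmed"
    catalog_duplicate: bool = False  # also emit a second, lower-star submission


@dataclass
class SimulatedCohort:
    vcf: Path
    ped: Path
    clinvar: Path
    panel: Path
    annotations: Path
    truth_table: Path
    run_config: Path
    truth: list[TruthRecord]


# ---------------------------------------------------------------------------


@dataclass
class _Member:
    id: str
    family: str
    sex: Sex
    role: str
    affected: bool
    similar: bool = False


class _FamilyPool:
    def __init__(self, families: list[dict]) -> None:
        self._free = list(families)

    def take(self, kind: str, proband_sex: Optional[Sex] = None) -> dict:
        for i, fam in enumerate(self._free):
            if fam["kind"] != kind:
                continue
            if proband_sex is not None and fam["proband"].sex is not proband_sex:
                continue
            return self._free.pop(i)
        raise ValueError(
            f"not enough unused {kind} families"
            + (f" with a {proband_sex.value} proband" if proband_sex else "")
            + "; increase n_trios/n_singletons or reduce class_counts"
        )


_CHROMS = [str(c) for c in range(1, 23)] + ["X"]
_SNV_ROTATION = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]


class _Plotter:
    """Allocates unique genes and genomic positions to plants."""

    def __init__(self) -> None:
        self._i = 0

    def next_site(self, chrom: Optional[str] = None, indel: bool = False):
        i = self._i
        self._i += 1
        if chrom is None:
            chrom = str(1 + i % 22)
        pos = 1_000_000 + 1_000 * i
        if indel:
            ref, alt = "GAT", "G"
        else:
            ref, alt = _SNV_ROTATION[i % 4]
        return VariantKey(chrom, pos, ref, alt), i


def _stop_gained(maf: float = 0.0, ac: int = 0) -> dict:
    return {
        "consequence": "stop_gained",
        "predictor": "not_applicable",
        "population_maf": maf,
        "allele_count": ac,
    }


def _missense(predictor: str, maf: float = 0.0, ac: int = 0) -> dict:
    return {
        "consequence": "missense_variant",
        "predictor": predictor,
        "population_maf": maf,
        "allele_count": ac,
    }


def plant_compound_het(
    proband_id: str,
    mother_id: Optional[str],
    father_id: Optional[str],
    phase: str,
) -> tuple[dict[str, GTSpec], dict[str, GTSpec]]:
    """Genotype assignments for a two-variant compound het in one family.

    ``trans`` puts one variant on each parental haplotype (requires a trio),
    ``cis`` puts both on the same parent's haplotype, and for a singleton
    (no parent ids) the child simply carries both hets with phase undefined.
    """
    if phase not in ("trans", "cis"):
        raise ValueError(f"phase must be 'trans' or 'cis', got {phase!r}")
    het = (0, 1)
    ref = (0, 0)
    first = {proband_id: GTSpec(het)}
    second = {proband_id: GTSpec(het)}
    if mother_id is None and father_id is None:
        return first, second
    if mother_id is None or father_id is None:
        raise ValueError("compound-het planting needs a full trio or a singleton")
    if phase == "trans":
        first.update({mother_id: GTSpec(het), father_id: GTSpec(ref)})
        second.update({mother_id: GTSpec(ref), father_id: GTSpec(het)})
    else:
        first.update({mother_id: GTSpec(het), father_id: GTSpec(ref)})
        second.update({mother_id: GTSpec(het), father_id: GTSpec(ref)})
    return first, second


def _build_families(config: SimulationConfig) -> tuple[list[_Member], list[dict]]:
    members: list[_Member] = []
    families: list[dict] = []
    for i in range(config.n_trios):
        fid = f"F{i + 1:04d}"
        sex = Sex.MALE if i % 2 == 0 else Sex.FEMALE
        proband = _Member(f"{fid}_p", fid, sex, "proband", True)
        mother = _Member(f"{fid}_m", fid, Sex.FEMALE, "mother", False)
        father = _Member(f"{fid}_f", fid, Sex.MALE, "father", False)
        members.extend([proband, mother, father])
        families.append(
            {"id": fid, "kind": "trio", "proband": proband, "mother": mother, "father": father}
        )
    for i in range(config.n_singletons):
        fid = f"S{i + 1:04d}"
        sex = Sex.MALE if i % 2 == 0 else Sex.FEMALE
        proband = _Member(f"{fid}_p", fid, sex, "proband", True)
        members.append(proband)
        families.append(
            {"id": fid, "kind": "singleton", "proband": proband, "mother": None, "father": None}
        )
    return members, families


def _maybe_mosaic(rng: np.random.Generator, config: SimulationConfig) -> Optional[float]:
    if rng.random() < config.mosaic_fraction:
        return float(rng.uniform(0.05, 0.35))
    return None


def _build_plants(
    config: SimulationConfig, families: list[dict], rng: np.random.Generator
) -> list[PlantedVariant]:
    pool = _FamilyPool(families)
    plotter = _Plotter()
    plants: list[PlantedVariant] = []
    run_cfg = scaled_run_config(config)
    n_probands = config.n_trios + config.n_singletons

    def catalog_style(i: int) -> dict:
        sig = "Pathogenic" if i % 2 == 0 else "Likely pathogenic"
        stars = (
            "criteria provided, single submitter"
            if i % 3
            else "criteria provided, multiple submitters, no conflicts"
        )
        return {"significance": sig, "review_status": stars, "catalog_duplicate": i % 5 == 0}

    def add(planted_class: str, fam: dict, key: VariantKey, idx: int, **kw) -> PlantedVariant:
        truth = [
            TruthRecord(key, fam["proband"].id, planted_class, EXPECTED_STATUS[planted_class])
        ]
        plant = PlantedVariant(
            key=key,
            gene=kw.pop("gene"),
            panel_requirement=kw.pop("panel_requirement"),
            mechanism=kw.pop("mechanism", ""),
            genotypes=kw.pop("genotypes"),
            truth=truth,
            **catalog_style(idx),
            **kw,
        )
        plants.append(plant)
        return plant

    het, hom, ref = (0, 1), (1, 1), (0, 0)
    counts = {c: config.class_counts.get(c, 0) for c in ALL_CLASSES}

    for c in _SINGLETON_CLASSES:
        if counts[c] > 0 and config.n_singletons == 0:
            raise ValueError(f"class {c} needs singleton probands but n_singletons is 0")
    trio_only = set(EXCLUSION_CLASSES) - _SINGLETON_CLASSES | {"LOW_GQ"}
    for c in trio_only:
        if counts[c] > 0 and config.n_trios == 0:
            raise ValueError(f"class {c} needs trio probands but n_trios is 0")

    for n, planted_class in ((counts[c], c) for c in EXCLUSION_CLASSES):
        for j in range(n):
            gene = f"G{plotter._i + 1:04d}"
            if planted_class == "DENOVO_LOW_QUALITY":
                fam = pool.take("trio")
                key, idx = plotter.next_site()
                gts = {
                    fam["proband"].id: GTSpec(het, dp=6),
                    fam["mother"].id: GTSpec(ref),
                    fam["father"].id: GTSpec(ref),
                }
                add(planted_class, fam, key, idx, gene=gene,
                    panel_requirement="monoallelic", genotypes=gts, **_stop_gained())
            elif planted_class == "INHERITED_UNAFFECTED_PARENT":
                fam = pool.take("trio")
                key, idx = plotter.next_site()
                parent = fam["mother"] if j % 2 == 0 else fam["father"]
                other = fam["father"] if j % 2 == 0 else fam["mother"]
                gts = {
                    fam["proband"].id: GTSpec(het),
                    parent.id: GTSpec(het, vaf=_maybe_mosaic(rng, config)),
                    other.id: GTSpec(ref),
                }
                add(planted_class, fam, key, idx, gene=gene,
                    panel_requirement="monoallelic", genotypes=gts,
                    **_missense("probably_damaging"))
            elif planted_class == "POP_ALLELE_COUNT_GT5":
                fam = pool.take("trio")
                key, idx = plotter.next_site()
                gts = {
                    fam["proband"].id: GTSpec(het),
                    fam["mother"].id: GTSpec(ref),
                    fam["father"].id: GTSpec(ref),
                }
                add(planted_class, fam, key, idx, gene=gene,
                    panel_requirement="monoallelic", genotypes=gts,
                    **_stop_gained(ac=6 + j))
            elif planted_class == "MAF_INHERITANCE_UNKNOWN":
                fam = pool.take("singleton")
                key, idx = plotter.next_site()
                gts = {fam["proband"].id: GTSpec(het)}
                add(planted_class, fam, key, idx, gene=gene,
                    panel_requirement="monoallelic", genotypes=gts,
                    **_stop_gained(maf=0.0002))
            elif planted_class == "MALE_X_HET":
                fam = pool.take("trio", Sex.MALE)
                key, idx = plotter.next_site(chrom="X")
                gts = {
                    fam["proband"].id: GTSpec(het),  # anomalous diploid het on male X
                    fam["mother"].id: GTSpec(het),
                    fam["father"].id: GTSpec((0,)),
                }
                add(planted_class, fam, key, idx, gene=gene,
                    panel_requirement="hemizygous", genotypes=gts, **_stop_gained())
            elif planted_class == "FEMALE_HET_HEMIZYGOUS_GENE":
                fam = pool.take("trio", Sex.FEMALE)
                key, idx = plotter.next_site(chrom="X")
                gts = {
                    fam["proband"].id: GTSpec(het),
                    fam["mother"].id: GTSpec(het),
                    fam["father"].id: GTSpec((0,)),
                }
                add(planted_class, fam, key, idx, gene=gene,
                    panel_requirement="hemizygous", genotypes=gts, **_stop_gained())
            elif planted_class == "XL_OVERDOMINANCE_INHERITED":
                fam = pool.take("trio", Sex.FEMALE)
                key, idx = plotter.next_site(chrom="X")
                gts = {
                    fam["proband"].id: GTSpec(het),
                    fam["mother"].id: GTSpec(ref),
                    fam["father"].id: GTSpec((1,)),
                }
                add(planted_class, fam, key, idx, gene=gene,
                    panel_requirement="x-linked over-dominance", genotypes=gts,
                    **_stop_gained())
            elif planted_class == "UNIPARENTAL_HOMOZYGOUS":
                fam = pool.take("trio")
                key, idx = plotter.next_site()
                carrier = fam["mother"] if j % 2 == 0 else fam["father"]
                other = fam["father"] if j % 2 == 0 else fam["mother"]
                gts = {
                    fam["proband"].id: GTSpec(hom),
                    carrier.id: GTSpec(het),
                    other.id: GTSpec(ref),
                }
                add(planted_class, fam, key, idx, gene=gene,
                    panel_requirement="biallelic", genotypes=gts, **_stop_gained())
            elif planted_class == "MISSENSE_PREDICTED_BENIGN":
                fam = pool.take("singleton")
                key, idx = plotter.next_site()
                gts = {fam["proband"].id: GTSpec(het)}
                add(planted_class, fam, key, idx, gene=gene,
                    panel_requirement="monoallelic", genotypes=gts,
                    **_missense("benign", maf=0.00005))
            elif planted_class == "NONCODING_CONSEQUENCE":
                fam = pool.take("trio")
                key, idx = plotter.next_site()
                gts = {
                    fam["proband"].id: GTSpec(het),
                    fam["mother"].id: GTSpec(ref),
                    fam["father"].id: GTSpec(ref),
                }
                noncoding = ["synonymous_variant", "intron_variant", "splice_region_variant",
                             "5_prime_UTR_variant", "3_prime_UTR_variant"][j % 5]
                add(planted_class, fam, key, idx, gene=gene,
                    panel_requirement="monoallelic", genotypes=gts,
                    consequence=noncoding, predictor="not_applicable",
                    population_maf=0.0, allele_count=0)
            elif planted_class == "IMPRINTED_NOT_INHERITED":
                fam = pool.take("trio")
                key, idx = plotter.next_site()
                gts = {
                    fam["proband"].id: GTSpec(het),
                    fam["mother"].id: GTSpec(ref),
                    fam["father"].id: GTSpec(ref),
                }
                add(planted_class, fam, key, idx, gene=gene,
                    panel_requirement="monoallelic", mechanism="imprinted",
                    genotypes=gts, **_stop_gained())
            elif planted_class == "MOSAIC_MECHANISM_NOT_DENOVO":
                fam = pool.take("singleton")
                key, idx = plotter.next_site()
                gts = {fam["proband"].id: GTSpec(het)}
                add(planted_class, fam, key, idx, gene=gene,
                    panel_requirement="monoallelic", mechanism="mosaic",
                    genotypes=gts, **_stop_gained())
            elif planted_class == "COMPOUND_HET_PARTNER_FAILED":
                fam = pool.take("trio")
                key1, idx = plotter.next_site()
                key2 = VariantKey(key1.chrom, key1.pos + 100, key1.ref, key1.alt)
                gts1, gts2 = plant_compound_het(
                    fam["proband"].id, fam["mother"].id, fam["father"].id, "trans"
                )
                # clean member at the lower coordinate; partner fails the
                # noncoding-consequence rule
                add(planted_class, fam, key1, idx, gene=gene,
                    panel_requirement="biallelic", genotypes=gts1, **_stop_gained())
                partner = PlantedVariant(
                    key=key2, gene=gene, panel_requirement="biallelic", mechanism="",
                    consequence="synonymous_variant", predictor="not_applicable",
                    population_maf=0.0, allele_count=0, genotypes=gts2, truth=[],
                    **catalog_style(idx + 1),
                )
                plants.append(partner)

    # --- cohort-prefilter drop classes ---
    for _ in range(counts["LOW_GQ"]):
        fam = pool.take("trio")
        gene = f"G{plotter._i + 1:04d}"
        key, idx = plotter.next_site()
        gts = {
            fam["proband"].id: GTSpec(het, gq=20),
            fam["mother"].id: GTSpec(het),
            fam["father"].id: GTSpec(ref),
        }
        add("LOW_GQ", fam, key, idx, gene=gene,
            panel_requirement="monoallelic", genotypes=gts, **_stop_gained())

    ordered_probands = [f for f in families]
    for plant_i in range(counts["INTERNAL_MAF"]):
        gene = f"G{plotter._i + 1:04d}"
        key, idx = plotter.next_site()
        mono_thresh = run_cfg.internal_maf_mono
        n_carriers = min(n_probands, math.ceil(2 * n_probands * mono_thresh) + 2)
        carrier_fams = ordered_probands[plant_i::1][:n_carriers]
        gts = {f["proband"].id: GTSpec(het) for f in carrier_fams}
        truth = [
            TruthRecord(key, f["proband"].id, "INTERNAL_MAF", "DROPPED")
            for f in carrier_fams
        ]
        plants.append(
            PlantedVariant(
                key=key, gene=gene, panel_requirement="monoallelic", mechanism="",
                genotypes=gts, truth=truth, **catalog_style(idx), **_stop_gained(),
            )
        )

    for plant_i in range(counts["RECURRENT_INDEL"]):
        gene = f"G{plotter._i + 1:04d}"
        key, idx = plotter.next_site(indel=True)
        n_carriers = min(n_probands, config.recurrent_indel_families)
        carrier_fams = ordered_probands[-n_carriers:]
        gts = {f["proband"].id: GTSpec(het) for f in carrier_fams}
        truth = [
            TruthRecord(key, f["proband"].id, "RECURRENT_INDEL", "DROPPED")
            for f in carrier_fams
        ]
        plants.append(
            PlantedVariant(
                key=key, gene=gene, panel_requirement="monoallelic", mechanism="",
                genotypes=gts, truth=truth, **catalog_style(idx), **_stop_gained(),
            )
        )

    for _ in range(counts["SINGLETON_DOUBLE_HET"]):
        fam = pool.take("singleton")
        gene = f"G{plotter._i + 1:04d}"
        key1, idx = plotter.next_site()
        key2 = VariantKey(key1.chrom, key1.pos + 100, key1.ref, key1.alt)
        gts1, gts2 = plant_compound_het(fam["proband"].id, None, None, "trans")
        add("SINGLETON_DOUBLE_HET", fam, key1, idx, gene=gene,
            panel_requirement="biallelic", genotypes=gts1, **_stop_gained())
        plants.append(
            PlantedVariant(
                key=key2, gene=gene, panel_requirement="biallelic", mechanism="",
                genotypes=gts2, truth=[], **catalog_style(idx + 1), **_stop_gained(),
            )
        )

    # --- variants the standard filter reports ---
    for j in range(counts[REPORTED_CLASS]):
        fam = pool.take("trio")
        gene = f"G{plotter._i + 1:04d}"
        key, idx = plotter.next_site()
        if j % 2 == 0:
            gts = {
                fam["proband"].id: GTSpec(het),
                fam["mother"].id: GTSpec(ref),
                fam["father"].id: GTSpec(ref),
            }
            ann = _missense("probably_damaging")
        else:
            # inherited from an affected parent: reportable despite transmission
            fam["mother"].affected = True
            gts = {
                fam["proband"].id: GTSpec(het),
                fam["mother"].id: GTSpec(het),
                fam["father"].id: GTSpec(ref),
            }
            ann = _stop_gained()
        add(REPORTED_CLASS, fam, key, idx, gene=gene,
            panel_requirement="monoallelic", genotypes=gts, **ann)

    # --- catalog-ineligible background ---
    styles = [
        {"significance": "Benign", "review_status": "criteria provided, single submitter"},
        {"significance": "Uncertain significance",
         "review_status": "criteria provided, single submitter"},
        {"significance": "Pathogenic", "review_status": "no assertion criteria provided"},
        {"significance": "Pathogenic", "review_status": "criteria provided, single submitter",
         "origin": "somatic"},
        {"significance": "Pathogenic", "review_status": "criteria provided, single submitter",
         "assembly": "GRCh38"},
        {"significance": "Conflicting interpretations of pathogenicity",
         "review_status": "criteria provided, conflicting interpretations"},
        {"significance": "Pathogenic", "review_status": "criteria provided, single submitter",
         "panel_requirement": "monoallelic", "panel_confidence": "possible"},
    ]
    for j in range(counts[BACKGROUND_CLASS]):
        fam = families[int(rng.integers(0, len(families)))]
        gene = f"BKG{j + 1:03d}"
        key, idx = plotter.next_site()
        style = dict(styles[j % len(styles)])
        requirement = style.pop("panel_requirement", None)
        confidence = style.pop("panel_confidence", "confirmed")
        gts = {fam["proband"].id: GTSpec(het)}
        plants.append(
            PlantedVariant(
                key=key, gene=gene, panel_requirement=requirement,
                panel_confidence=confidence, mechanism="", genotypes=gts,
                truth=[TruthRecord(key, fam["proband"].id, BACKGROUND_CLASS, "NOT_MATCHED")],
                **style, **_stop_gained(),
            )
        )
    return plants


# ---------------------------------------------------------------------------
# file writers


def _chrom_order(chrom: str) -> int:
    return _CHROMS.index(chrom)


def _format_call(
    spec: Optional[GTSpec],
    member: _Member,
    on_x: bool,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> str:
    if spec is None:
        alleles = (0,) if on_x and member.sex is Sex.MALE else (0, 0)
        spec = GTSpec(alleles)
    dm = config.depth_model
    if spec.dp is not None:
        dp = spec.dp
    elif config.sequencing_noise:
        r = dm.overdispersion
        p = r / (r + dm.mean)
        dp = max(1, int(rng.negative_binomial(r, p)))
    else:
        dp = int(round(dm.mean))
    n_alt_alleles = sum(1 for a in spec.alleles if a == 1)
    if n_alt_alleles == 0:
        vaf = 0.0
    elif spec.vaf is not None:
        vaf = spec.vaf
    elif n_alt_alleles == len(spec.alleles):
        vaf = 1.0
    else:
        vaf = 0.5
    if config.sequencing_noise and 0.0 < vaf < 1.0:
        ad_alt = int(rng.binomial(dp, vaf))
    else:
        ad_alt = int(round(dp * vaf))
    ad_ref = dp - ad_alt
    gt = "/".join(str(a) for a in spec.alleles)
    return f"{gt}:{spec.gq}:{dp}:{ad_ref},{ad_alt}"


def _write_vcf(
    path: Path,
    plants: list[PlantedVariant],
    members: list[_Member],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> None:
    samples = [m.id for m in members]
    by_sample = {m.id: m for m in members}
    header = ["##fileformat=VCFv4.2", "##source=clinvar_rescreen-synthetic-cohort"]
    header += [f"##contig=<ID={c}>" for c in _CHROMS]
    header += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">',
    ]
    header.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    lines = list(header)
    seen: set[VariantKey] = set()
    for plant in sorted(plants, key=lambda p: (_chrom_order(p.key.chrom), p.key.pos)):
        if plant.key in seen:
            continue
        seen.add(plant.key)
        on_x = plant.key.chrom == "X"
        fields = [
            plant.key.chrom, str(plant.key.pos), ".", plant.key.ref, plant.key.alt,
            "100", "PASS", ".", "GT:GQ:DP:AD",
        ]
        for sample in samples:
            fields.append(
                _format_call(plant.genotypes.get(sample), by_sample[sample], on_x, config, rng)
            )
        lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + "\n")


def _write_ped(path: Path, members: list[_Member], families: list[dict]) -> None:
    lines = []
    for fam in families:
        proband = fam["proband"]
        if fam["kind"] == "trio":
            lines.append(
                "\t".join([fam["id"], proband.id, fam["father"].id, fam["mother"].id,
                           "1" if proband.sex is Sex.MALE else "2", "2", "0"])
            )
            for parent in (fam["mother"], fam["father"]):
                lines.append(
                    "\t".join([fam["id"], parent.id, "0", "0",
                               "1" if parent.sex is Sex.MALE else "2",
                               "2" if parent.affected else "1",
                               "1" if parent.similar else "0"])
                )
        else:
            lines.append(
                "\t".join([fam["id"], proband.id, "0", "0",
                           "1" if proband.sex is Sex.MALE else "2", "2", "0"])
            )
    path.write_text("\n".join(lines) + "\n")


def _write_tables(out: Path, plants: list[PlantedVariant]) -> None:
    catalog_rows = []
    variation_id = 0
    for plant in plants:
        variation_id += 1
        catalog_rows.append(
            {
                "assembly": plant.assembly, "chrom": plant.key.chrom,
                "pos": plant.key.pos, "ref": plant.key.ref, "alt": plant.key.alt,
                "significance": plant.significance, "review_status": plant.review_status,
                "origin": plant.origin, "gene": plant.gene,
                "variation_id": f"V{variation_id:06d}",
            }
        )
        if plant.catalog_duplicate:
            variation_id += 1
            dup = dict(catalog_rows[-1])
            dup["review_status"] = "criteria provided, single submitter"
            dup["variation_id"] = f"V{variation_id:06d}"
            catalog_rows.append(dup)
    pd.DataFrame(catalog_rows).to_csv(out / "clinvar.tsv", sep="\t", index=False)

    panel_rows = {}
    for plant in plants:
        if plant.panel_requirement is None:
            continue
        panel_rows[plant.gene] = {
            "gene": plant.gene,
            "allelic_requirement": plant.panel_requirement,
            "mutation_consequence": "altered gene product structure",
            "mechanism": plant.mechanism,
            "confidence": plant.panel_confidence,
        }
    pd.DataFrame([panel_rows[g] for g in sorted(panel_rows)]).to_csv(
        out / "panel.csv", index=False
    )

    ann_rows = []
    seen: set[VariantKey] = set()
    for plant in sorted(plants, key=lambda p: (_chrom_order(p.key.chrom), p.key.pos)):
        if plant.key in seen:
            continue
        seen.add(plant.key)
        ann_rows.append(
            {
                "chrom": plant.key.chrom, "pos": plant.key.pos,
                "ref": plant.key.ref, "alt": plant.key.alt,
                "consequence": plant.consequence,
                "missense_predictor": plant.predictor,
                "population_maf": repr(plant.population_maf),
                "population_allele_count": plant.allele_count,
            }
        )
    pd.DataFrame(ann_rows).to_csv(out / "annotations.tsv", sep="\t", index=False)


def write_truth_table(truth: list[TruthRecord], path: Path) -> None:
    rows = [
        {
            "chrom": t.key.chrom, "pos": t.key.pos, "ref": t.key.ref, "alt": t.key.alt,
            "proband": t.proband, "planted_class": t.planted_class,
            "expected_status": t.expected_status,
        }
        for t in truth
    ]
    pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "proband", "planted_class", "expected_status"],
    ).to_csv(path, sep="\t", index=False)


def read_truth_table(path: str | Path) -> list[TruthRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        TruthRecord(
            VariantKey(r.chrom, int(r.pos), r.ref, r.alt),
            r.proband, r.planted_class, r.expected_status,
        )
        for r in df.itertuples(index=False)
    ]


def simulate(config: SimulationConfig, out_dir: str | Path) -> SimulatedCohort:
    """Generate the five pipeline inputs plus truth table and run config.

    Deterministic given ``config.seed``: repeated runs produce byte-identical
    files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    members, families = _build_families(config)
    plants = _build_plants(config, families, rng)

    _write_vcf(out / "cohort.vcf", plants, members, config, rng)
    _write_ped(out / "cohort.ped", members, families)
    _write_tables(out, plants)
    truth = [t for plant in plants for t in plant.truth]
    write_truth_table(truth, out / "truth.tsv")
    run_cfg = scaled_run_config(config)
    run_cfg.to_yaml(out / "run_config.yaml")
    return SimulatedCohort(
        vcf=out / "cohort.vcf",
        ped=out / "cohort.ped",
        clinvar=out / "clinvar.tsv",
        panel=out / "panel.csv",
        annotations=out / "annotations.tsv",
        truth_table=out / "truth.tsv",
        run_config=out / "run_config.yaml",
        truth=truth,
    )
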
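"""Readers/writers for the external file formats and shared variant-key handling.

Everything downstream joins a clinical catalog (ClinVar-style TSV) against
cohort genotypes (multi-sample VCF) by allele identity, so every entry point
funnels coordinates through :func:`normalize_key`, which produces the minimal
left-aligned representation of a variant. Coordinates are 1-based, fully
closed, VCF convention throughout; chromosome labels are stripped of any
``chr`` prefix on read.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterator, Mapping, Optional

import pandas as pd
import pysam

logger = logging.getLogger(__name__)

_ALLELE_ALPHABET = frozenset("ACGT")

NONCODING_CONSEQUENCES = frozenset(
    {
        "splice_region_variant",
        "5_prime_UTR_variant",
        "3_prime_UTR_variant",
        "intron_variant",
        "synonymous_variant",
    }
)


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


class Role(str, Enum):
    PROBAND = "proband"
    MOTHER = "mother"
    FATHER = "father"


class GT(str, Enum):
    """Per-sample genotype with respect to one alternate allele."""

    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    HEMI_ALT = "hemi_alt"
    MISSING = "missing"


class AllelicRequirement(str, Enum):
    """Normalized allelic requirement of a gene-disease pair.

    ``hemizygous`` covers the panel's "x-linked dominant" spelling as well:
    both describe genes where a single X-borne allele suffices in males.
    """

    MONOALLELIC = "monoallelic"
    BIALLELIC = "biallelic"
    HEMIZYGOUS = "hemizygous"
    X_LINKED_OVERDOMINANT = "x-linked over-dominance"


_REQUIREMENT_ALIASES = {
    "monoallelic": AllelicRequirement.MONOALLELIC,
    "biallelic": AllelicRequirement.BIALLELIC,
    "hemizygous": AllelicRequirement.HEMIZYGOUS,
    "x-linked dominant": AllelicRequirement.HEMIZYGOUS,
    "x-linked over-dominance": AllelicRequirement.X_LINKED_OVERDOMINANT,
    "x-linked overdominance": AllelicRequirement.X_LINKED_OVERDOMINANT,
}

_MECHANISM_FLAGS = frozenset({"imprinted", "mosaic"})


def _clean_chrom(chrom: str) -> str:
    chrom = str(chrom).strip()
    if chrom.lower().startswith("chr"):
        chrom = chrom[3:]
    return chrom


@dataclass(frozen=True, order=True)
class VariantKey:
    """Identity of a biallelic variant in minimal left-aligned representation."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        for allele in (self.ref, self.alt):
            if not allele or not set(allele) <= _ALLELE_ALPHABET:
                raise ValueError(f"invalid allele string {allele!r}")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @classmethod
    def parse(cls, text: str) -> "VariantKey":
        chrom, pos, ref, alt = text.split(":")
        return cls(_clean_chrom(chrom), int(pos), ref, alt)


def normalize_key(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    reference_context: Optional[Mapping[str, str]] = None,
) -> VariantKey:
    """Reduce (chrom, pos, ref, alt) to its minimal left-aligned representation.

    Shared leading/trailing bases are trimmed, and indels are shifted left
    through repeat context when ``reference_context`` (a mapping of chromosome
    label to its full sequence, 1-based positions) is supplied. Idempotent:
    a key already minimal and left-aligned is returned unchanged.

    Symbolic alleles (``<DEL>``, ``*``) and unsplit multi-allelic ALT strings
    are rejected; callers must decompose multi-allelic sites first.
    """
    chrom = _clean_chrom(chrom)
    ref = str(ref).upper()
    alt = str(alt).upper()
    if "," in alt:
        raise ValueError(f"unsplit multi-allelic ALT {alt!r}; decompose the site first")
    for allele in (ref, alt):
        if not allele or not set(allele) <= _ALLELE_ALPHABET:
            raise ValueError(f"symbolic or invalid allele {allele!r}")

    def _base_before(p: int) -> Optional[str]:
        # reference base at 1-based position p-1, if the context covers it
        if reference_context is None or p <= 1:
            return None
        seq = reference_context.get(chrom)
        if seq is None or p - 2 >= len(seq) or p - 2 < 0:
            return None
        base = seq[p - 2].upper()
        return base if base in _ALLELE_ALPHABET else None

    # right-trim / left-shift (standard variant normalization)
    while ref != alt:
        if ref[-1] == alt[-1]:
            if len(ref) > 1 and len(alt) > 1:
                ref, alt = ref[:-1], alt[:-1]
                continue
            prev = _base_before(pos)
            if prev is None:
                break
            ref, alt = prev + ref[:-1], prev + alt[:-1]
            pos -= 1
            continue
        break
    # left-trim shared prefix
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return VariantKey(chrom, pos, ref, alt)


# ---------------------------------------------------------------------------
# pedigree


@dataclass(frozen=True)
class Individual:
    id: str
    family_id: str
    sex: Sex
    role: Role
    affected: bool
    similar_phenotype_to_child: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.role is Role.PROBAND and not self.affected:
            raise ValueError(f"proband {self.id} must be affected")
        if self.role is Role.PROBAND and self.similar_phenotype_to_child is not None:
            raise ValueError("similar_phenotype_to_child is defined only for parents")


@dataclass
class Family:
    id: str
    probands: list[Individual] = field(default_factory=list)
    mother: Optional[Individual] = None
    father: Optional[Individual] = None


@dataclass
class Pedigree:
    members: dict[str, Individual]
    families: dict[str, Family]

    def probands(self) -> list[Individual]:
        out: list[Individual] = []
        for fid in sorted(self.families):
            out.extend(self.families[fid].probands)
        return out

    def parents_of(self, proband: Individual) -> tuple[Optional[Individual], Optional[Individual]]:
        fam = self.families[proband.family_id]
        return fam.mother, fam.father

    def is_singleton(self, proband: Individual) -> bool:
        mother, father = self.parents_of(proband)
        return mother is None and father is None


def read_pedigree(path: str | Path) -> Pedigree:
    """Parse a 6(+1)-column PED file into a trio/singleton pedigree.

    Columns: family, individual, father, mother, sex (1=male/2=female),
    phenotype (1=unaffected/2=affected), optional 7th column = parental
    phenotype-similarity flag (0/1). Probands must list either both parents
    (trio) or neither (singleton); one recorded parent is an error.
    """
    rows: list[tuple[str, ...]] = []
    for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = tuple(line.split())
        if len(parts) not in (6, 7):
            raise ValueError(f"{path}:{line_no}: expected 6 or 7 columns, got {len(parts)}")
        rows.append(parts)

    father_ids = {r[2] for r in rows if r[2] != "0"}
    mother_ids = {r[3] for r in rows if r[3] != "0"}
    all_ids = {r[1] for r in rows}
    for parent_id in (father_ids | mother_ids) - all_ids:
        raise ValueError(f"parent {parent_id} referenced but has no PED row")

    members: dict[str, Individual] = {}
    families: dict[str, Family] = {}
    proband_rows: list[tuple[str, ...]] = []
    for fam, iid, fat, mot, sex_code, phen, *extra in rows:
        if iid in members:
            raise ValueError(f"individual {iid} appears twice")
        if sex_code not in ("1", "2"):
            raise ValueError(f"individual {iid}: sex must be 1 or 2, got {sex_code!r}")
        sex = Sex.MALE if sex_code == "1" else Sex.FEMALE
        affected = phen == "2"
        if iid in father_ids or iid in mother_ids:
            role = Role.FATHER if iid in father_ids else Role.MOTHER
            if iid in father_ids and iid in mother_ids:
                raise ValueError(f"individual {iid} listed as both father and mother")
            if role is Role.FATHER and sex is not Sex.MALE:
                raise ValueError(f"father {iid} must be male")
            if role is Role.MOTHER and sex is not Sex.FEMALE:
                raise ValueError(f"mother {iid} must be female")
            similar = bool(int(extra[0])) if extra else False
            ind = Individual(iid, fam, sex, role, affected, similar)
        else:
            if (fat == "0") != (mot == "0"):
                raise ValueError(
                    f"proband {iid} lists exactly one parent; trios or singletons only"
                )
            role = Role.PROBAND
            ind = Individual(iid, fam, sex, role, affected, None)
            proband_rows.append((fam, iid, fat, mot))
        if ind.family_id in families and any(
            m.family_id != fam for m in members.values() if m.id == iid
        ):  # pragma: no cover - guarded by duplicate-id check above
            raise ValueError(f"individual {iid} appears in two families")
        members[iid] = ind
        family = families.setdefault(fam, Family(fam))
        if role is Role.PROBAND:
            family.probands.append(ind)
        elif role is Role.MOTHER:
            if family.mother is not None:
                raise ValueError(f"family {fam} has two mothers")
            family.mother = ind
        else:
            if family.father is not None:
                raise ValueError(f"family {fam} has two fathers")
            family.father = ind

    for fam, iid, fat, mot in proband_rows:
        if fat != "0" and members[fat].family_id != fam:
            raise ValueError(f"father of {iid} belongs to a different family")
        if mot != "0" and members[mot].family_id != fam:
            raise ValueError(f"mother of {iid} belongs to a different family")
    for family in families.values():
        if not family.probands:
            raise ValueError(f"family {family.id} has no proband")
    return Pedigree(members, families)


def write_pedigree(pedigree: Pedigree, path: str | Path) -> None:
    lines = []
    for fid in sorted(pedigree.families):
        fam = pedigree.families[fid]
        order = fam.probands + [p for p in (fam.mother, fam.father) if p is not None]
        for ind in order:
            if ind.role is Role.PROBAND:
                fat = fam.father.id if fam.father else "0"
                mot = fam.mother.id if fam.mother else "0"
            else:
                fat = mot = "0"
            sex_code = "1" if ind.sex is Sex.MALE else "2"
            phen = "2" if ind.affected else "1"
            similar = "0"
            if ind.similar_phenotype_to_child:
                similar = "1"
            lines.append("\t".join([fid, ind.id, fat, mot, sex_code, phen, similar]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# genotypes


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's call against a single alternate allele."""

    gt: GT
    gq: int = 0
    dp: int = 0
    ad_ref: int = 0
    ad_alt: int = 0

    def __post_init__(self) -> None:
        if self.gq < 0 or self.dp < 0 or self.ad_ref < 0 or self.ad_alt < 0:
            raise ValueError("genotype metrics must be non-negative")
        if self.ad_ref + self.ad_alt > self.dp:
            raise ValueError("allele depths exceed total depth")

    @property
    def vaf(self) -> Optional[float]:
        denom = self.ad_ref + self.ad_alt
        if denom == 0:
            return None
        return self.ad_alt / denom

    @property
    def carries_alt(self) -> bool:
        return self.gt in (GT.HET, GT.HOM_ALT, GT.HEMI_ALT)


def _decompose_sample(
    gt_tuple: tuple,
    alt_index: int,
    gq: int,
    dp: int,
    ad: tuple,
) -> GenotypeCall:
    """Project a possibly multi-allelic sample call onto one alt allele.

    Other alternate alleles are treated as reference for the projected key;
    allele depths are remapped so ad_alt is the depth of this allele alone.
    """
    target = alt_index + 1
    ad_ref = int(ad[0]) if ad and ad[0] is not None else 0
    ad_alt = 0
    if ad and len(ad) > target and ad[target] is not None:
        ad_alt = int(ad[target])
    dp = max(int(dp), ad_ref + ad_alt)
    if gt_tuple is None or all(a is None for a in gt_tuple):
        return GenotypeCall(GT.MISSING, 0, dp, 0, 0)
    alleles = [a for a in gt_tuple if a is not None]
    n_target = sum(1 for a in alleles if a == target)
    if len(alleles) == 1:
        gt = GT.HEMI_ALT if n_target == 1 else GT.HOM_REF
    elif n_target == 0:
        gt = GT.HOM_REF
    elif n_target == 1:
        gt = GT.HET
    else:
        gt = GT.HOM_ALT
    return GenotypeCall(gt, int(gq), dp, ad_ref, ad_alt)


def read_cohort_vcf(
    path: str | Path, pedigree: Pedigree
) -> Iterator[tuple[VariantKey, dict[str, GenotypeCall]]]:
    """Stream a multi-sample cohort VCF as (key, sample -> call) pairs.

    Multi-allelic sites are decomposed into one biallelic key per alternate
    allele before normalization; missing genotypes are yielded with
    ``gt = missing``. Every VCF sample must exist in the pedigree.
    """
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        unknown = [s for s in samples if s not in pedigree.members]
        if unknown:
            raise ValueError(f"VCF samples absent from pedigree: {unknown}")
        for rec in vcf:
            alts = rec.alts or ()
            for alt_index, alt in enumerate(alts):
                try:
                    key = normalize_key(rec.chrom, rec.pos, rec.ref, alt)
                except ValueError:
                    logger.warning("skipping unparseable allele at %s:%s", rec.chrom, rec.pos)
                    continue
                calls: dict[str, GenotypeCall] = {}
                for sample in samples:
                    s = rec.samples[sample]
                    calls[sample] = _decompose_sample(
                        s.get("GT"),
                        alt_index,
                        s.get("GQ") or 0,
                        s.get("DP") or 0,
                        s.get("AD") or (),
                    )
                yield key, calls


# ---------------------------------------------------------------------------
# catalog / panel / annotation tables

_CLINVAR_COLUMNS = [
    "assembly",
    "chrom",
    "pos",
    "ref",
    "alt",
    "significance",
    "review_status",
    "origin",
    "gene",
    "variation_id",
]


def read_clinvar_table_counted(path: str | Path):
    """Read a ClinVar-style TSV; returns (records, n_skipped).

    Rows whose coordinates cannot be parsed into a valid allele key are
    skipped and counted. No eligibility filtering happens here.
    """
    from .clinvar_catalog import CatalogRecord  # deferred: avoids import cycle

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in _CLINVAR_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"catalog table is missing mandatory column {col!r}")
    records = []
    n_skipped = 0
    for row in df.itertuples(index=False):
        try:
            key = normalize_key(row.chrom, int(row.pos), row.ref, row.alt)
        except (ValueError, TypeError):
            n_skipped += 1
            continue
        records.append(
            CatalogRecord(
                key=key,
                significance=row.significance,
                review_status=row.review_status,
                origin=row.origin,
                assembly=row.assembly,
                gene=row.gene,
                variation_id=row.variation_id,
            )
        )
    if n_skipped:
        logger.warning("skipped %d catalog rows with unparseable coordinates", n_skipped)
    return records, n_skipped


def read_clinvar_table(path: str | Path):
    """Read a ClinVar-style TSV into a list of CatalogRecord."""
    return read_clinvar_table_counted(path)[0]


def write_clinvar_table(records, path: str | Path) -> None:
    rows = [
        {
            "assembly": r.assembly,
            "chrom": r.key.chrom,
            "pos": r.key.pos,
            "ref": r.key.ref,
            "alt": r.key.alt,
            "significance": r.significance,
            "review_status": r.review_status,
            "origin": r.origin,
            "gene": r.gene,
            "variation_id": r.variation_id,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_CLINVAR_COLUMNS).to_csv(path, sep="\t", index=False)


_PANEL_COLUMNS = ["gene", "allelic_requirement", "mutation_consequence", "mechanism", "confidence"]


def read_gene_panel(path: str | Path):
    """Read a gene-to-phenotype panel CSV into a list of PanelEntry.

    The allelic-requirement vocabulary is fixed; unknown strings raise with
    the accepted values listed. The mechanism column holds semicolon-joined
    flags from {imprinted, mosaic} (may be empty).
    """
    from .clinvar_catalog import PanelEntry  # deferred: avoids import cycle

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in _PANEL_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"panel table is missing mandatory column {col!r}")
    entries = []
    for row in df.itertuples(index=False):
        req_raw = row.allelic_requirement.strip().lower()
        if req_raw not in _REQUIREMENT_ALIASES:
            raise ValueError(
                f"unknown allelic requirement {row.allelic_requirement!r} for gene "
                f"{row.gene}; accepted: {sorted(_REQUIREMENT_ALIASES)}"
            )
        flags = {f.strip().lower() for f in row.mechanism.split(";") if f.strip()}
        if not flags <= _MECHANISM_FLAGS:
            raise ValueError(
                f"unknown mechanism flags {sorted(flags - _MECHANISM_FLAGS)}; "
                f"accepted: {sorted(_MECHANISM_FLAGS)}"
            )
        entries.append(
            PanelEntry(
                gene=row.gene,
                requirement=_REQUIREMENT_ALIASES[req_raw],
                mutation_consequence=row.mutation_consequence,
                imprinted="imprinted" in flags,
                mosaic="mosaic" in flags,
                confidence=row.confidence.strip().lower(),
            )
        )
    return entries


def write_gene_panel(entries, path: str | Path) -> None:
    rows = []
    for e in entries:
        flags = ";".join(f for f, on in (("imprinted", e.imprinted), ("mosaic", e.mosaic)) if on)
        rows.append(
            {
                "gene": e.gene,
                "allelic_requirement": e.requirement.value,
                "mutation_consequence": e.mutation_consequence,
                "mechanism": flags,
                "confidence": e.confidence,
            }
        )
    pd.DataFrame(rows, columns=_PANEL_COLUMNS).to_csv(path, index=False)


class MissensePrediction(str, Enum):
    BENIGN = "benign"
    POSSIBLY_DAMAGING = "possibly_damaging"
    PROBABLY_DAMAGING = "probably_damaging"
    NOT_APPLICABLE = "not_applicable"


@dataclass(frozen=True)
class AnnotationRecord:
    """Per-variant functional annotation consumed by the clinical filter.

    ``population_maf`` models a gnomAD-style frequency and
    ``population_allele_count`` an ExAC-style count; they come from two
    different reference resources and need not be mutually consistent.
    """

    key: VariantKey
    consequence: str
    missense_predictor: MissensePrediction
    population_maf: float
    population_allele_count: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.population_maf <= 1.0:
            raise ValueError("population_maf must be in [0, 1]")
        if self.population_allele_count < 0:
            raise ValueError("population_allele_count must be >= 0")
        is_missense = self.consequence == "missense_variant"
        if is_missense == (self.missense_predictor is MissensePrediction.NOT_APPLICABLE):
            raise ValueError(
                "missense_predictor must be set exactly for missense_variant consequences"
            )


_ANNOTATION_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "consequence",
    "missense_predictor",
    "population_maf",
    "population_allele_count",
]


def read_annotations(path: str | Path) -> dict[VariantKey, AnnotationRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in _ANNOTATION_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"annotation table is missing mandatory column {col!r}")
    out: dict[VariantKey, AnnotationRecord] = {}
    for row in df.itertuples(index=False):
        key = normalize_key(row.chrom, int(row.pos), row.ref, row.alt)
        if key in out:
            raise ValueError(f"duplicate annotation key {key}")
        out[key] = AnnotationRecord(
            key=key,
            consequence=row.consequence,
            missense_predictor=MissensePrediction(row.missense_predictor),
            population_maf=float(row.population_maf),
            population_allele_count=int(row.population_allele_count),
        )
    return out


def write_annotations(records, path: str | Path) -> None:
    rows = [
        {
            "chrom": r.key.chrom,
            "pos": r.key.pos,
            "ref": r.key.ref,
            "alt": r.key.alt,
            "consequence": r.consequence,
            "missense_predictor": r.missense_predictor.value,
            "population_maf": repr(r.population_maf),
            "population_allele_count": r.population_allele_count,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# report output

DECISION_COLUMNS = [
    "family",
    "proband",
    "sex",
    "chrom",
    "pos",
    "ref",
    "alt",
    "partner",
    "gene",
    "requirement",
    "genotype_class",
    "male_x_het",
    "inheritance",
    "internal_maf",
    "stars",
    "child_gq",
    "child_dp",
    "child_vaf",
    "parent_vaf",
    "consequence",
    "missense_predictor",
    "population_maf",
    "population_allele_count",
    "status",
    "drop_reason",
    "primary_reason",
    "all_reasons",
    "parental_mosaicism",
]


def write_report(rows: list[dict], out_dir: str | Path, summary: dict) -> tuple[Path, Path]:
    """Write the per-observation decision TSV and the Table-1-style JSON summary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tsv_path = out_dir / "decisions.tsv"
    json_path = out_dir / "summary.json"
    pd.DataFrame(rows, columns=DECISION_COLUMNS).to_csv(tsv_path, sep="\t", index=False)
    json_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return tsv_path, json_path


def read_report(path: str | Path) -> pd.DataFrame:
    """Re-read a decision TSV (all columns as strings; empty cells = '')."""
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
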
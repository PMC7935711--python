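"""Find eligible catalog variants in probands with requirement-appropriate zygosity.

A catalog variant only becomes an observation when the proband's genotype
satisfies the allelic requirement of the gene-disease pair: heterozygous (or
homozygous) in monoallelic genes, homozygous or trans compound-heterozygous in
biallelic genes, hemizygous in X-linked genes in males and het/hom in females.
Observations then pass through the cohort prefilter (internal allele
frequency, genotype quality, recurrent indels, unphaseable singleton double
hets) before the clinical rule engine sees them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from itertools import combinations
from typing import Mapping, Optional

from .clinvar_catalog import EligibleCatalog, PanelEntry
from .config import Config
from .io_formats import (
    GT,
    AllelicRequirement,
    AnnotationRecord,
    GenotypeCall,
    Individual,
    Pedigree,
    Sex,
    VariantKey,
)

logger = logging.getLogger(__name__)


class GenotypeClass(str, Enum):
    HET = "het"
    HOM = "hom"
    HEMI = "hemi"
    COMPOUND_HET_PAIR = "compound_het_pair"


class Inheritance(str, Enum):
    MATERNAL = "maternal"
    PATERNAL = "paternal"
    BIPARENTAL = "biparental"
    DE_NOVO = "de_novo"
    UNKNOWN = "unknown"


class DropReason(str, Enum):
    """Cohort-prefilter elimination classes, in drop precedence order."""

    LOW_GQ = "LOW_GQ"
    INTERNAL_MAF = "INTERNAL_MAF"
    RECURRENT_INDEL = "RECURRENT_INDEL"
    SINGLETON_DOUBLE_HET = "SINGLETON_DOUBLE_HET"


def is_x(chrom: str) -> bool:
    # chrX is treated uniformly non-pseudoautosomal
    return chrom.upper() == "X"


def classify_genotype(call: GenotypeCall, sex: Sex, chrom: str) -> tuple[GT, bool]:
    """Classify one call given carrier sex and chromosome.

    Returns (genotype, male_x_het_flag). On non-PAR X in males any alt call
    is hemizygous; a diploid het call there is anomalous (mosaicism or XXY
    aneuploidy) and is flagged rather than reinterpreted.
    """
    if call.gt is GT.MISSING:
        raise ValueError("cannot classify a missing call")
    if is_x(chrom) and sex is Sex.MALE:
        if call.gt is GT.HET:
            return GT.HET, True
        if call.gt in (GT.HOM_ALT, GT.HEMI_ALT):
            return GT.HEMI_ALT, False
        return GT.HOM_REF, False
    return call.gt, False


def infer_inheritance(
    child_call: GenotypeCall,
    mother_call: Optional[GenotypeCall],
    father_call: Optional[GenotypeCall],
    config: Config | None = None,
) -> Inheritance:
    """Infer transmission of the child's alt allele from parental genotypes.

    De novo status requires both parents confidently hom-ref (GQ and depth
    floors from config); a carrier parent is positive evidence regardless of
    quality. Missing parents or missing parental calls give ``unknown``.
    """
    config = config or Config()
    if not child_call.carries_alt:
        raise ValueError("inheritance is only defined when the child carries the alt allele")
    if mother_call is None or father_call is None:
        return Inheritance.UNKNOWN
    if mother_call.gt is GT.MISSING or father_call.gt is GT.MISSING:
        return Inheritance.UNKNOWN
    m_carrier = mother_call.carries_alt
    f_carrier = father_call.carries_alt
    if m_carrier and f_carrier:
        return Inheritance.BIPARENTAL
    if m_carrier:
        return Inheritance.MATERNAL
    if f_carrier:
        return Inheritance.PATERNAL

    def confident_ref(call: GenotypeCall) -> bool:
        return call.gq >= config.parent_min_gq and call.dp >= config.parent_min_dp

    if confident_ref(mother_call) and confident_ref(father_call):
        return Inheritance.DE_NOVO
    return Inheritance.UNKNOWN


def internal_maf(
    key: VariantKey,
    calls: Mapping[str, GenotypeCall],
    pedigree: Pedigree,
) -> float:
    """Cohort alternate-allele frequency over unrelated probands.

    One proband per family (distinct family ids define "unrelated"); parents
    are excluded to avoid double-counting transmitted alleles. Males
    contribute a single allele on chrX. Zero called alleles gives 0 with a
    warning.
    """
    alt = 0
    called = 0
    for fid in sorted(pedigree.families):
        proband = pedigree.families[fid].probands[0]
        call = calls.get(proband.id)
        if call is None or call.gt is GT.MISSING:
            continue
        haploid = is_x(key.chrom) and proband.sex is Sex.MALE
        if haploid:
            called += 1
            alt += 1 if call.carries_alt else 0
        else:
            called += 2
            alt += {GT.HOM_REF: 0, GT.HET: 1, GT.HOM_ALT: 2, GT.HEMI_ALT: 1}[call.gt]
    if called == 0:
        logger.warning("no called alleles for %s; internal MAF undefined, using 0", key)
        return 0.0
    return alt / called


def carrier_family_count(calls: Mapping[str, GenotypeCall], pedigree: Pedigree) -> int:
    """Number of distinct families whose proband carries the alt allele."""
    n = 0
    for fid in sorted(pedigree.families):
        proband = pedigree.families[fid].probands[0]
        call = calls.get(proband.id)
        if call is not None and call.carries_alt:
            n += 1
    return n


@dataclass
class VariantObservation:
    """A catalog variant detected in one proband with appropriate zygosity."""

    proband: Individual
    key: VariantKey
    gene: str
    requirement: AllelicRequirement
    genotype_class: GenotypeClass
    child_call: GenotypeCall
    mother: Optional[Individual] = None
    father: Optional[Individual] = None
    mother_call: Optional[GenotypeCall] = None
    father_call: Optional[GenotypeCall] = None
    inheritance: Inheritance = Inheritance.UNKNOWN
    internal_maf: float = 0.0
    male_x_het: bool = False
    hom_in_monoallelic: bool = False
    stars: Optional[int] = None
    annotation: Optional[AnnotationRecord] = None
    partner: Optional["VariantObservation"] = None  # compound-het second member

    def __post_init__(self) -> None:
        if (self.partner is not None) != (
            self.genotype_class is GenotypeClass.COMPOUND_HET_PAIR
        ):
            raise ValueError("partner is defined iff genotype_class is compound_het_pair")

    @property
    def partner_key(self) -> Optional[VariantKey]:
        return self.partner.key if self.partner is not None else None

    @property
    def is_singleton(self) -> bool:
        return self.mother is None and self.father is None

    def transmitting_parent(self) -> Optional[Individual]:
        if self.inheritance is Inheritance.MATERNAL:
            return self.mother
        if self.inheritance is Inheritance.PATERNAL:
            return self.father
        return None

    def transmitting_call(self) -> Optional[GenotypeCall]:
        if self.inheritance is Inheritance.MATERNAL:
            return self.mother_call
        if self.inheritance is Inheritance.PATERNAL:
            return self.father_call
        return None


def _single_observation(
    proband: Individual,
    pedigree: Pedigree,
    key: VariantKey,
    entry: PanelEntry,
    calls: Mapping[str, GenotypeCall],
    mafs: Mapping[VariantKey, float],
    stars: Optional[int],
    config: Config,
) -> Optional[VariantObservation]:
    child = calls.get(proband.id)
    if child is None or child.gt is GT.MISSING:
        return None
    gclass, male_x_het = classify_genotype(child, proband.sex, key.chrom)
    if gclass is GT.HOM_REF:
        return None
    mother, father = pedigree.parents_of(proband)
    mother_call = calls.get(mother.id) if mother else None
    father_call = calls.get(father.id) if father else None
    inheritance = (
        infer_inheritance(child, mother_call, father_call, config)
        if (mother or father)
        else Inheritance.UNKNOWN
    )
    genotype_class = {
        GT.HET: GenotypeClass.HET,
        GT.HOM_ALT: GenotypeClass.HOM,
        GT.HEMI_ALT: GenotypeClass.HEMI,
    }[gclass]
    return VariantObservation(
        proband=proband,
        key=key,
        gene=entry.gene,
        requirement=entry.requirement,
        genotype_class=genotype_class,
        child_call=child,
        mother=mother,
        father=father,
        mother_call=mother_call,
        father_call=father_call,
        inheritance=inheritance,
        internal_maf=mafs.get(key, 0.0),
        male_x_het=male_x_het,
        stars=stars,
    )


def match_proband(
    proband: Individual,
    pedigree: Pedigree,
    catalog: EligibleCatalog,
    genotypes: Mapping[VariantKey, Mapping[str, GenotypeCall]],
    mafs: Mapping[VariantKey, float],
    config: Config | None = None,
) -> list[VariantObservation]:
    """Emit the proband's observations whose zygosity satisfies the gene requirement.

    Monoallelic (including imprinted/mosaic-mechanism genes): het suffices;
    hom-alt is matched too (a dominant allele is no less present when
    homozygous) and flagged. Biallelic: hom-alt, or a pair of distinct het
    catalog variants in one gene - in trios the pair must be in trans (one
    maternal, one paternal); in singletons phase is unknowable and the pair
    is emitted for the prefilter to drop. X-linked (hemizygous and
    overdominant requirements): hemizygous males, het/hom females; a diploid
    male X het is matched with its anomaly flag so the filter can adjudicate
    it.
    """
    config = config or Config()
    by_gene: dict[str, list[VariantObservation]] = {}
    for key in sorted(catalog.records):
        record = catalog.records[key]
        calls = genotypes.get(key)
        if calls is None:
            continue
        entry = catalog.panel_index[record.gene]
        obs = _single_observation(
            proband, pedigree, key, entry, calls, mafs, record.stars, config
        )
        if obs is not None:
            by_gene.setdefault(record.gene, []).append(obs)

    out: list[VariantObservation] = []
    for gene in sorted(by_gene):
        members = by_gene[gene]
        requirement = members[0].requirement
        if requirement is AllelicRequirement.BIALLELIC:
            for obs in members:
                if obs.genotype_class is GenotypeClass.HOM:
                    out.append(obs)
            hets = [m for m in members if m.genotype_class is GenotypeClass.HET]
            for first, second in combinations(hets, 2):
                singleton = first.is_singleton
                if not singleton:
                    pair_inh = {first.inheritance, second.inheritance}
                    if pair_inh != {Inheritance.MATERNAL, Inheritance.PATERNAL}:
                        continue  # cis or unresolved phase: not a trans pair
                pair = replace(
                    first,
                    genotype_class=GenotypeClass.COMPOUND_HET_PAIR,
                    partner=second,
                )
                out.append(pair)
        else:
            for obs in members:
                if requirement is AllelicRequirement.MONOALLELIC:
                    if obs.genotype_class is GenotypeClass.HOM:
                        obs.hom_in_monoallelic = True
                    out.append(obs)
                else:  # X-linked requirements
                    out.append(obs)
    out.sort(key=lambda o: (o.key.chrom, o.key.pos, o.key.ref, o.key.alt))
    return out


def prefilter(
    observation: VariantObservation,
    config: Config,
    indel_family_counts: Mapping[VariantKey, int],
) -> Optional[DropReason]:
    """Apply the cohort elimination rules; None means the observation is kept.

    Drop precedence: LOW_GQ, INTERNAL_MAF, RECURRENT_INDEL,
    SINGLETON_DOUBLE_HET. For compound-het pairs each check considers the
    worse member.
    """
    members = [observation]
    if observation.partner is not None:
        members.append(observation.partner)

    if min(m.child_call.gq for m in members) < config.min_gq:
        return DropReason.LOW_GQ

    threshold = (
        config.internal_maf_biallelic
        if observation.requirement is AllelicRequirement.BIALLELIC
        else config.internal_maf_mono
    )
    if max(m.internal_maf for m in members) > threshold:
        return DropReason.INTERNAL_MAF

    for m in members:
        if m.key.is_indel and indel_family_counts.get(m.key, 0) > config.recurrent_indel_families:
            return DropReason.RECURRENT_INDEL

    if (
        observation.genotype_class is GenotypeClass.COMPOUND_HET_PAIR
        and observation.is_singleton
    ):
        return DropReason.SINGLETON_DOUBLE_HET
    return None
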
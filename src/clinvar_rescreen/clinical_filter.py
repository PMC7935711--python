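"""Rule engine reproducing the automated clinical variant filter.

Each observation that survives the cohort prefilter is adjudicated against
thirteen exclusion rules covering variant quality, population frequency,
predicted consequence, and genotype/inheritance consistency with the family
history and the gene's allelic requirement. An observation with no triggered
rule would have been reported by the standard pipeline; otherwise it is
excluded, carrying every triggered reason with the first (fixed precedence
order) as primary. Parental-mosaicism evidence is computed for all inherited
observations: a transmitting parent with allele fraction below 0.4 while the
child's exceeds 0.4 suggests the parent is mosaic rather than a constitutive
heterozygote.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

from .clinvar_catalog import PanelEntry
from .cohort_match import GenotypeClass, Inheritance, VariantObservation, is_x
from .config import Config
from .io_formats import (
    NONCODING_CONSEQUENCES,
    AllelicRequirement,
    AnnotationRecord,
    MissensePrediction,
    Sex,
)


class ExclusionReason(str, Enum):
    """The thirteen exclusion classes, in precedence (reason-table row) order."""

    DENOVO_LOW_QUALITY = "DENOVO_LOW_QUALITY"
    INHERITED_UNAFFECTED_PARENT = "INHERITED_UNAFFECTED_PARENT"
    POP_ALLELE_COUNT_GT5 = "POP_ALLELE_COUNT_GT5"
    MAF_INHERITANCE_UNKNOWN = "MAF_INHERITANCE_UNKNOWN"
    MALE_X_HET = "MALE_X_HET"
    FEMALE_HET_HEMIZYGOUS_GENE = "FEMALE_HET_HEMIZYGOUS_GENE"
    XL_OVERDOMINANCE_INHERITED = "XL_OVERDOMINANCE_INHERITED"
    UNIPARENTAL_HOMOZYGOUS = "UNIPARENTAL_HOMOZYGOUS"
    MISSENSE_PREDICTED_BENIGN = "MISSENSE_PREDICTED_BENIGN"
    NONCODING_CONSEQUENCE = "NONCODING_CONSEQUENCE"
    IMPRINTED_NOT_INHERITED = "IMPRINTED_NOT_INHERITED"
    MOSAIC_MECHANISM_NOT_DENOVO = "MOSAIC_MECHANISM_NOT_DENOVO"
    COMPOUND_HET_PARTNER_FAILED = "COMPOUND_HET_PARTNER_FAILED"


class Status(str, Enum):
    REPORTED_STANDARD = "REPORTED_STANDARD"
    EXCLUDED = "EXCLUDED"


def denovo_quality_ok(observation: VariantObservation, config: Config | None = None) -> bool:
    """Programmatic depth/allele-balance proxy for visual de novo validation.

    Requires child depth at the site, child allele fraction in the het band
    (or near 1 for hom/hemi calls), and at most a single alternate read in
    either parent.
    """
    config = config or Config()
    call = observation.child_call
    if call.dp < config.denovo_min_depth:
        return False
    vaf = call.vaf
    if vaf is None:
        return False
    if observation.genotype_class is GenotypeClass.HET:
        lo, hi = config.denovo_ab
        if not lo <= vaf <= hi:
            return False
    else:
        if vaf < config.denovo_ab_hom:
            return False
    for parent_call in (observation.mother_call, observation.father_call):
        if parent_call is not None and parent_call.ad_alt > config.denovo_parent_alt_max:
            return False
    return True


def parental_mosaicism_evidence(observation: VariantObservation) -> bool:
    """Depressed transmitting-parent VAF (<0.4) with normal child VAF (>0.4)."""
    if observation.inheritance not in (Inheritance.MATERNAL, Inheritance.PATERNAL):
        return False
    parent_call = observation.transmitting_call()
    child_vaf = observation.child_call.vaf
    if parent_call is None or parent_call.vaf is None or child_vaf is None:
        return False
    return parent_call.vaf < 0.4 and child_vaf > 0.4


def _parent_unaffected(observation: VariantObservation) -> bool:
    parent = observation.transmitting_parent()
    if parent is None:
        return False
    return not parent.affected and not bool(parent.similar_phenotype_to_child)


def _confirmed_de_novo(observation: VariantObservation, config: Config) -> bool:
    return observation.inheritance is Inheritance.DE_NOVO and denovo_quality_ok(
        observation, config
    )


# --- individual rule predicates (evaluated on single observations) ---------


def _rule_denovo_low_quality(obs, entry, ann, config) -> bool:
    return obs.inheritance is Inheritance.DE_NOVO and not denovo_quality_ok(obs, config)


def _rule_inherited_unaffected(obs, entry, ann, config) -> bool:
    return (
        obs.genotype_class is GenotypeClass.HET
        and obs.requirement is AllelicRequirement.MONOALLELIC
        and not is_x(obs.key.chrom)
        and obs.inheritance in (Inheritance.MATERNAL, Inheritance.PATERNAL)
        and _parent_unaffected(obs)
    )


def _rule_pop_allele_count(obs, entry, ann, config) -> bool:
    return ann.population_allele_count > config.pop_allele_count_max


def _rule_maf_unknown_inheritance(obs, entry, ann, config) -> bool:
    return (
        obs.requirement is AllelicRequirement.MONOALLELIC
        and obs.inheritance is Inheritance.UNKNOWN
        and ann.population_maf > config.pop_maf_unknown_inheritance
    )


def _rule_male_x_het(obs, entry, ann, config) -> bool:
    return obs.male_x_het


def _rule_female_het_hemizygous(obs, entry, ann, config) -> bool:
    return (
        obs.proband.sex is Sex.FEMALE
        and obs.genotype_class is GenotypeClass.HET
        and obs.requirement is AllelicRequirement.HEMIZYGOUS
        and not _confirmed_de_novo(obs, config)
    )


def _rule_xl_overdominance(obs, entry, ann, config) -> bool:
    return obs.requirement is AllelicRequirement.X_LINKED_OVERDOMINANT and (
        obs.inheritance in (Inheritance.MATERNAL, Inheritance.PATERNAL)
    )


def _rule_uniparental_homozygous(obs, entry, ann, config) -> bool:
    if (
        obs.genotype_class is not GenotypeClass.HOM
        or obs.requirement is not AllelicRequirement.BIALLELIC
        or obs.mother_call is None
        or obs.father_call is None
    ):
        return False
    carriers = sum(
        1 for c in (obs.mother_call, obs.father_call) if c.carries_alt
    )
    return carriers == 1


def _rule_missense_benign(obs, entry, ann, config) -> bool:
    if ann.consequence != "missense_variant":
        return False
    if ann.missense_predictor is not MissensePrediction.BENIGN:
        return False
    if obs.inheritance is Inheritance.UNKNOWN:
        return True
    return obs.inheritance in (
        Inheritance.MATERNAL,
        Inheritance.PATERNAL,
    ) and _parent_unaffected(obs)


def _rule_noncoding(obs, entry, ann, config) -> bool:
    return ann.consequence in NONCODING_CONSEQUENCES


def _rule_imprinted(obs, entry, ann, config) -> bool:
    return entry.imprinted and obs.inheritance in (
        Inheritance.DE_NOVO,
        Inheritance.UNKNOWN,
    )


def _rule_mosaic_mechanism(obs, entry, ann, config) -> bool:
    return entry.mosaic and obs.inheritance is not Inheritance.DE_NOVO


_SINGLE_RULES: list[tuple[ExclusionReason, callable]] = [
    (ExclusionReason.DENOVO_LOW_QUALITY, _rule_denovo_low_quality),
    (ExclusionReason.INHERITED_UNAFFECTED_PARENT, _rule_inherited_unaffected),
    (ExclusionReason.POP_ALLELE_COUNT_GT5, _rule_pop_allele_count),
    (ExclusionReason.MAF_INHERITANCE_UNKNOWN, _rule_maf_unknown_inheritance),
    (ExclusionReason.MALE_X_HET, _rule_male_x_het),
    (ExclusionReason.FEMALE_HET_HEMIZYGOUS_GENE, _rule_female_het_hemizygous),
    (ExclusionReason.XL_OVERDOMINANCE_INHERITED, _rule_xl_overdominance),
    (ExclusionReason.UNIPARENTAL_HOMOZYGOUS, _rule_uniparental_homozygous),
    (ExclusionReason.MISSENSE_PREDICTED_BENIGN, _rule_missense_benign),
    (ExclusionReason.NONCODING_CONSEQUENCE, _rule_noncoding),
    (ExclusionReason.IMPRINTED_NOT_INHERITED, _rule_imprinted),
    (ExclusionReason.MOSAIC_MECHANISM_NOT_DENOVO, _rule_mosaic_mechanism),
]


@dataclass
class FilterDecision:
    observation: VariantObservation
    status: Status
    primary_reason: Optional[ExclusionReason]
    all_reasons: list[ExclusionReason]
    parental_mosaicism: bool

    def __post_init__(self) -> None:
        if (self.status is Status.EXCLUDED) != (self.primary_reason is not None):
            raise ValueError("primary_reason is defined iff status is EXCLUDED")
        if self.all_reasons and self.primary_reason is not self.all_reasons[0]:
            raise ValueError("primary_reason must be the first triggered reason")


def _single_reasons(
    obs: VariantObservation,
    entry: PanelEntry,
    annotation: AnnotationRecord,
    config: Config,
) -> list[ExclusionReason]:
    reasons = []
    for reason, predicate in _SINGLE_RULES:
        if not config.rule_enabled(reason.value):
            continue
        if predicate(obs, entry, annotation, config):
            reasons.append(reason)
    return reasons


def apply_standard_filter(
    observation: VariantObservation,
    panel_entry: PanelEntry,
    annotation: AnnotationRecord | None,
    config: Config | None = None,
) -> FilterDecision:
    """Adjudicate one prefiltered observation against the standard filter.

    Rules are evaluated in precedence order; all triggered reasons are kept
    and the first is primary. For compound-het pairs the single-variant rules
    run on each member: the pair inherits the primary member's own reasons,
    and a clean primary member with a failing partner yields the
    partner-failed reason. The annotation is mandatory - an observation
    without one cannot be adjudicated.
    """
    config = config or Config()
    if annotation is None:
        raise ValueError(f"annotation missing for {observation.key}; cannot adjudicate")

    reasons = _single_reasons(observation, panel_entry, annotation, config)
    if observation.partner is not None:
        partner = observation.partner
        if partner.annotation is None:
            raise ValueError(
                f"annotation missing for compound-het partner {partner.key}"
            )
        partner_reasons = _single_reasons(
            partner, panel_entry, partner.annotation, config
        )
        if partner_reasons and config.rule_enabled(
            ExclusionReason.COMPOUND_HET_PARTNER_FAILED.value
        ):
            reasons.append(ExclusionReason.COMPOUND_HET_PARTNER_FAILED)

    status = Status.EXCLUDED if reasons else Status.REPORTED_STANDARD
    mosaic = parental_mosaicism_evidence(observation)
    return FilterDecision(
        observation=observation,
        status=status,
        primary_reason=reasons[0] if reasons else None,
        all_reasons=reasons,
        parental_mosaicism=mosaic,
    )
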
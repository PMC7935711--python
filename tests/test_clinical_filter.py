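"""Rule-engine behaviour, including equivalence with an independently coded
set of standalone rule predicates over randomized observations."""

import random

import pytest

from clinvar_rescreen.clinical_filter import (
    ExclusionReason,
    Status,
    apply_standard_filter,
    denovo_quality_ok,
    parental_mosaicism_evidence,
)
from clinvar_rescreen.clinvar_catalog import PanelEntry
from clinvar_rescreen.cohort_match import GenotypeClass, Inheritance
from clinvar_rescreen.config import Config, profile_config
from clinvar_rescreen.io_formats import (
    GT,
    AllelicRequirement,
    AnnotationRecord,
    GenotypeCall,
    MissensePrediction,
    Sex,
)

from conftest import make_annotation, make_call, make_observation


def entry_for(obs, imprinted=False, mosaic=False):
    return PanelEntry(obs.gene, obs.requirement, "lof", imprinted, mosaic, "confirmed")


def adjudicate(obs, annotation=None, imprinted=False, mosaic=False, config=None):
    annotation = annotation or make_annotation(obs.key)
    if obs.partner is not None and obs.partner.annotation is None:
        obs.partner.annotation = make_annotation(obs.partner.key)
    return apply_standard_filter(obs, entry_for(obs, imprinted, mosaic), annotation,
                                 config or Config())


class TestDenovoQuality:
    def test_clean_de_novo_passes(self):
        obs = make_observation()
        assert denovo_quality_ok(obs)

    def test_low_depth_fails(self):
        obs = make_observation(child_call=make_call(GT.HET, dp=6))
        assert not denovo_quality_ok(obs)

    def test_skewed_allele_balance_fails(self):
        obs = make_observation(child_call=GenotypeCall(GT.HET, 99, 50, 44, 6))  # vaf 0.12
        assert not denovo_quality_ok(obs)

    def test_parental_alt_reads_fail(self):
        obs = make_observation(mother_call=GenotypeCall(GT.HOM_REF, 99, 40, 37, 3))
        assert not denovo_quality_ok(obs)

    def test_hom_band(self):
        obs = make_observation(genotype_class=GenotypeClass.HOM,
                               child_call=GenotypeCall(GT.HOM_ALT, 99, 40, 2, 38))
        assert denovo_quality_ok(obs)
        obs = make_observation(genotype_class=GenotypeClass.HOM,
                               child_call=GenotypeCall(GT.HOM_ALT, 99, 40, 16, 24))
        assert not denovo_quality_ok(obs)


class TestParentalMosaicism:
    @pytest.mark.parametrize(
        "parent_vaf,child_vaf,expected",
        [
            ((17, 3), (13, 12), True),    # 0.15 vs 0.48
            ((20, 20), (20, 20), False),  # both exactly at the bound
            ((22, 14), (24, 16), False),  # 0.39 parent but child exactly 0.40
        ],
    )
    def test_bounds_are_strict(self, parent_vaf, child_vaf, expected):
        pr, pa = parent_vaf
        cr, ca = child_vaf
        obs = make_observation(
            inheritance=Inheritance.MATERNAL,
            mother_call=GenotypeCall(GT.HET, 99, pr + pa, pr, pa),
            child_call=GenotypeCall(GT.HET, 99, cr + ca, cr, ca),
        )
        assert parental_mosaicism_evidence(obs) is expected

    def test_undefined_vaf_is_no_evidence(self):
        obs = make_observation(
            inheritance=Inheritance.MATERNAL,
            mother_call=GenotypeCall(GT.HET, 99, 0, 0, 0),
        )
        assert not parental_mosaicism_evidence(obs)

    def test_not_computed_for_de_novo(self):
        assert not parental_mosaicism_evidence(make_observation())


class TestStandardFilterExamples:
    def test_inherited_from_unaffected_parent_excluded(self):
        obs = make_observation(inheritance=Inheritance.PATERNAL)
        decision = adjudicate(obs, make_annotation(obs.key, "missense_variant"))
        assert decision.status is Status.EXCLUDED
        assert decision.primary_reason is ExclusionReason.INHERITED_UNAFFECTED_PARENT

    def test_clean_de_novo_stop_gain_reported(self):
        decision = adjudicate(make_observation())
        assert decision.status is Status.REPORTED_STANDARD
        assert decision.primary_reason is None and decision.all_reasons == []

    def test_synonymous_de_novo_excluded_as_noncoding(self):
        obs = make_observation()
        decision = adjudicate(obs, make_annotation(obs.key, "synonymous_variant"))
        assert decision.primary_reason is ExclusionReason.NONCODING_CONSEQUENCE

    def test_rare_maf_threshold_for_unknown_inheritance(self):
        obs = make_observation(singleton=True, inheritance=Inheritance.UNKNOWN)
        excluded = adjudicate(obs, make_annotation(obs.key, maf=0.0002))
        assert excluded.primary_reason is ExclusionReason.MAF_INHERITANCE_UNKNOWN
        kept = adjudicate(obs, make_annotation(obs.key, maf=0.0001))
        assert kept.status is Status.REPORTED_STANDARD

    def test_imprinted_de_novo_excluded_despite_quality(self):
        obs = make_observation()
        assert denovo_quality_ok(obs)
        decision = adjudicate(obs, imprinted=True)
        assert decision.primary_reason is ExclusionReason.IMPRINTED_NOT_INHERITED

    def test_benign_missense_not_excluded_when_de_novo(self):
        obs = make_observation()
        ann = make_annotation(obs.key, "missense_variant", MissensePrediction.BENIGN)
        assert adjudicate(obs, ann).status is Status.REPORTED_STANDARD
        singleton = make_observation(singleton=True, inheritance=Inheritance.UNKNOWN)
        ann = make_annotation(singleton.key, "missense_variant", MissensePrediction.BENIGN)
        decision = adjudicate(singleton, ann)
        assert decision.primary_reason is ExclusionReason.MISSENSE_PREDICTED_BENIGN

    def test_female_het_hemizygous_gene_needs_confirmed_de_novo(self):
        inherited = make_observation(chrom="X", requirement=AllelicRequirement.HEMIZYGOUS,
                                     inheritance=Inheritance.MATERNAL)
        assert adjudicate(inherited).primary_reason is (
            ExclusionReason.FEMALE_HET_HEMIZYGOUS_GENE
        )
        confirmed = make_observation(chrom="X", requirement=AllelicRequirement.HEMIZYGOUS)
        assert adjudicate(confirmed).status is Status.REPORTED_STANDARD
        unconfirmed = make_observation(chrom="X", requirement=AllelicRequirement.HEMIZYGOUS,
                                       child_call=make_call(GT.HET, dp=6))
        assert ExclusionReason.FEMALE_HET_HEMIZYGOUS_GENE in adjudicate(unconfirmed).all_reasons

    def test_uniparental_homozygous(self):
        obs = make_observation(requirement=AllelicRequirement.BIALLELIC,
                               genotype_class=GenotypeClass.HOM,
                               inheritance=Inheritance.MATERNAL,
                               mother_call=make_call(GT.HET),
                               father_call=make_call(GT.HOM_REF))
        assert adjudicate(obs).primary_reason is ExclusionReason.UNIPARENTAL_HOMOZYGOUS
        both = make_observation(requirement=AllelicRequirement.BIALLELIC,
                                genotype_class=GenotypeClass.HOM,
                                inheritance=Inheritance.BIPARENTAL,
                                mother_call=make_call(GT.HET),
                                father_call=make_call(GT.HET))
        assert adjudicate(both).status is Status.REPORTED_STANDARD

    def test_compound_het_partner_failure_propagates(self):
        partner = make_observation(pos=2000, inheritance=Inheritance.PATERNAL,
                                   requirement=AllelicRequirement.BIALLELIC,
                                   parent_affected=False)
        partner.annotation = make_annotation(partner.key, "synonymous_variant")
        pair = make_observation(inheritance=Inheritance.MATERNAL,
                                requirement=AllelicRequirement.BIALLELIC,
                                genotype_class=GenotypeClass.COMPOUND_HET_PAIR,
                                partner=partner)
        decision = adjudicate(pair)
        assert decision.primary_reason is ExclusionReason.COMPOUND_HET_PARTNER_FAILED

    def test_missing_annotation_is_an_error(self):
        with pytest.raises(ValueError, match="annotation missing"):
            apply_standard_filter(make_observation(), entry_for(make_observation()),
                                  None, Config())

    def test_precedence_is_rule_order(self):
        # triggers both the population-count rule (3) and noncoding rule (10)
        obs = make_observation()
        ann = make_annotation(obs.key, "synonymous_variant", ac=10)
        decision = adjudicate(obs, ann)
        assert decision.all_reasons == [
            ExclusionReason.POP_ALLELE_COUNT_GT5,
            ExclusionReason.NONCODING_CONSEQUENCE,
        ]
        assert decision.primary_reason is ExclusionReason.POP_ALLELE_COUNT_GT5

    def test_revised_profile_disables_two_rules(self):
        imprinted_dn = make_observation()
        assert adjudicate(imprinted_dn, imprinted=True,
                          config=profile_config("revised")).status is Status.REPORTED_STANDARD
        xlod = make_observation(chrom="X",
                                requirement=AllelicRequirement.X_LINKED_OVERDOMINANT,
                                inheritance=Inheritance.PATERNAL)
        assert adjudicate(xlod, config=profile_config("revised")).status is (
            Status.REPORTED_STANDARD
        )
        assert adjudicate(xlod).primary_reason is ExclusionReason.XL_OVERDOMINANCE_INHERITED


class TestMonotonicity:
    def test_raising_allele_count_never_unexcludes(self):
        rng = random.Random(0)
        for _ in range(50):
            obs = random_observation(rng)
            low = adjudicate_random(obs, ac=0)
            high = adjudicate_random(obs, ac=100)
            if low.status is Status.EXCLUDED:
                assert high.status is Status.EXCLUDED

    def test_lowering_depth_never_unexcludes_de_novo(self):
        obs = make_observation()
        good = adjudicate(obs)
        bad = adjudicate(make_observation(child_call=make_call(GT.HET, dp=5)))
        assert good.status is Status.REPORTED_STANDARD
        assert bad.status is Status.EXCLUDED


def adjudicate_random(obs, ac):
    ann = AnnotationRecord(obs.key, "stop_gained", MissensePrediction.NOT_APPLICABLE,
                           0.0, ac)
    if obs.partner is not None and obs.partner.annotation is None:
        obs.partner.annotation = make_annotation(obs.partner.key)
    return apply_standard_filter(obs, entry_for(obs), ann, Config())


# ---------------------------------------------------------------------------
# randomized equivalence with standalone predicates

CONSEQUENCES = [
    "stop_gained", "missense_variant", "frameshift_variant", "splice_donor_variant",
    "synonymous_variant", "intron_variant", "splice_region_variant",
    "5_prime_UTR_variant", "3_prime_UTR_variant",
]
NONCODING = {"splice_region_variant", "5_prime_UTR_variant", "3_prime_UTR_variant",
             "intron_variant", "synonymous_variant"}


def random_observation(rng: random.Random):
    requirement = rng.choice(list(AllelicRequirement))
    x_linked = requirement in (AllelicRequirement.HEMIZYGOUS,
                               AllelicRequirement.X_LINKED_OVERDOMINANT)
    chrom = "X" if x_linked or rng.random() < 0.2 else str(rng.randint(1, 22))
    sex = rng.choice([Sex.MALE, Sex.FEMALE])
    singleton = rng.random() < 0.3
    if singleton:
        inheritance = Inheritance.UNKNOWN
    else:
        inheritance = rng.choice(list(Inheritance))
    if requirement is AllelicRequirement.BIALLELIC and rng.random() < 0.5:
        genotype_class = GenotypeClass.HOM
    elif sex is Sex.MALE and chrom == "X" and rng.random() < 0.5:
        genotype_class = GenotypeClass.HEMI
    else:
        genotype_class = GenotypeClass.HET
    dp = rng.choice([5, 8, 12, 40, 80])
    ad_alt = rng.randint(0, dp)
    child_call = GenotypeCall(
        {GenotypeClass.HET: GT.HET, GenotypeClass.HOM: GT.HOM_ALT,
         GenotypeClass.HEMI: GT.HEMI_ALT}[genotype_class],
        rng.choice([35, 99]), dp, dp - ad_alt, ad_alt,
    )

    def parent_call(carrier):
        pdp = rng.choice([6, 40])
        pad = rng.randint(1, pdp) if carrier else rng.choice([0, 0, 0, 1, 2, 3])
        return GenotypeCall(GT.HET if carrier else GT.HOM_REF,
                            rng.choice([10, 99]), pdp, pdp - pad, pad)

    mother_call = father_call = None
    if not singleton:
        mother_call = parent_call(inheritance in (Inheritance.MATERNAL,
                                                  Inheritance.BIPARENTAL))
        father_call = parent_call(inheritance in (Inheritance.PATERNAL,
                                                  Inheritance.BIPARENTAL))
    obs = make_observation(
        chrom=chrom,
        pos=rng.randint(1000, 999999),
        requirement=requirement,
        genotype_class=genotype_class,
        inheritance=inheritance,
        sex=sex,
        child_call=child_call,
        mother_call=mother_call,
        father_call=father_call,
        singleton=singleton,
        parent_affected=rng.random() < 0.2,
        parent_similar=rng.random() < 0.2,
        male_x_het=(sex is Sex.MALE and chrom == "X"
                    and genotype_class is GenotypeClass.HET),
        stars=rng.randint(1, 3),
    )
    return obs


def random_annotation(rng: random.Random, key):
    consequence = rng.choice(CONSEQUENCES)
    predictor = (
        rng.choice([MissensePrediction.BENIGN, MissensePrediction.POSSIBLY_DAMAGING,
                    MissensePrediction.PROBABLY_DAMAGING])
        if consequence == "missense_variant"
        else MissensePrediction.NOT_APPLICABLE
    )
    return AnnotationRecord(key, consequence, predictor,
                            rng.choice([0.0, 0.00005, 0.0002, 0.01]),
                            rng.choice([0, 1, 5, 6, 50]))


def independent_reasons(obs, ann, imprinted, mosaic):
    """Standalone restatement of each exclusion rule, conjunction-checked."""
    cfg = Config()
    reasons = []
    vaf = obs.child_call.vaf

    def quality():
        if obs.child_call.dp < 10 or vaf is None:
            return False
        if obs.genotype_class is GenotypeClass.HET and not (0.3 <= vaf <= 0.7):
            return False
        if obs.genotype_class is not GenotypeClass.HET and vaf < 0.85:
            return False
        for pc in (obs.mother_call, obs.father_call):
            if pc is not None and pc.ad_alt > 1:
                return False
        return True

    def from_unaffected_parent():
        parent = obs.mother if obs.inheritance is Inheritance.MATERNAL else (
            obs.father if obs.inheritance is Inheritance.PATERNAL else None)
        return (parent is not None and not parent.affected
                and not parent.similar_phenotype_to_child)

    if obs.inheritance is Inheritance.DE_NOVO and not quality():
        reasons.append("DENOVO_LOW_QUALITY")
    if (obs.genotype_class is GenotypeClass.HET
            and obs.requirement is AllelicRequirement.MONOALLELIC
            and obs.key.chrom != "X"
            and obs.inheritance in (Inheritance.MATERNAL, Inheritance.PATERNAL)
            and from_unaffected_parent()):
        reasons.append("INHERITED_UNAFFECTED_PARENT")
    if ann.population_allele_count > 5:
        reasons.append("POP_ALLELE_COUNT_GT5")
    if (obs.requirement is AllelicRequirement.MONOALLELIC
            and obs.inheritance is Inheritance.UNKNOWN
            and ann.population_maf > 0.0001):
        reasons.append("MAF_INHERITANCE_UNKNOWN")
    if obs.male_x_het:
        reasons.append("MALE_X_HET")
    if (obs.proband.sex is Sex.FEMALE
            and obs.genotype_class is GenotypeClass.HET
            and obs.requirement is AllelicRequirement.HEMIZYGOUS
            and not (obs.inheritance is Inheritance.DE_NOVO and quality())):
        reasons.append("FEMALE_HET_HEMIZYGOUS_GENE")
    if (obs.requirement is AllelicRequirement.X_LINKED_OVERDOMINANT
            and obs.inheritance in (Inheritance.MATERNAL, Inheritance.PATERNAL)):
        reasons.append("XL_OVERDOMINANCE_INHERITED")
    if (obs.genotype_class is GenotypeClass.HOM
            and obs.requirement is AllelicRequirement.BIALLELIC
            and obs.mother_call is not None and obs.father_call is not None
            and sum(c.gt in (GT.HET, GT.HOM_ALT, GT.HEMI_ALT)
                    for c in (obs.mother_call, obs.father_call)) == 1):
        reasons.append("UNIPARENTAL_HOMOZYGOUS")
    if (ann.consequence == "missense_variant"
            and ann.missense_predictor is MissensePrediction.BENIGN
            and (obs.inheritance is Inheritance.UNKNOWN
                 or (obs.inheritance in (Inheritance.MATERNAL, Inheritance.PATERNAL)
                     and from_unaffected_parent()))):
        reasons.append("MISSENSE_PREDICTED_BENIGN")
    if ann.consequence in NONCODING:
        reasons.append("NONCODING_CONSEQUENCE")
    if imprinted and obs.inheritance in (Inheritance.DE_NOVO, Inheritance.UNKNOWN):
        reasons.append("IMPRINTED_NOT_INHERITED")
    if mosaic and obs.inheritance is not Inheritance.DE_NOVO:
        reasons.append("MOSAIC_MECHANISM_NOT_DENOVO")
    return reasons


def test_rule_engine_matches_independent_predicates_on_randomized_observations():
    rng = random.Random(20240901)
    n = 10_000
    for i in range(n):
        obs = random_observation(rng)
        ann = random_annotation(rng, obs.key)
        imprinted = rng.random() < 0.1
        mosaic = rng.random() < 0.1
        entry = PanelEntry(obs.gene, obs.requirement, "lof", imprinted, mosaic,
                           "confirmed")
        decision = apply_standard_filter(obs, entry, ann, Config())
        expected = independent_reasons(obs, ann, imprinted, mosaic)
        got = [r.value for r in decision.all_reasons]
        assert got == expected, f"case {i}: {got} != {expected}"
        assert (decision.status is Status.EXCLUDED) == bool(expected)
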
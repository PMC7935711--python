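import pytest

from clinvar_rescreen.cohort_match import (
    GenotypeClass,
    Inheritance,
    VariantObservation,
)
from clinvar_rescreen.io_formats import (
    GT,
    AllelicRequirement,
    AnnotationRecord,
    GenotypeCall,
    Individual,
    MissensePrediction,
    Role,
    Sex,
    VariantKey,
)


def make_call(gt=GT.HET, gq=99, dp=40, ad_alt=None):
    if ad_alt is None:
        ad_alt = {GT.HOM_REF: 0, GT.HET: dp // 2, GT.HOM_ALT: dp, GT.HEMI_ALT: dp,
                  GT.MISSING: 0}[gt]
    return GenotypeCall(gt, gq, dp, dp - ad_alt, ad_alt)


def make_individual(id="P1", family="F1", sex=Sex.FEMALE, role=Role.PROBAND,
                    affected=None, similar=None):
    if affected is None:
        affected = role is Role.PROBAND
    if role is Role.PROBAND:
        similar = None
    elif similar is None:
        similar = False
    return Individual(id, family, sex, role, affected, similar)


def make_annotation(key, consequence="stop_gained", predictor=None, maf=0.0, ac=0):
    if predictor is None:
        predictor = (
            MissensePrediction.PROBABLY_DAMAGING
            if consequence == "missense_variant"
            else MissensePrediction.NOT_APPLICABLE
        )
    return AnnotationRecord(key, consequence, predictor, maf, ac)


def make_observation(
    chrom="1",
    pos=1000,
    requirement=AllelicRequirement.MONOALLELIC,
    genotype_class=GenotypeClass.HET,
    inheritance=Inheritance.DE_NOVO,
    sex=Sex.FEMALE,
    child_call=None,
    mother_call=None,
    father_call=None,
    singleton=False,
    parent_affected=False,
    parent_similar=False,
    male_x_het=False,
    stars=1,
    partner=None,
    gene="GENE1",
):
    key = VariantKey(chrom, pos, "A", "G")
    child_gt = {GenotypeClass.HET: GT.HET, GenotypeClass.HOM: GT.HOM_ALT,
                GenotypeClass.HEMI: GT.HEMI_ALT,
                GenotypeClass.COMPOUND_HET_PAIR: GT.HET}[genotype_class]
    if child_call is None:
        child_call = make_call(child_gt)
    proband = make_individual("P1", "F1", sex=sex)
    mother = father = None
    if not singleton:
        mother = make_individual("M1", "F1", sex=Sex.FEMALE, role=Role.MOTHER,
                                 affected=parent_affected, similar=parent_similar)
        father = make_individual("D1", "F1", sex=Sex.MALE, role=Role.FATHER,
                                 affected=parent_affected, similar=parent_similar)
        if mother_call is None:
            mother_call = make_call(
                GT.HET if inheritance in (Inheritance.MATERNAL, Inheritance.BIPARENTAL)
                else GT.HOM_REF
            )
        if father_call is None:
            father_call = make_call(
                GT.HET if inheritance in (Inheritance.PATERNAL, Inheritance.BIPARENTAL)
                else GT.HOM_REF
            )
    return VariantObservation(
        proband=proband,
        key=key,
        gene=gene,
        requirement=requirement,
        genotype_class=genotype_class,
        child_call=child_call,
        mother=mother,
        father=father,
        mother_call=mother_call,
        father_call=father_call,
        inheritance=inheritance,
        male_x_het=male_x_het,
        stars=stars,
        partner=partner,
    )


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """Noise-free synthetic cohort shared by pipeline-level tests."""
    from clinvar_rescreen.synthetic_cohort import SimulationConfig, simulate

    out = tmp_path_factory.mktemp("cohort")
    config = SimulationConfig(n_trios=60, n_singletons=15, seed=11, sequencing_noise=False)
    cohort = simulate(config, out)
    return cohort
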
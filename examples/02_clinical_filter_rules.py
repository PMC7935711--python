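"""Adjudicate single observations against the clinical rule engine.

Shows how the rule engine treats (1) a heterozygous variant in a dominant
gene transmitted by an unaffected parent - the most common reason a
known-pathogenic variant is excluded - and (2) the same transmission with a
depressed parental allele fraction, which flags possible parental mosaicism
(parent VAF < 0.4 while the child's is > 0.4).
"""

from clinvar_rescreen import (
    AnnotationRecord,
    GenotypeCall,
    Individual,
    PanelEntry,
    VariantKey,
    apply_standard_filter,
)
from clinvar_rescreen.cohort_match import GenotypeClass, Inheritance, VariantObservation
from clinvar_rescreen.io_formats import GT, AllelicRequirement, MissensePrediction, Role, Sex

key = VariantKey("2", 166_848_646, "C", "T")
entry = PanelEntry("SCN1A_LIKE", AllelicRequirement.MONOALLELIC,
                   "altered gene product structure", False, False, "confirmed")
annotation = AnnotationRecord(key, "missense_variant",
                              MissensePrediction.PROBABLY_DAMAGING, 0.0, 0)

proband = Individual("child", "FAM1", Sex.FEMALE, Role.PROBAND, affected=True)
father = Individual("father", "FAM1", Sex.MALE, Role.FATHER, affected=False,
                    similar_phenotype_to_child=False)
mother = Individual("mother", "FAM1", Sex.FEMALE, Role.MOTHER, affected=False,
                    similar_phenotype_to_child=False)


def observe(father_call: GenotypeCall) -> VariantObservation:
    return VariantObservation(
        proband=proband, key=key, gene=entry.gene, requirement=entry.requirement,
        genotype_class=GenotypeClass.HET,
        child_call=GenotypeCall(GT.HET, 99, 42, 20, 22),      # child VAF 0.52
        mother=mother, father=father,
        mother_call=GenotypeCall(GT.HOM_REF, 99, 38, 38, 0),
        father_call=father_call,
        inheritance=Inheritance.PATERNAL,
    )


constitutive = observe(GenotypeCall(GT.HET, 99, 40, 21, 19))  # father VAF 0.48
mosaic_like = observe(GenotypeCall(GT.HET, 99, 40, 33, 7))    # father VAF 0.18

for label, obs in [("constitutive father", constitutive), ("mosaic-like father", mosaic_like)]:
    decision = apply_standard_filter(obs, entry, annotation)
    print(f"{label}:")
    print(f"  status          {decision.status.value}")
    print(f"  primary reason  {decision.primary_reason.value}")
    print(f"  parental mosaicism evidence: {decision.parental_mosaicism}")
    print()

print("Both observations are excluded as inherited from an apparently unaffected")
print("parent, but the second carries mosaicism evidence: the transmitting parent")
print("shows the variant in only 18% of reads, so the 'unaffected carrier parent'")
print("argument against pathogenicity is weak and the variant deserves review.")
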
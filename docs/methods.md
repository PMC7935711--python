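# Methods

## Problem and model

The package models a catalog reanalysis of diagnostic exome data. Three data
sources meet: a catalog of clinically asserted variants (ClinVar-style), a
curated gene–disease panel with per-gene allelic requirements (DDG2P-style),
and cohort genotypes for affected probands sequenced as parent–offspring
trios or as singletons. The question answered is not "which variants are
pathogenic" but "which variants *already asserted* pathogenic would a
standard automated clinical filter exclude, and why" — an audit of the
filter's false negatives.

The unit of accounting is the **observation**: one catalog variant detected
in one proband with requirement-appropriate zygosity. A variant seen in two
probands counts twice; a compound-heterozygous pair is one observation
carrying both variant keys. Every stage is count-conserving
(matched = dropped + adjudicated; adjudicated = reported + excluded), which
the run manifest asserts on every run.

## Variant identity

Catalog and cohort coordinates are joined on the normalized
(chromosome, position, ref, alt) key: 1-based VCF convention, `chr` prefixes
stripped, multi-allelic sites decomposed (per-allele depths remapped, other
alternate alleles treated as reference for the projected key), shared
prefix/suffix bases trimmed, and indels left-aligned through repeat context
when a reference context is available. Allele-level identity is the only
join; rsIDs and catalog accession numbers are carried but never matched on.
When no reference context is supplied, normalization trims but does not
shift; the synthetic generator always writes keys in already-normalized form
so catalog and cohort agree by construction.

## Eligibility, matching and inheritance

Catalog eligibility (germline origin, GRCh37, P/LP without conflict markers,
≥ 1 gold star, panel gene with confirmed/probable confidence) is evaluated
per raw submission row; duplicates of one variant keep the max-star record.
Both the raw-eligible count and the deduplicated count are reported, since
published catalog tallies rarely state which was used. "Germline" matches
any multi-valued origin field containing the word; P vs LP duplicates are
treated as concordant (both satisfy the P/LP criterion), so the
contradictory-duplicate error path cannot fire for the accepted vocabulary
and exists as a guard.

Zygosity matching per requirement:

* monoallelic (including imprinted- or mosaic-mechanism genes):
  heterozygous; homozygous-alt also matches (a dominant allele is no less
  present when homozygous) and is flagged for review;
* biallelic: homozygous-alt, or two distinct heterozygous catalog variants
  in the same gene — in trios the pair must be *trans* (one maternal, one
  paternal); singleton pairs are matched and then dropped as unphaseable;
* X-linked (hemizygous/X-linked-dominant, and X-linked-overdominant):
  hemizygous males, het/hom females. A diploid heterozygous male X call is
  anomalous (mosaicism or XXY) and is matched carrying its anomaly flag so
  the rule engine can adjudicate it. chrX is treated uniformly
  non-pseudoautosomal; the generator never plants PAR variants.

Inheritance: a carrier parent is positive evidence regardless of call
quality; de novo status additionally requires both parents confidently
homozygous-reference (GQ ≥ 30, DP ≥ 7 — chosen to mirror the cohort GQ
filter and typical exome depth floors, since reanalysis pipelines rarely
publish these); missing parents or calls give *unknown*. The child-GQ
prefilter applies to the child call only; poor parental calls degrade
inheritance to unknown rather than dropping the observation, because the
elimination list concerns the detected variant.

Internal cohort MAF is computed over unrelated probands only (one proband
per family, parents excluded to avoid double-counting transmitted alleles;
males contribute one allele on chrX). "Unrelated" means distinct family ids;
pedigree relatedness is trusted, not inferred.

## The rule engine

Thirteen exclusion rules are evaluated in fixed precedence order (the order
of the published exclusion-reason table, which assigns each variant a single
reason without stating tie-breaks); all triggered reasons are recorded and
the first is primary. Key interpretation choices:

* "apparently unaffected parent" = affected flag false **and**
  phenotype-similarity flag false. The similarity flag is a pedigree
  extension column (a boolean), not phenotype-ontology matching.
* the benign-missense rule applies only to variants inherited from an
  unaffected parent or with unknown inheritance — a de novo benign-predicted
  missense is not excluded by it.
* a female het in a hemizygous-requirement gene is reportable only with
  confirmed de novo status (inferred de novo *and* passing the quality
  proxy).
* uniparental homozygosity is defined genotypically (homozygous child,
  exactly one carrier parent); array-based UPD detection is out of scope —
  the genotype pattern is the observable.
* exactly five Sequence Ontology terms count as "noncoding":
  splice_region_variant, 5_prime_UTR_variant, 3_prime_UTR_variant,
  intron_variant, synonymous_variant.
* the reference-population allele count is the global count; per-population
  maxima are not modeled.
* de novo quality is a programmatic proxy for visual read inspection: child
  depth ≥ 10, child VAF in [0.3, 0.7] for hets (≥ 0.85 hom/hemi), at most
  one alternate read in either parent.
* compound-het pairs: the single-variant rules run on each member. A clean
  primary member with a failing partner yields the partner-failed reason; a
  primary member failing its own rule keeps that reason (precedence order).
* parental mosaicism (transmitting parent VAF < 0.4, child VAF > 0.4, both
  bounds strict) is computed for every inherited observation and reported as
  a flag, never as an exclusion.

The inherited-from-unaffected-parent rule is restricted to autosomal
monoallelic genes; X-linked transmission is handled by the three X rules.
All thresholds live in `Config` with the published values as defaults. The
`revised` profile disables the imprinted-gene and X-linked-overdominance
rules, reflecting the later relaxation of those two exclusions.

## Synthetic cohort

The generator emulates the study conditions at desk scale: trios plus
singletons (defaults 200 + 50 for pipeline-level verification; unit tests
use 60 + 15), proband sex alternating, parents unaffected unless a plant
requires otherwise. Each planted class is the *minimal* configuration that
triggers exactly its rule, one gene per plant, so truth labels are
unambiguous. Read depth is negative-binomial (mean 40×, overdispersion 10 —
ordinary exome coverage); allele depths are binomial around the true allele
fraction (0.5 het, 1.0 hom, or a mosaic parent fraction drawn uniformly from
0.05–0.35 for a configurable share of inherited plants, default 10%). With
`sequencing_noise=False` depths and allele counts are set deterministically,
making plant recovery exact. A single seeded generator drives all draws;
outputs are byte-identical given the seed.

**Internal-MAF scaling.** Cohort-frequency thresholds do not transfer across
cohort sizes: one het carrier among N probands has frequency 1/(2N), which
exceeds the published 0.0005 monoallelic threshold whenever N < 1000 — at
desk scale every planted variant would be dropped. The generator therefore
writes a run config alongside the cohort with
`internal_maf_mono = clamp(max(0.0005, (k+2)/(2N)), ≤ 0.5)` where k is the
recurrent-indel carrier count (default 9), and the biallelic threshold at
10× the monoallelic one (the published ratio). The formula keeps the
recurrent-indel plant below the MAF cut (so it is dropped for recurrence,
matching the published drop precedence) while the internal-MAF plant, seeded
into ⌈2N·threshold⌉+2 families, exceeds it. At the original study's scale
(13,462 probands) the formula reproduces the published 0.0005/0.005 exactly.
`Config` defaults remain the published values.

What the generator does **not** emulate: linkage disequilibrium, realistic
site-frequency spectra, sequence-context mutation models, pseudoautosomal
regions, genotyping error in non-carriers, or clinical review behaviour
(review labels are external inputs). Passing plant-recovery therefore shows
the pipeline implements its rules exactly as specified, not that the rules
are calibrated for real sequencing artefacts.

## Statistics

Exclusion tables count observations per primary reason with the fraction
judged diagnostic on review (labels are an input; the package does not model
reviewer judgment). Predictor statistics are 2×2 tables of stratum ×
reported-after-review; the test is the exact two-sided Fisher test, computed
by summing hypergeometric probabilities not exceeding the observed table's
(relative tolerance 1e-7 against floating-point ties), with
continuity-corrected chi-square reported alongside for transparency. Fisher
was chosen because several strata are small; the p-values it produces on the
published count tables match the published ones at their printed precision.
Percentages use half-up rounding, matching conventional printed tables. A
variant absent from the reference population counts as below any MAF
threshold (absence is the strongest rarity evidence); unstratifiable records
are surfaced as a count rather than forced into a stratum.

## Verification strategy and problem sizes

* plant recovery: exact confusion-matrix identity on a noise-free cohort of
  200 trios + 50 singletons (all 13 exclusion classes, 4 drop classes,
  standard-reported and background plants); with noise enabled at 40×,
  recovery is checked to stay ≥ 95% across 10 seeds.
* rule engine: agreement with an independently coded set of standalone rule
  predicates on 10,000 randomized observations.
* Fisher test: agreement with a from-scratch binomial-coefficient
  enumeration for every table with margins ≤ 12 (exhaustive) plus 400
  seeded random margin sets up to 50, and with an independent library
  implementation on random tables.
* normalization: idempotence (property-based) and collapse of
  brute-force-enumerated indel placements to a single key.
* conservation and determinism: stage counts conserve; repeated runs on
  identical inputs are byte-identical (output ordering canonicalized by
  chromosome, position, proband).

## Known limitations

Phasing is pedigree-only (no read-backed phasing); relatedness is trusted
from the pedigree; liftover between assemblies is unsupported (non-GRCh37
records are rejected, not converted); the clinical-review step that decides
which excluded variants are true diagnoses is outside the model; and the
eligible-catalog construction treats the variant-summary table as the single
source of truth rather than reconciling it with a release VCF.
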
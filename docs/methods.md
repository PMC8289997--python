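# Methods

## Cohort model

The cohort is a dense genotype matrix (variants × samples) over four call
states: hom-ref, het, hom-alt, missing. A *carrier* has at least one
alternate allele; dosage is never used for filtering (het and hom-alt are
equivalent everywhere except the homozygote audit column). Families carry
only their sequenced affected members; parental genotypes, phase and
unaffected relatives are out of scope by design, since only affected
patients were sequenced in the study setting this models.

**BC_GF** (cohort genotype frequency) for a variant is the fraction of all
sequenced patients — the whole cohort, never one family — with a
non-missing call. It is a missing-data guard: `BC_GF > 0.8` removes
variants whose genotypes failed in more than a fifth of the cohort.

**Segregation** ("detected in all family members") is evaluated strictly:
every sequenced member must be an observed carrier, and a missing genotype
fails the family just as a hom-ref call does. The strict rule keeps every
tier a deterministic function of the calls; the BC_GF filter already
bounds cohort-wide missingness, and families that fail only because of a
missing call are flagged `failed_due_to_missing` in the call provenance so
the lenient alternative can be audited without re-running anything.

## Annotation normalization

**MMAF** folds each population panel's allele frequency to the minor
allele, `min(af, 1 − af)`, and takes the maximum over panels; a variant
reported by no panel has MMAF 0 (and such variants do occur in real
annotation dumps — rare alleles private to a cohort). The folded (minor
allele) definition is used consistently; the panel that supplied the
maximum is recorded per variant for audit. Panels are arbitrary `AF_*`
columns; the default set is ExAC, 200Danes, SweGen and 1000 Genomes.

**Function classes** are StopGain, Splicing, FrameshiftDeletion,
FrameshiftInsertion, Missense and Other. ANNOVAR labels ("stopgain",
"nonsynonymous SNV", ...) and report-table shorthand ("Missense",
"Insert", "Deletion") both map onto them, case-insensitively; explicitly
non-frameshift indels and anything unrecognized map to Other. The four
truncating/splice classes form the *deleterious* subset.

**ClinVar** strings are canonicalized by case/punctuation folding. An
absent value is Absent; an unrecognized non-empty string becomes a
distinct Unrecognized class. Both are treated as *not benign* (retained)
because the clinical-panel screen excludes only variants considered
benign; mapping unknowns to Uncertain would silently launder them into a
recognized category.

**CADD** comparisons are strict (`>`). An un-scored variant passes a CADD
threshold only when its class is frameshift insertion/deletion: frameshift
indels are systematically absent from CADD score dumps, and waiving the
threshold only for that class keeps un-scored missense or synonymous
variants out while retaining the truncating indels the deleterious tiers
are meant to catch.

## Tiers

Defaults (all configurable via YAML): KnownGene — gene in a 15-gene
clinical breast/ovarian panel, BC_GF > 0.8, MMAF < 0.2, ClinVar not
(likely) benign, CADD > 20, *no* segregation requirement (the published
panel screen reports families where only some sequenced members carry the
variant, so requiring segregation would be wrong for this tier).
NovelCandidate — segregation required, BC_GF > 0.8, MMAF < 0.01,
CADD > 20, with an explicit exclusion list for families already explained
by a pathogenic panel finding (an input, not auto-detected, so the tier
stays a pure function). HighRisk — NovelCandidate narrowed to families
with 3–4 sequenced members, MMAF < 0.001, CADD > 25; the thresholds nest
strictly, so the high-risk calls are provably a subset of the novel calls.

The novel tier imposes no function-class criterion: rarity plus a strict
CADD threshold is the filter, and the function class is a reporting
dimension (the cohort summary cross-tabulates by it). Each surviving call
records every criterion with its observed value; re-evaluating the
criteria from the raw inputs reproduces the call set exactly, which the
tests check.

Whether `BC_GF > 0.8` should be strict or `≥` is not decidable from the
printed criteria; the implementation is strict and the comparator's
threshold is exposed in config.

## Synthetic cohort generator

The generator reproduces the study conditions as its defaults: 24
families — three with four sequenced members, six with three, fourteen
with two, one with one (59 patients) — 400 background exome sites, ~2%
missing genotypes, and one planted segregating risk variant per family
(drawn inside the high-risk thresholds for 3–4-member families, inside the
novel-candidate thresholds otherwise; an infeasible planted range is a
validation error, not a silent clamp).

Background population frequencies follow a three-part mixture: a point
mass at 0 (allele absent from every panel, weight 0.25), a log-uniform
rare component on [1e-5, 0.01) (weight 0.55) and a uniform common
component on [0.01, 0.5). Panel AFs are constructed so their folded
maximum equals the drawn MMAF exactly. CADD for scored sites is uniform on
[0, 40]; frameshift sites are un-scored 70% of the time (they mostly are,
in real dumps), other sites 2%. Sites are independent (no LD) — the
screens filter sites one at a time, so LD would not change what the tests
can detect. Background genotypes are drawn independently per sample under
Hardy–Weinberg at the site frequency; MMAF-0 sites receive a rare
cohort-private frequency so that panel-absent variants still appear in
patients. Missingness is applied last, uniformly at random per
(variant, sample) — no informative missingness mechanism is modelled.

Relatedness enters through the **gene-drop** machinery: a schematic
pedigree hangs the sequenced members off one founder couple at the meiotic
distance implied by the family's degree label (siblings for 1st degree, a
sibling's child for 2nd, grandchild for 3rd, ...); founder genotypes are
drawn under HWE and each meiosis transmits each allele with probability ½.
`expected_chance_segregating` uses it to Monte-Carlo the number of
background variants passing the segregation screen per family by chance —
the small-family bias: every additional sequenced member multiplies the
chance-segregation probability by roughly ½ for a rare transmitted allele,
so two-member families accumulate more chance hits than four-member
families. A sib-pair enumeration oracle (all nine founder genotype
combinations) verifies the transmission model in the tests.

What the generator does **not** emulate: realistic exome site counts (it
uses hundreds of sites, not ~30M bases — the screens are per-site, so
scale only affects runtime), LD, sequencing batch effects, informative
missingness, population substructure across panels, and real pedigree
topologies. Passing tests therefore demonstrate the correctness of the
filtering logic under the stated statistical model, not robustness to
real-data artefacts.

## Printed-table reconstructions

The two public report tables are re-keyed in `famseg.fixtures`: every row's
gene, position, alleles, function, MMAF, CADD, ClinVar string and carrier
list, embedded as data. Genotypes are set het for listed carriers (hom-alt
for the one reported homozygote), hom-ref elsewhere, so BC_GF is 1 for
every fixture variant. Running the corresponding screen must return
exactly the printed rows — the bookkeeping (10 observations / 13 carriers
/ 9 families for the panel screen; 22 variants / 22 genes / 6 families
with Br7 contributing 6 for the high-risk screen) is asserted in the
acceptance tests and recomputed by `scripts/acceptance.py`. The
shared-variant fixture encodes the reported four-family carrier pattern
(2 of 2, 2 of 4, 1, 1 → 6 carriers); its MMAF (1.7e-3) and CADD (36) are
synthetic stand-ins inside the reported qualifying ranges, since the
source prints the ranges but not the values.

Cohort-wide counts (hundreds of candidate variants over the full exome)
require the access-controlled genotype data and are not reproducible here;
they are covered instead by property guarantees: tier nesting, MMAF and
gene-drop oracle equivalence, exact planted-variant recovery at zero
missingness, and byte-identical outputs under a fixed seed.

## Numerical and interface choices

Coordinates are 1-based; chromosome labels are matched after stripping any
`chr` prefix. The annotation join key is (chrom, pos, ref, alt) after
multi-allelic decomposition, with no indel re-normalization — inputs must
be consistently left-aligned upstream, and orphan annotation rows or
unannotated variants are flagged rather than dropped silently. Absent
numeric cells stay absent (never 0), except MMAF, which is defined as 0
when no panel reports the allele. Report rows sort by (chrom numeric-first,
pos, alt, family) and writers are byte-deterministic. Within a family a
variant yields exactly one call; the same variant in several families
yields one call per family. Problem sizes in the analysis drivers and
tests (hundreds of sites, tens of gene-drop replicates) were chosen so the
whole suite runs in seconds while keeping the statistical checks
well-powered at 3–4 standard deviations.
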
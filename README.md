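# famseg

Tiered prioritization of rare germline variants in breast-cancer families
where only affected relatives were exome sequenced.

## The problem

In a cohort of families with a strong breast-cancer history, one to four
affected members per family are whole-exome sequenced. With no unaffected
relatives and no full pedigree genotypes, prioritization rests on a small
set of per-variant filters and on within-family segregation among the
sequenced patients. `famseg` implements that pipeline as a tested library
for anyone re-running or adapting this style of family-based screen:

* **BC_GF** — the fraction of all sequenced patients with a non-missing
  genotype at a variant (a cohort-wide missing-data guard, `> 0.8`);
* **MMAF** — the maximum minor allele frequency across population panels
  (each panel's AF folded to `min(af, 1 − af)`, then the max; `0` when the
  allele is absent from every panel);
* **CADD** (phred-scaled) with strict thresholds; un-scored frameshift
  indels are exempted, since they are systematically missing from CADD
  dumps yet belong in the deleterious tiers;
* **ClinVar** class normalization, where only Benign/Likely-benign
  excludes a variant from the clinical-panel screen.

Three screens are built from these, all thresholds strict:

| tier | BC_GF | MMAF | CADD | segregation | eligibility |
|---|---|---|---|---|---|
| KnownGene | > 0.8 | < 0.2 | > 20 | no | 15-gene clinical panel, ClinVar not benign |
| NovelCandidate | > 0.8 | < 0.01 | > 20 | all sequenced members carry | families without a pathogenic panel finding |
| HighRisk | > 0.8 | < 0.001 | > 25 | all sequenced members carry | families with 3–4 sequenced members |

Cross-family views aggregate the calls: **recurrent genes** (segregating
candidates in ≥ 2 families), **shared variants** (carriers in ≥ 3 families
with MMAF < 0.01 and CADD > 25, no segregation required), and a
function-class × WES-class cohort summary.

Because the real genotype data is access-controlled, the package ships a
**synthetic cohort generator** (Hardy–Weinberg background, schematic
pedigrees with gene-drop transmission, planted segregating risk variants,
configurable missingness) and fixtures that reconstruct the published
report tables row by row.

## Worked example

Re-run the clinical-panel screen on the reconstructed published cohort:

```bash
python analysis/02_screen_known_genes.py
```

```
10 (variant, family) observations, 13 carrier observations (12 distinct patients), 9 families
  MSH2    chr2:47703548G>T             Br2   carriers=Br2.2,Br2.4
  NBN     chr8:90983460G>A             Br24  carriers=Br24.1
  ...
  CHEK2   chr22:29091857C>-            Br1   carriers=Br1.1,Br1.3
  CHEK2   chr22:29091857C>-            Br15  carriers=Br15.2
  CHEK2   chr22:29091857C>-            Br7   carriers=Br7.3
```

Ten variant–family observations across nine families; the recurrent CHEK2
frameshift (c.1100delC) appears once per carrier family — four carriers in
three families — and survives the CADD filter through the un-scored
frameshift rule. The novel/high-risk step:

```bash
python analysis/03_screen_novel_and_high_risk.py
```

```
22 high-risk variants in 22 genes across 6 families
  Br7: 6
  Br9: 5
  Br5: 4
  Br6: 4
  Br8: 2
  Br3: 1
missense with CADD > 30: ['EPPK1', 'GALC']
```

The remaining drivers simulate a full cohort (`01`), run the shared/
recurrent views (`04`) and quantify, by gene-drop simulation, how many
background variants pass the segregation screen by chance in each family
size class (`05` — the small-family ascertainment bias inherent to
segregation filtering).

The same operations are available as a CLI over VCF/TSV/YAML inputs:

```bash
famseg-prio screen-known --vcf cohort.vcf --families families.tsv \
    --annotations annotations.tsv --out known.tsv
famseg-prio simulate --seed 1 --out simdir/
```

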
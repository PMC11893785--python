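# fgf14repeat

Long-read genotyping of the GAA short tandem repeat in intron 1 of *FGF14*,
the locus responsible for spinocerebellar ataxia type 27B (SCA27B).
Pathogenic alleles are pure (GAA)N expansions — ≥250 units is the pathogenic
range, ≥300 full penetrance — while interrupted "complex" configurations
built from GCA-containing motifs are benign but confound PCR-based assays.
The package turns long reads spanning the locus (HiFi reads of long-range
PCR amplicons, or pre-extracted reads from PCR-free whole-genome
sequencing) into per-individual diploid repeat calls and cohort frequency
tables, for geneticists screening ataxia and MSA cohorts.

## What it computes

For each read the repeat tract is located and sized **without alignment**:

* **Anchored extraction** — a read spans the locus iff it contains at least
  one of three alternative 20–24-nt anchor sequences on *each* side of the
  repeat, in the correct order and orientation (three anchors per side
  tolerate sequencing errors without fuzzy matching).
* **Junction sizing** — the repeat size in GAA units is the distance between
  the upstream junction 20-mer `AACCAACTTTCTGTGAAGAA` and the downstream
  junction 20-mer `GAAGAATAGAAATGTGTTTA`:
  `units = round((down_start − up_end)/3) + 3`
  (one unit lies inside the upstream 20-mer, two inside the downstream one).
* **Motif decomposition** — greedy longest-match tokenization over the six
  motifs GCA(GAA)₄, GCA(GAA)₃, (GCA)₂GAA, GCA(GAA)₂, GCAGAA, GAA (the
  "waterfall" view), yielding per-read purity and terminal pure-GAA runs.
* **Allele calling** — uniform-length read selection, clustering into ≤2
  alleles, then per-allele classification: configuration class (pure vs
  complex, split at a 100-unit embedded run), penetrance band
  (≥300 / 250–299 / 200–249 / below), rule-based RP-PCR outcome prediction
  (positive / inconclusive / negative), and genotyping of the upstream
  rs534066520-like T>A SNP whose A allele tracks complex configurations.
* **Cohort statistics** — frequency tables per group, Fisher's exact test
  (two-sided small-p convention, exact rational arithmetic), Spearman
  correlation with an exact permutation p for n ≤ 8, and amplicon-vs-WGS
  sizing-bias summaries.

A synthetic-read generator (`fgf14repeat.simulate`, presets in
`fgf14repeat.presets`) produces fully specified diploid cohorts with
HiFi-like errors and preparative-gel selection of products > 750 bp, so the
entire pipeline is testable end to end without external data.

## Worked example

```sh
python examples/genotype_individual.py
```

simulates a compound heterozygote — a pure (GAA)312 expansion plus a
complex configuration with a 167-unit downstream run — and calls it:

```
sample patient_1: 2 alleles
  allele 1: 230 units (range 230-230, 17 reads), class COMPLEX_RUN_GE100, band UNCERTAIN, longest run 129, SNP A
  allele 2: 312 units (range 312-312, 17 reads), class PURE, band FULL, longest run 179, SNP T
RP-PCR prediction: positive
SNP genotype: T/A
```

The 312-unit allele sizes exactly (junction sizing is robust to
substitution errors) and lands in the full-penetrance band; the complex
allele carries the alternate SNP base, giving the T/A genotype.
`examples/cohort_frequencies.py` runs the three study groups (476 ataxia /
548 MSA / 455 healthy individuals, truth-mirrored expanded-allele counts)
through the pipeline and prints the cohort table — e.g. 6 of 476 ataxia
individuals (1.3%) with a pure expansion ≥250 units versus 1 of 455 healthy
(0.2%) — plus the exact test (OR = 5.80, p = 0.124) and a perfectly
concordant SNP association (pure → T, complex → A).
`examples/sizing_bias.py` and `examples/waterfall.py` show the
amplicon-vs-WGS size comparison (11–14 units underestimated by LR-PCR) and
the waterfall plot export.

There is also a thin CLI:

```sh
fgf14 sim --table1 --out sim/ --mode wgs --seed 17 --exact-counts
fgf14 run --in sim/ --manifest sim/manifest.tsv --out report/
```

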
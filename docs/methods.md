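# Methods

## Locus model

The package never aligns reads to a reference genome. Instead it carries a
`LocusTemplate`: 79 nt of upstream flank and 71 nt of downstream flank
(150 nt total, so that a 200-unit tract gives exactly a 750 bp product),
three alternative anchor sequences per side, two junction 20-mers, the
position of an rs534066520-like T>A SNP in the upstream flank, and the
six-motif repeat lexicon. The template models the *published* anchor and
junction sequences faithfully; the genomic phase of the repeat relative to
the true GRCh38 flank is deliberately not reproduced. The internal
convention — one repeat unit inside the upstream junction 20-mer, two
inside the downstream one, hence the `+3` in the unit formula — is
calibrated by round-trip tests (every pure (GAA)N allele with 3 ≤ N ≤ 500
sizes back to exactly N), not assumed from the genome.

Two structural facts follow from the printed sequences and are asserted at
template construction: the upstream flank must end in `GAA` (it is the
junction prefix), so tracts shorter than 3 units cannot be sized (their
junction matches overlap and `locate_junctions` reports
`inverted_junctions`); and `GAA` as a trinucleotide necessarily occurs
inside the printed flanks, so flank validation only excludes motifs of
length ≥ 6. All motifs are T-free while both junction 20-mers contain T,
so neither junction can arise inside a clean tract.

## Read extraction

A read is accepted iff one orientation contains ≥1 upstream and ≥1
downstream anchor with every upstream match ending before every downstream
match begins (the order check rejects chimeric reads). Matching is exact
by default; a Hamming-distance tolerance (`max_mismatches`) exists because
single substitutions otherwise drop reads, but the default follows the
three-alternative-anchors design, which already tolerates errors. `N`
bases never match. Reads with full anchor signal in both orientations are
rejected as `ambiguous_orientation` rather than guessed. Every input read
is accounted for exactly once (accepted or one rejection category).

## Sizing and decomposition

`locate_junctions` searches exactly for each 20-mer, taking the last
upstream and first downstream match, which maximizes the enclosed tract
against spurious error-induced internal matches. The tract
`[junction_up_end − 3, junction_down_start + 6)` is tokenized greedily
left-to-right, trying motifs longest-first ((GCA)₂GAA before GCA(GAA)₂
among the 9-mers); unmatched positions become 1-nt NOISE tokens, so token
spans always partition the tract. On error-free concatenations of lexicon
motifs greedy tokenization achieves zero noise, which equals the
minimal-noise dynamic-programming tiling (enforced by test); on noisy
reads greedy may diverge from the DP optimum, which is tolerated for
speed. One consequence of longest-first matching: at a `GCAGAA → GAA`
block boundary the 15-mer GCA(GAA)₄ absorbs three units of the following
run. The synthetic complex-allele constructor therefore places a single
(GCA)₂GAA block between the interruption region and the terminal run,
which segments unambiguously; measured terminal runs then equal the
constructed ones exactly.

Terminal runs are maximal stretches of GAA tokens in which ≤2 consecutive
noise nt are transparent (substitutions inside expanded pure tracts are
common in amplicon HiFi data); noise inside a run adds no units. The
upstream (downstream) run counts only when it starts (ends) at the tract
boundary. Purity is GAA-token nt over all motif-token nt.

## Uniform-length selection and allele clustering

Amplicon read-length distributions show shattered and artifactual tails,
so reads are filtered to the dense length mode before calling. Sorted
tract lengths are first split into candidate allele populations at gaps
> 30 nt (10 units); within each population a window of width
max(12 nt, 1% of the population median length) slides over the lengths and
the most populated window is kept (ties: lower variance, then shorter
median, then lower start); populations whose best window holds fewer than
`min_reads` (default 3) reads are discarded. The pre-split keeps both
alleles of a compound heterozygote. The published procedure selects the
uniform region visually; the window rule is this package's quantitative
construction and is configurable.

Clustering then splits sorted unit counts at the largest gap when it
reaches `split_gap_units` (default 10), yielding ≤2 alleles; clusters
under `min_reads` are dropped with a warning flag. A homozygote's two
identical alleles deliberately collapse into one call. Allele consensus
values (units, purity, runs) are per-read medians.

## Classification

* Configuration class: PURE iff consensus purity ≥ 0.95 (the published
  classification is visual; a numeric threshold is required and exposed);
  otherwise complex, split at a 100-unit longest embedded run.
* Penetrance bands (inclusive integer bounds): ≥300 full, 250–299
  incomplete, 200–249 uncertain, <200 below.
* RP-PCR prediction: per allele the score is the longest embedded run, or
  the total size for pure alleles; ≥191 → positive, 100–190 →
  inconclusive, <100 → negative; the individual takes the best outcome
  across alleles. The cutoffs are *inferred brackets* from the published
  outcome categories (largest negative run 83, inconclusive runs 134–167,
  smallest positive pure allele 191), not measured constants, and are
  configurable.
* SNP genotyping reads the base at the anchor-relative offset of the SNP
  site (no alignment), takes a per-allele majority (≥80%, coverage ≥3,
  else unknown), and combines alleles; with a single visible allele the
  genotype is reported as homozygous for the observed base.

## Cohort statistics

The frequency table counts each individual once under its
highest-priority category (pure ≥250 > pure 200–249 > pure <200 >
complex ≥100-run > complex <100-run). An allele is reportable as expanded
when its unit count is ≥ 100 (`expanded_min_units`): the published
positive set includes a 191-unit allele whose modeled product (723 bp)
sits below the 750 bp gel cutoff, so gel length alone cannot define
"expanded" when WGS-mode reads are present, and 100 units separates every
expansion from the wild-type allele distribution by a wide margin. Pure
categories report total units; complex categories report the longest
embedded run. Percentages are count/n rounded half-up to one decimal.

`fisher_exact` uses the two-sided small-p convention (sum of
hypergeometric probabilities ≤ the observed one) with exact integer
numerators, so tie handling needs no floating tolerance and the returned
p is a correctly rounded rational. `spearman_exact` uses midranks; for
n ≤ 8 the p-value enumerates all n! permutations exactly, otherwise the
large-sample approximation is used. The sizing-bias summary reports
per-sample WGS-minus-amplicon differences.

## Synthetic data: what it emulates and what it does not

The generator emulates: diploid individuals with one or two alleles whose
tracts are pure (GAA)N or block-structured mixes of the six motifs,
flanked by the printed anchor/junction context; an upstream SNP phased
with configuration (pure/wild-type → T, complex → A); uniform per-base
substitution/insertion/deletion errors at HiFi-like rates (defaults 0;
study-condition runs use 0 or 0.002–0.005 substitutions/base); per-allele
depth drawn from `depth_range` (default (20, 200), a desk-scale reduction
of the reported per-individual read counts, median ≈ 1644); strand
assignment with probability 0.5; and preparative-gel selection (amplicon
mode omits reads of alleles with products ≤ 750 bp; wgs mode keeps all).
Exact-counts mode assigns alleles by largest-remainder quota,
rarest-first, so scarce expanded alleles spread one per individual and
truth counts are conserved exactly.

It does **not** emulate PCR stutter or chimeras, somatic mosaicism,
subread/CCS error structure, homopolymer-weighted errors, quality-score
realism, or coverage biases against long alleles. Passing tests therefore
demonstrate the correctness of the decision rules and size arithmetic
under controlled noise, not robustness to every artifact of real amplicon
data.

The bundled three-group cohort preset fixes per-category expanded-allele
counts to the published table, uses the published unit values where they
are printed (269; 251–361 with five ≥300; 212/240; 191; terminal runs
34/167, 27/134, 27/160, 31/140; complex-run ranges 24–83, 21–83, 23–75)
and spreads the unprinted members evenly across the printed ranges.
Complex alleles pad their GCAGAA interruption block to ~230 total units so
that every one is LR-PCR positive; the wild-type allele is (GAA)25.
Cohort reproduction runs in wgs mode with error-free reads at depth 20
(around 60,000 reads, a few seconds on one CPU).

## Numerical choices

* Coordinates are 0-based half-open; `junction_up_end` is exclusive.
* `count_units` rounds to nearest with ties-to-even; with substitution-only
  errors the gap is always a multiple of 3 and rounding is inert.
* Negative junction gaps raise; unit counts are ≥3 whenever both
  junctions are found.
* All randomness descends from one seed; cohort simulation derives one
  RNG per individual via `SeedSequence(seed, spawn_key=(group, index))`,
  so outputs are byte-identical across reruns and independent of
  iteration order.
* Read ids carry truth metadata after a `|` separator for debugging only;
  an id-scrambling test enforces that no pipeline stage reads it.

## Known limitations

* Junction matching is exact-only; reads with an error inside a junction
  20-mer are unsized (at HiFi rates this loses ~18% of reads per 20-mer
  pair at 0.5%/base substitution, which depth absorbs).
* Tracts under 3 units cannot be sized (junction overlap, above).
* The RP-PCR predictor is a rule on run lengths, not a model of primer
  chemistry or electropherogram traces.
* With amplicon-mode input, alleles under the gel cutoff are invisible,
  so genotypes are reported homozygous-by-observation and short-allele
  heterozygosity is unknowable — matching the wet-lab assay's own limits.
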
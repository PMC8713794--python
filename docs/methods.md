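# Methods

## Coordinate and format conventions

Everything is 0-based half-open (BED arithmetic).  Overlap requires at
least one shared base: intervals `[0,10)` and `[10,20)` are adjacent
and never merge under the default rules.  Strand is carried on
intervals but ignored by overlap and merge — regulatory elements are
strandless; only TSS logic respects gene strand.  Readers validate
coordinates and report malformed lines with file and line number;
BED round-trips are property-tested to guard the convention.

## pRE catalog

Overlapping wild-type TF ChIP-seq peaks are merged into discrete pREs.
Merging is transitive (a chain of pairwise-overlapping peaks becomes
one span) and strict by default: `min_gap` (the smallest gap that
prevents merging, default 0 bp) is exposed because the field has no
consensus gap rule, but adjacent-but-disjoint peaks do not merge.  A TF
binds a pRE iff at least one of its peaks overlaps it by ≥ 1 bp; with
the merge construction this is equivalent to having contributed a
source peak.  Mutant peak sets are rejected at catalog construction:
the WT catalog is the fixed universe against which mutant chromatin is
compared.

Peak-height comparability across TFs with different sequencing depths
is achieved in two steps: reads-per-million scaling
(signal × 10⁶ / library size) followed by within-TF percentile
midranks, (rank − 0.5)/n × 100 with average ranks for ties, so a
singleton peak ranks 50 and any per-TF monotone rescaling of raw
signal leaves ranks unchanged.  Quartile classes ("no peak", ≤ 25th
percentile, > 25th) aggregate multiple overlapping peaks by the
maximum rank (mean available).

## Interactome

A loop links a pRE to a gene iff one bin-pair anchor overlaps the
promoter bin — the single fixed-resolution bin containing the TSS
(`promoter_slop_bins`, default 0, widens it) — and the other anchor
overlaps the pRE by ≥ 1 bp.  Loops are consumed pre-filtered at
FDR < 0.01; loop calling itself is out of scope.  The locus window is
the union of the gene body ± 100 kb and the span to the farthest loop
contact, so added loops can only grow a locus.  Members carry evidence
tags (`loop5k`/`loop10k`, `computational`, `window`) that accumulate
rather than overwrite.  Precomputed enhancer–gene associations are
consumed as a two-column table and never recomputed.  The distal test
uses the nearest anchor edge to the linked TSS with an inclusive
2,500 bp floor ("at least 2,500 bp").  Where an analysis needs "the
interactome" (e.g. locus ratios), all evidence tags count by default;
a flag restricts to loop-linked members.

## Enhancer activity associations

The binding↔activity association is deliberately the simplest model
that yields signed, gated calls: per TF × label, the φ coefficient of
the two binary vectors (identical to Pearson r on 0/1 data, checked)
with a two-sided Fisher exact p, significant at raw *P* < 0.01.  No
multiple-testing correction is applied by default because the
reference analysis gates on a raw threshold; Benjamini–Hochberg is one
flag away.  Degenerate margins return a flagged "none" direction
rather than raising.  A joint logistic alternative (label ~ five TF
indicators, ridge-stabilised) is provided for the "combinations of
TFs" reading; presence/absence is the default predictor, height ranks
optional.

## Network enrichment

A gene satisfies the criterion when some pRE with occupancy ≥ 3 lies
at a TSS distance within [2,500 bp, 100 kb], both bounds inclusive.
The null draws 1,000 uniform same-size gene sets from the full
annotated universe — network genes included, since random sets of that
size are drawn from all genes; `exclude_network` removes them.  The
universe is a required input, never defaulted.  Empirical p-values use
the add-one convention (1 + #{null ≥ obs})/(n_perm + 1) and can never
be zero; the null median of an even-length vector is the midpoint
average.  Folds are reported to one decimal, percentages as integers,
round-half-up.

A note on calibration testing: the null count over a set of size 38
takes at most 39 values, so its permutation p-values are inherently
too discrete for a two-sided KS-against-uniform check regardless of
implementation correctness.  The calibration suite therefore tests
uniformity at a larger null study (3,000-gene universe, sets of 400,
499 permutations, 200 replicates) where the statistic is fine-grained;
the 38-gene configuration is exercised for determinism and reporting
arithmetic.

## Chromatin state and locus ratios

Mark flags (accessible / active / repressed) are independent ≥ 1 bp
overlap calls; bivalent-style co-occurrence is permitted and marks are
tabulated separately.  The locus ratio counts flagged member pREs (not
peak counts or coverage) with pseudocount α = 0.5 to keep empty
denominators finite: (n_active + α)/(n_repressed + α).  The
medial-pallium comparison is an unpaired two-tailed Welch t-test on
log-ratios (variance stabilisation); group means of raw ratios and
pooled-count ratios are both emitted because either summary is a
defensible reading.  MP membership is an input list, never inferred.
Degenerate comparisons (empty group, zero variance) are reported with
a message instead of an exception.

## Differential state

The differential statistic is a transparent deterministic rule rather
than a replicate-aware dispersion model (single libraries per
condition cannot support one): mean RPM over the pRE in each
condition, log2((mut + ε)/(wt + ε)) with ε = 0.25 RPM, Gain at
log2FC ≥ +1, Loss at ≤ −1 (boundaries inclusive), and a floor — the
stronger condition must reach 1 RPM, else NoChange.  Swapping the
conditions provably flips every call and negates every effect size.
Tallies report two denominators side by side, because "percent of
pREs" is ambiguous: pREs assessed for the mark (carrying its WT peak
or a differential call) and the full catalog.

Locus direction sums ±1 over differential member pREs (+1 for
H3K27ac Gain or H3K27me3 Loss, −1 for the opposites); ATAC
contributes only behind a flag since the ratio language concerns the
histone marks, and accessibility changes are empirically the least
informative.  Concordance assesses only loci with a non-zero RNA
direction and ≥ 1 differential member: match = (down ∧ repressed) ∨
(up ∧ activated), reported as an integer percent or NA.

## Synthetic data

The generator emulates the study conditions rather than arbitrary
data.  Defaults: 4 chromosomes × 60 Mb, 300 genes, 240 locus sites
plus 500 assay (enhancer) sites on a 5-kb grid (≥ 5 kb spacing so
neighbouring sites never merge), five TFs, a 38-gene network.

* Co-binding: latent site strength u ~ U(0,1);
  P(bind) = σ(−0.2 + 6c(u − ½)) with cobinding strength c = 0.8; c = 0
  reduces exactly to independent Binomial(5, σ(−0.2)) occupancy
  (tested).  Per-TF library-depth factors differ so RPM/rank
  normalisation is genuinely exercised.
* Marks: P(ATAC|k) = 0.25 + 0.15k, P(H3K27ac|k) = 0.15 + 0.125k,
  P(H3K27me3|k) = 0.60 − 0.10k, clamped to [0,1] — anchored to the
  reported progenitor profile (all five-TF pREs accessible, ~78%
  active-marked, ~10% repressed; 60% of unbound elements repressed).
* Activity labels: class and pallial labels from logistic models in k
  with planted positive LVP/RC and negative MP/DV couplings
  (coefficients in `SimulationConfig.activity_coefs`).  The pallial
  gate is kept mild (slope 0.25) so the marginal MP/DV couplings stay
  strongly negative; a steeper gate attenuates them below
  detectability at n = 500, which would contradict the intended
  planting.
* Loops: half of bound locus sites loop to the nearest gene's TSS bin
  at 5 kb, FDR ~ U(10⁻⁴, 0.009); decoy pairs and above-threshold rows
  exercise the filter.
* Coverage: per-site depth ~ Poisson(target · width)/width, flat
  within the site, 0.05 RPM uniform background; WT library 10⁶,
  mutant 2×10⁶ (depths scaled accordingly).  Mutant effects perturb
  10% of catalog sites per mutant by |log2FC| = 2 at 20 RPM (30%
  gains, 70% losses), matching the regime in which the paper-style
  Gain/Loss calls are meaningful.
* Network planting: by default 79% of network genes are drawn from the
  satisfying pool against a ~20% background rate — the 30/38-vs-7/38
  regime; `network_satisfying_frac=None` gives a null (uniform) draw.
* RNA labels derive deterministically from the signed planted histone
  changes of each network locus, with 10% label noise by default
  (0 for the noise-free recovery checks).

What the generator does *not* emulate: nucleotide sequence, read-level
noise, replicate structure, peak-caller behaviour, inter-site
correlation beyond the latent factor, and realistic loop distance
distributions.  Passing tests therefore demonstrate that the
implementations recover what they are defined to measure under
Poisson-level noise — not that the biological effect sizes in real
data are detectable.

## Problem sizes and numerical choices

Test and acceptance runs use the default study (~740 sites, 300 genes)
except where a property needs more resolution: mark–occupancy recovery
uses 2,000 sites; permutation calibration uses a 3,000-gene universe;
differential recovery pools 20 seeds.  Ties in ranks use average
midranks; percentages round half-up to integers and folds to one
decimal; the empirical p is add-one; the ratio pseudocount is 0.5;
log2 fold changes use ε = 0.25 RPM.  All randomness flows from a
single integer seed per run; identical seeds give byte-identical
outputs (tested).

## Known limitations

* Differential calls have no dispersion model; with real replicated
  data a count-based test would be preferable (a non-default exact-test
  hook is the natural extension point).
* The correlalogram treats labels independently; the logistic mode
  adjusts for co-binding but not for spatial autocorrelation of
  enhancers.
* The locus ratio weighs every member pRE equally regardless of
  distance or evidence strength.
* Catalog size is data-dependent (a function of upstream peak-calling
  thresholds) and is therefore reported, never asserted.
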
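# preatlas

Integrative analysis of the regulatory elements that pattern the
developing cortex.  During mouse corticogenesis, transcription factors
(TFs) with graded expression in ventricular-zone progenitors — EMX2,
LHX2, NR2F1, PAX6, and PBX1 — bind shared enhancers and translate
signalling gradients into regional gene expression.  `preatlas`
re-implements, as a tested and reusable pipeline, the analyses used to
characterise such a network from multi-assay epigenomic data:

1. **pRE catalog** — overlapping TF ChIP-seq peaks are merged into
   putative regulatory elements (pREs); each pRE carries an occupancy
   vector over the five TFs, and peak heights are made comparable
   across TFs via reads-per-million scaling and within-TF percentile
   ranks.
2. **Interactome** — pREs are assigned to gene promoters using
   significant chromatin-loop bin pairs (PLAC-seq style, 5-kb or 10-kb
   bins, FDR < 0.01), plus a ±100 kb gene-body window and optional
   precomputed associations; the distal fraction (anchors ≥ 2,500 bp
   from the TSS) is reported.
3. **Activity model** — in vivo tested enhancers (VISTA-style labels:
   Pallial / Subpallial / Nontelencephalic / Inactive, with pallial
   region and gradient labels) are scored for combinatorial binding;
   a correlalogram reports, per TF × label, the φ coefficient with a
   two-sided Fisher exact test at *P* < 0.01.
4. **Network enrichment** — a permutation test asks whether genes of a
   regulatory network have a combinatorially bound (≥ 3 TFs) distal pRE
   within 100 kb of the TSS more often than 1,000 random same-size gene
   sets; fold = observed proportion / null-median proportion.
5. **Chromatin state** — ATAC / H3K27ac / H3K27me3 peaks are overlaid
   on the catalog; mark prevalence is profiled by occupancy class, and
   each gene locus gets an acetylation/methylation ratio
   (active + α)/(repressed + α) with a medial-pallium vs other t-test.
6. **Differential state** — WT vs mutant (Emx2, Nr2f1, Pax6 knockouts)
   coverage is compared per pRE per mark: log2((mut+ε)/(wt+ε)) with
   Gain/Loss/NoChange at |log2FC| ≥ 1; calls aggregate to signed locus
   directions and are scored for concordance with curated RNA-direction
   annotations.
7. **Synthetic data** — a generator plants co-binding, occupancy-coupled
   marks and activity labels, loops, and mutant effects, with truth
   tables, so the whole pipeline is testable without any download.

All coordinates are 0-based half-open (BED-native); 1-based input is
not supported.  Formats: BED6, BEDPE (+FDR column), bedGraph, TSV.

## Worked example

Generate a synthetic study and run every stage:

```bash
preatlas simulate --out data/ --seed 1
preatlas run-all --data data/ --out out/ --seed 1
```

which prints (seed 1):

```
pRE catalog: 543 elements, occupancy spectrum 0:0, 1:129, 2:133, 3:93, 4:114, 5:74
loop interactions distal (>= 2.5 kb from TSS): 99%
network enrichment: 30/38 (79%) vs null median 8 (21%): 3.8-fold (empirical P = 0.000999)
Emx2-KO: RNA/epigenome concordance 2/2 (100%)
Nr2f1-KO: RNA/epigenome concordance 4/5 (80%)
Pax6-KO: RNA/epigenome concordance 5/5 (100%)
```

Reading: the five TF peak sets merge into 543 pREs, 74 of which are
bound by all five TFs.  99% of promoter-anchored loop contacts are
distal.  30 of the 38 network genes have a ≥3-TF distal pRE within
100 kb of their TSS versus a median of 8/38 in 1,000 random gene sets —
a 3.8-fold enrichment that no random set matched (empirical
*P* ≈ 0.001).  The concordance lines compare each mutant's curated
RNA directions against the epigenomic locus directions; the single
Nr2f1-KO mismatch is the generator's 10% RNA label noise at work.
`out/summary.json` carries the full machine-readable
report (mark-by-occupancy percentages, locus-ratio comparison,
per-mutant differential tallies and RNA concordance).

The same analyses are available as library functions
(`preatlas.call_pres`, `preatlas.permutation_test`,
`preatlas.correlalogram`, `preatlas.call_differential`, ...); see the
docstrings and `docs/methods.md`.

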
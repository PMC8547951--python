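# Methods

This note documents the models, conventions and design choices behind
kairoscan, in the order data flows through the package.

## Coordinates and formats

All intervals are 0-based, half-open internally. GFF3 (1-based, closed)
converts at the read/write boundary, so a GFF3 gene `start=1001, end=2000`
becomes `[1000, 2000)` with length `end − start`. bedGraph is already
half-open and passes through unchanged; overlapping bedGraph bins are an
error rather than being merged silently, because a merge rule would change
densities without the user noticing. Only `gene` features are read from
GFF3: the analysis is gene-level, and transcript structure (introns vs
exons) is deliberately ignored — the transcribed region is treated as one
interval.

The metabolic annotation is a gene → pathway → domain membership table.
Domains are transferred from pathways to genes. A gene's *unique domain* is
defined only when all of its pathways map to exactly one common domain;
domain-level analyses use only such genes, so adding a multi-domain gene to
the input cannot change any domain-level result (this is tested).

## Gene windows and signal density

Each gene's analysis window is its transcribed region extended by
`upstream_bp = 1000` and `downstream_bp = 500` (defaults), applied
strand-aware: upstream of a minus-strand gene is genomically to the right.
Whether a published analysis of this kind extends strand-aware or not is
usually ambiguous; strand-aware is the biologically meaningful reading, and
both extents are parameters. Windows are clipped at chromosome bounds and
flagged.

Tracks are rank-normalized per mark: bin values become genome-wide
fractional ranks in (0, 1] with average ranks for ties. This makes
densities comparable across marks whose raw dynamic ranges differ by orders
of magnitude, and makes the whole downstream analysis invariant under any
monotone transform of the raw signal (tested as a scaling property).

A window's signal is Σ over bins of `value · overlap_bp / bin_len`:
proportional overlap weighting. The paper-style alternative (count a bin
fully if it touches the window) depends on bin size; proportional weighting
does not, and equals an exact per-bp accumulation whenever bin edges align
(and is tested against a brute-force per-bp oracle in general). Overlapping
windows of neighboring genes double-count shared bins by design: per-gene
sums must be gene-local, and set totals are sums over member genes.

Set density = (Σ member signal sums) / (Σ member window lengths), in units
of rank-signal per bp. The background is the set density of the whole
metabolic-gene universe, so "background" is definitionally the universe's
pooled density, not an average of per-gene densities.

## Enrichment calls

The effect size for a set × mark pair is the density fold change against
background. Significance needs counts, so the package tests marked-gene
membership: a gene is *marked* for a modification when its density reaches
the empirical `quantile = 0.75` (linear interpolation) of the universe's
density distribution. The quantile is an explicit, configurable modeling
choice — field practice for "marked by modification X" varies, and no
single rule is canonical. Fisher's exact test (two-sided, scipy's
conventional sum of hypergeometric probabilities ≤ the observed one, with
1e-7 relative tie tolerance) is applied to the 2×2 table
(marked∩set, set∖marked, marked∖set, rest), and Benjamini–Hochberg FDR is
applied jointly across the full set × mark matrix (per-mark adjustment is a
flag). Calls: enriched if FC ≥ 1.5 and q ≤ 0.01; depleted symmetrically at
FC ≤ 1/1.5. The FC bound is inclusive ("at least 1.5"); a raw-p gate
(p < 0.05) reproduces the looser legend-style rule and is exposed as
`use_raw_p`/`alpha`. Degenerate tables (any zero margin) return p = 1.

Pathway-level analyses default to specialized-metabolism pathways with at
least 10 member genes (inclusive bound, configurable); domain-level
analyses use unique-domain genes only.

## Bivalency

Co-occurrence is |marked_A ∩ marked_B| over a gene universe; percentages
round to the nearest integer. Correlation attribution computes Pearson's r
of per-gene densities (densities, not sums, to remove gene-length
confounding) over the universe and again after removing a candidate
subset; the attached p-value is the standard r→t transform with n − 2 df.
Zero-variance vectors are an error (r undefined) rather than NaN.

## qPCR arithmetic

All formulas assume 100% amplification efficiency (base 2).

* **Percent input**: `100 · 2^((Cq_input − log2(1/f)) − Cq_IP)` with input
  fraction `f = 0.01` by default. The dilution factor cancels in every
  treated/mock ratio reported downstream, so its exact value is
  uncritical.
* **Relative abundance**: per-replicate treated percent inputs divided by
  the mock mean, keeping replicate spread for the t-test.
* **SeqChIP percent of first ChIP**: implemented exactly as the assay
  convention prints it, `100 · 2^(Cq_2nd − Cq_1st)`. Because more cycles
  mean less DNA this exceeds 100% when the second pull-down recovers less
  material; the physically decreasing form `2^(Cq_1st − Cq_2nd)` is one
  flag away (`sign_corrected`). Both are kept because the printed
  convention is what practitioners report, while the corrected form is
  what co-localization comparisons should use.
* **ΔΔCq fold change**: per replicate ΔCq = Cq_target − Cq_reference;
  FC = 2^−(mean ΔCq_treated − mean ΔCq_mock), immune to any constant plate
  offset; p from a pooled-variance (Student) two-tailed t-test on the
  replicate ΔCq values, matching the two-group tests used throughout.
* **Earliest induction**: the first time point with p ≤ α (default 0.05)
  and FC > 1. The published statements of "significantly induced within
  t" never state the rule; this is the minimal reading, both knobs are
  exposed, and the FC > 1 gate makes the false-call rate per null time
  point one-sided (~α/2).

## Three-way ANOVA

`anova3` fits genotype × treatment × duration by least squares with
sequential (Type I) sums of squares in the order G, T, D, G×T, G×D, T×D,
G×T×D. Duration is categorical. Only balanced, fully crossed designs are
accepted; unbalanced input raises an explicit error instead of silently
choosing among Type I/II/III, because in a balanced design all types
coincide (order invariance is tested by factor relabeling, and the whole
table is tested against a closed-form cell-mean-contrast oracle). The
expression response defaults to per-replicate relative expression 2^−ΔCq;
a ΔCq-scale response is a flag. A constant (or perfectly fitted) response
reports NA F statistics.

## Synthetic data: what it emulates, and what it does not

The generator produces every input the pipeline consumes, deterministically
from (config, seed) — same config, byte-identical files.

* **Genome**: `n_genes = 1000` non-overlapping genes of 1–3 kb on 2
  chromosomes of 2.5 Mb, placed so every window fits in bounds; uniform
  random strands.
* **Tracks**: per-bin (200 bp) lognormal(μ = 0, σ = 0.75) baseline.
  σ = 0.75 is a moderate, ChIP-coverage-like dispersion (CV ≈ 0.9);
  because the pipeline rank-transforms, σ only controls how well a
  multiplicative effect separates from baseline. Planted effects are
  multiplicative: bins overlapping the windows of a pathway's genes are
  scaled by that pathway's per-mark multiplier, and a designated bivalent
  subset (default 20 genes, multiplier 4) is co-elevated for the mark
  pair. Default planted pathways: a camalexin-like 20-gene pathway at ×3
  on both marks, a glucosinolate-like one at ×2.5, eight null specialized
  pathways, and a background pathway holding the rest.
* **Cq tables**: additive Gaussian noise on the cycle scale
  (σ = 0.2 cycles default — a typical qPCR technical SD), 6 replicates
  (two experiments of three biological replicates, combined). Expression:
  Cq_target = base − log2(FC) + noise against a constant reference gene.
  ChIP and SeqChIP records encode planted abundance ratios and recovery
  fractions through the same percent-input arithmetic the analysis
  inverts. Default kinetic schedules mirror the biological scenario: wild
  type induces camalexin genes from 30–60 min, repressive-mark mutants
  (clf28, pkl-1) precociously from 5 min with a stronger 6-h response,
  activating-mark mutants (idm1, idm2) with a 1–3 h delay.
* **Metabolite titers**: baseline 50 nM with multiplicative lognormal
  noise (σ = 0.15 on the log scale), accumulation factors per
  genotype × time (wild type ×3 from 3 h).

Every planted effect is recorded in a truth table written next to the
dataset; recovery tests read truth only from there.

What the generator does **not** model: read-level noise, nucleosome
positioning, spatial autocorrelation of marks along chromosomes,
mark–mark dependence beyond the planted multipliers, primer efficiency
≠ 100%, and unbalanced or missing wells. Passing recovery tests therefore
demonstrates correctness of the estimators and calls under the stated
noise model, not robustness to every artifact of real tracks and plates.

## Problem sizes used by the test suite

The statistical property tests run the full in-memory pipeline at 1000
genes × 2 marks per seed (200 seeds for null calibration, 100 for planted
recovery, 100 at 500 genes for correlation attribution, 500 for fold-change
recovery), sizes at which the planted effects' detection margins are large
relative to sampling noise while a full run of the suite stays in the
low minutes. Exact-test oracles are exhaustive (all 2×2 tables with
n ≤ 30) or closed-form (BH step-up, balanced ANOVA).

## Known limitations

* The marked-gene quantile (0.75) is a modeling decision, not a community
  standard; co-occurrence fractions depend on it directly.
* Fisher's test on marked-gene counts is one of several count-valued
  readings of "density fold change + exact test"; bins or base pairs could
  be counted instead, and would change p-values (not the FC effect size).
* The earliest-induction rule has a per-time false-call rate of about
  α/2 under the null, so a five-point series makes a spuriously early
  call in roughly 5% of datasets at α = 0.05.
* Unbalanced designs are rejected rather than analyzed; subsample or
  balance upstream.
* ANOVA p-values from real experiments depend on replicate-level data and
  design details; the package reproduces the machinery, not any specific
  published table.
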
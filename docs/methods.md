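# Methods

## Problem setting

Small-cohort 16S rRNA surveys (here: mouse colonic communities, 5–14
animals per group, ~1,000 reads per animal) produce taxon tables that
are compositional (only relative abundances are meaningful), heavily
zero-inflated (many taxa are carried by only some animals) and low-n.
The package's inferential core is a two-part statistic that treats
presence/absence and conditional abundance as two separate sources of
evidence, which matches how such communities actually differ: a taxon
can become more prevalent, more abundant where present, or both.

## Two-part statistic

For groups of sizes n₁, n₂ with k₁, k₂ positive samples:

* presence z: Z_p = (p̂₁ − p̂₂) / √(p̄(1−p̄)(1/n₁+1/n₂)), pooled
  p̄ = (k₁+k₂)/(n₁+n₂); Z_p = 0 if p̄ ∈ {0,1} (presence carries no
  information when a taxon is everywhere or nowhere).
* abundance z: Wilcoxon rank-sum on the non-zero values only,
  standardized with the tie-corrected variance
  Var W = n₁'n₂'/12 · [(N'+1) − Σ(t³−t)/(N'(N'−1))], no continuity
  correction. A fully tied pooled sample has zero variance and is
  assigned z = 0.
* combination: X² = Z_p² + Z_w² against χ²(2) when both parts are
  defined; χ²(1) fallbacks when presence is saturated (rank-sum on all
  values) or when one group has no positive values (presence only).

Degenerate-case conventions: a taxon absent from every sample of both
groups is an error (the prevalence filter removes such taxa first);
p-values are the upper-tail χ² probability, hence always in (0, 1].

The χ² reference is asymptotic. At n = 14 per group its null size at
0.05 is accurate to about a percentage point, but at n ≤ 8 the discrete
permutation distribution of the statistic deviates from χ² by up to
~0.1–0.2 in p (worst for n = 4–5, where the rank-sum lattice is
coarse). The test suite carries a vectorized permutation oracle that
quantifies this; users with very small groups should interpret p-values
near a decision boundary with that error in mind. An exact-enumeration
rank-sum is available behind a flag (`exact_wilcoxon`, for ≤ 10
tie-free non-zero values per group): the exact two-sided p is mapped
back to an equivalent normal deviate, leaving the χ² combination
unchanged. It is not the default — the package follows the
normal-approximation construction throughout so that the combined
statistic has a single, simple reference distribution.

Prevalence filtering retains a taxon if it is present in ≥ 50 % of the
samples of *either* group (inclusive comparison). FDR control is
Benjamini–Hochberg, applied within each pairwise comparison, over the
retained taxa only. Significance flags at 0.05/0.01 use the raw
two-part p (the Manhattan view's reference lines); adjusted p-values
are always reported alongside. The Kruskal–Wallis screen across all
groups runs independently of the prevalence filter, on every taxon with
at least one positive count, with the total-tie convention H = 0,
p = 1.

## Tables and summaries

Relative abundance is computed per sample (count / sample total) before
any pooling; group-level medians, means and quartiles are summaries of
the per-animal values, never ratios of pooled counts. Medians of
even-sized groups average the two central order statistics. Group
summaries also emit quartiles and 1.5×IQR whisker bounds so box-plot
figures can be reproduced from the TSV alone. Both median and mean are
reported because the two summaries can differ materially for skewed,
zero-inflated taxa.

## Read QC

Trimming inspects the terminal 5-base window at each end (5′ pass, then
3′) and removes the terminal base while the window mean is below 20;
when fewer than 5 bases remain the whole remainder is the window. This
terminal-base-removal formulation is deterministic and order-
independent; which end is trimmed is configurable (`trim_ends`), both
by default. Post-trim filters discard reads with more than one
ambiguity (any non-ACGT character, case-insensitive, so IUPAC partial
codes count) or shorter than 200 nt — a read of exactly 200 nt is kept.
FASTQ qualities are Phred+33. OTU identity is the exact taxonomy
string after whitespace canonicalization (strip flanks, collapse
internal runs, case preserved); assignments differing at any rank are
distinct OTUs.

## CLR-PCA

Each sample's counts are augmented by its own pseudocount
δ = 1/(sample total) before the centered log-ratio transform; the
per-sample δ (rather than one global constant) follows standard
compositional practice, and a global δ is available via an argument.
PCA is an SVD of the column-centered CLR matrix — covariance, not
correlation, since CLR values are already on a common log scale. Scores
are the sample projections, loadings the unit-norm right singular
vectors, oriented so each column's largest-magnitude entry is positive
(a deterministic sign convention). Variance ratios are normalized
squared singular values; a zero-variance matrix reports all-zero
ratios.

## Random forest

`RandomForestClassifier` with 10,000 trees by default and library
defaults otherwise, fitted to per-sample relative abundances.
Importance is mean decrease in impurity; ties rank lexicographically.
The out-of-bag misclassification rate is reported as the internal
generalization estimate. Permutation importance is available behind a
flag and is scored with log-loss, because with tens of features and a
dozen samples the training accuracy saturates and hard-label
permutation importances collapse to zero. The ranking is the contract,
not the OOB error: at these sample sizes the error estimate is noisy,
and test suites run 500-tree forests, which preserve the ranking.

## Simulator

Per sample: Bernoulli presence per taxon → group fold-change effects
applied to the baseline composition of present taxa, renormalized →
Dirichlet(overdispersion × proportions) → multinomial at a depth drawn
from a discretized log-normal (σ = 0.4, mean 1,000) clipped to
[388, 3,065]. Zero-inflation is explicit (a presence process distinct
from sampling zeros) because that is the structure the two-part test
targets. A single seed drives a hierarchical stream split per sample.

Default study conditions: groups of 14 animals, 45 taxa, a dominant
Gram-negative lineage fixed at 50 % of the baseline composition and
carried by every animal, a bloom taxon at a 0.5 % baseline, remaining
taxa on a geometric tail, shared carriage probability 0.85, Dirichlet
concentration 50 (moderate animal-to-animal compositional noise). The
bloom scenario multiplies the bloom's baseline 30-fold in the treatment
group (≈ 13 % of the community after renormalization). The contrast
scenario shifts eight mid-abundance taxa 10-fold up in each of two
groups (carriage 0.9) — a strong, many-taxon exposure difference of the
kind that separates cleanly along PC1. The null scenario has identical
parameters in every group and no effects.

What the simulator does **not** emulate: chimeras, sequencing error in
the bases (reads are random ACGT), barcode/adapter structure,
paired-end overlap, phylogenetic correlation between taxa, and
group-dependent sequencing depth (per-group depth overrides exist but
default to shared depths). Passing recovery tests therefore shows the
statistics behave correctly under the assumed zero-inflated
Dirichlet-multinomial structure — not that classification or chimera
artifacts in real data are handled, which are upstream concerns.

## Numerical conventions

* Output TSVs use 6 significant digits; reruns with the same seed are
  byte-identical.
* All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence` splits.
* Simulated depth draws land in [388, 3,065] by clipping, so extreme
  log-normal tails accumulate at the bounds rather than being redrawn.
* A sample drawing no present taxa is redrawn (bounded at 20 attempts)
  before failing with a diagnostic.

## Problem sizes in tests

The test suite runs replicate-based checks at reduced sizes (20
replicates, 500-tree forests) and the acceptance suite at the full
sizes: 100-replicate recovery and separation experiments, 2,000-taxon
null calibrations, and 10⁵-relabeling permutation comparisons. The
complete suite finishes in about a minute on one CPU.

## Known limitations

* The χ² p-values are asymptotic; see the permutation analysis above.
* The prevalence filter and FDR interact: adjusted p-values are
  conditional on the retained set, as in the per-comparison analyses
  the pipeline mirrors.
* OTU identity by exact taxonomy string means classifier granularity
  determines resolution; no rank-aware merging is attempted.
* The pipeline assumes single-end, pre-classified reads; assembly,
  chimera removal and taxonomic classification are out of scope.
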
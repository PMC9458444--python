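# Methods

## Model

The observable is per-nucleotide rRNA fragment coverage from Ribo-seq,
organized on a single concatenated coordinate axis over the species' rRNAs
(default order 28S, 18S, 5.8S, 5S; 1-based within each rRNA, 0-based
concatenated internally). The working hypothesis is a protection-change
model: a between-condition difference in the incorporation of ribosomal
protein R changes RNase accessibility, hence fragment coverage, specifically
at rRNA positions structurally close to R. The method therefore asks whether
per-position abundance changes concentrate in R's structure-derived contact
set, for every R, without interpreting the direction of the change (a gain
and a loss of an RP both perturb accessibility; calling direction from
fragment data alone is not supported).

## Structure-derived contact sets

* Reference atoms: N1 for rRNA residues, alpha carbon for protein residues.
  Residues without an N1 atom (unresolved bases, ligands) are missing for
  all RPs; there is no fallback atom. All polypeptide chains are RP
  candidates unless listed in an explicit deny-list (bound factors etc.).
* The proximity matrix holds min-distances d(R, i) in Å; building it checks
  that the structure chain sequence matches the FASTA reference (≥99%
  identity over resolved residues) so structure numbering and mapping
  coordinates agree.
* Cross-species transfer uses per-rRNA global pairwise alignment (match +2,
  mismatch −1, gap open −5, gap extend −1; the contract is the residue
  correspondence, not one particular optimal alignment). Aligned residues
  copy d; target insertions are linearly interpolated per RP between the
  nearest aligned flanks within the same rRNA, copy the single resolved
  flank when the other is missing, and stay missing when both are.
  Interpolation acts in distance space; no 3D re-embedding.
* Contact threshold τ: the 5% pooled quantile (type-7, linear interpolation)
  of all present matrix entries — one global Å threshold for all RPs, ≈27.4 Å
  on the human 80S structure. A per-RP-percentile mode exists for
  sensitivity analysis (`percentile` applied per row is not default).
* Sets are ordered by ascending distance (ties by ascending position) and
  capped at K = 360, 5% of the human rRNA length. τ's percentile and K are
  independent knobs even though both derive from the same 5% figure.
* Backgrounds: B = 100 circular translations of the contact set by b·s
  (mod L), b = 1..B, with s a species preset (human 71 nt, mouse 67 nt) or
  round(0.01·L) otherwise. Shifted positions may fall on structurally
  unresolved or filtered coordinates; they are dropped later by intersection
  with the analysis universe. A warning is emitted when B·s ≥ L (a shift can
  complete a full turn and reproduce the original set).

## Positional quantification

Coverage is full-read per-base: every reference position under an aligned
block of a counted read is incremented (deletions/skips are not). Defaults
count primary, mapped, non-QC-fail, sense-strand alignments and keep
duplicates, because Ribo-seq fragments are legitimately duplicated; an
optional fragment-length window (e.g. 19–35 nt) is available. bedGraph input
(0-based half-open, integer values) is the equivalent entry point for
pre-computed coverage. Exactly two condition groups are required; a
single-replicate group triggers a fixed conservative dispersion (0.2) and a
warning. Low-count filtering retains positions with mean raw count across
all samples ≥ 1 (cutoff configurable); filtering happens before
normalization, on raw means.

## Differential abundance

A deliberate simplification of the standard NB differential-expression
machinery, calibrated by simulation rather than aiming at bit-compatibility:

* Size factors: median-of-ratios over positions nonzero in every sample,
  rescaled to geometric mean 1; library-size fallback (with warning) when no
  such position exists.
* Dispersions: per-position method-of-moments from normalized counts (pooled
  within-group variance), a trend α(μ) = a0 + a1/μ fitted across positions
  by trimmed least squares, log-space shrinkage of the per-position estimate
  toward the trend, and a floor at the trend itself. The floor is the key
  calibration device: with ~4 residual df a below-trend estimate is
  indistinguishable from sampling noise, and plugging such estimates into a
  normal Wald test inflates the type-I error (~0.09 at nominal 0.05 in 3v3
  simulations); flooring at the trend restores ~0.04. Above-trend estimates
  are kept — they carry real per-position signal. Global floor 1e−8.
* Per position, an NB GLM with log link, size-factor offsets and a condition
  indicator is fitted by vectorized IRLS; coefficients are capped at ±30
  (natural log) so degenerate positions (a group all zero) park at a
  boundary instead of diverging. The Wald SE uses the information matrix at
  the fit with fitted means floored at 0.5, which keeps the SE finite and
  the test conservative at boundary fits without biasing regular ones.
  Conditions are oriented lexicographically (log2FC is second-vs-first
  level), so swapping labels exactly negates every log2FC and preserves
  p-values. Non-converged positions get missing p and are excluded from the
  BH adjustment, which runs across retained positions.
* Ranking score, exactly as printed by the method this package implements:
  `|log2FC| · max(−log10 padj, 5)`. The max is a floor: every position with
  padj ≥ 1e−5 gets multiplier exactly 5, so ordering among those positions
  is by |log2FC| alone. A config flag offers min() (a cap) instead, because
  the floor semantics are surprising; the default remains the floor. padj is
  clamped at 1e−300 before the log; missing padj counts as 1.

Sample similarity (QC) is a PCA of log2(normalized count + 1) on retained
positions; coordinates and explained-variance fractions are reported.

## Enrichment

* Positions are ranked by descending score, ties by ascending position.
* ES: weighted Kolmogorov–Smirnov running sum with weight exponent 1 — hits
  step by |score|/Σ|set scores|, misses by 1/(N − k); ES is the signed
  extremum (positive side wins an exact tie). Sets whose scores are all zero
  fall back to uniform hit steps.
* NES (ES1): null ES from n_perm = 1000 random same-size position sets drawn
  from the universe (one shared, seeded permutation pool; null distributions
  cached per set size); ES is divided by the mean |null ES| of matching
  sign. Permutation p uses the same-sign tail with +1 smoothing. Sets whose
  sign has no null mass get a missing NES.
* ES2: z-score of the RP's NES against its backgrounds' NES (sample sd,
  missing values dropped). When the RP set and its backgrounds share the
  same effective size, the NES normalization constant cancels and ES2 is
  exactly independent of the permutation seed — a useful stability property.
* ORA: upper-tail hypergeometric test of significant positions
  (padj < 0.05 and |log2FC| > 0.5, configurable) within the contact set.
* Universe = retained positions; contact and background sets are intersected
  with it for all three tests. BH for the set-enrichment and ORA p-values
  runs across the RP sets only; backgrounds never enter multiple testing.
  Candidates satisfy ES2 ≥ 1 (inclusive); ES1 and ORA are reported as triage
  axes but do not gate the call. Output is sorted by ES2 descending.

### Null behaviour of the candidate rule

Under a global null the contact set and its circular-shift backgrounds are
exchangeable, so ES2 behaves like a studentized score of one exchangeable
draw against B others: approximately t(B−1)·√(1+1/B). Its exceedance
probability at the default threshold 1 is therefore ≈16% per RP — about one
of six toy RPs is flagged in a typical null run. This is a property of the
rule itself, not an implementation artifact; the background-vs-sibling
z-scores confirm correct null behaviour (mean ≈ 0, sd ≈ 1). Candidate calls
should accordingly be read as a ranking device with a soft threshold, not as
an error-controlled test — the permutation and ORA p-values carry the
calibrated significance statements.

## Synthetic data generator

The generator emulates the protection-change model: NB counts around a
log-normal positional baseline (σ = 1 so coverage spans ~2 orders of
magnitude, mean = depth), with the condition effect a multiplicative
2^log2FC shift confined to a seeded random subset of the target RP's contact
positions. Defaults are the simulated study conditions used throughout the
tests: 3 samples per group, depth 50, dispersion 0.1, effect log2FC 1.5 at
60% of the target's contacts — only a fraction of contacts is affected
because in real data only hotspots within an RP's vicinity change. The toy
structure places one rRNA chain on a 3D helix and clusters each RP's alpha
carbons ~10 Å outside a distinct residue range, so contact sets are
localized by construction; files are byte-deterministic under the seed.

What the generator does **not** emulate — RNase sequence specificity,
read-length selection artifacts, rRNA-depletion dropout, positional
autocorrelation of coverage, overlapping RP footprints of a real ribosome —
bounds what passing tests show: recovery results demonstrate the pipeline's
statistical machinery, not robustness to protocol-specific biases of real
Ribo-seq libraries.

## Problem sizes and numerical choices

Simulation-based checks run on a 640-nt toy rRNA with 6 RPs (contact sets of
~30 positions), 2000-position null matrices for Wald calibration, 1000
permutations, 100 background sets, and 20 seeds for the end-to-end recovery
and null experiments; these sizes give stable estimates of the reported
rates while keeping the full study fast. Quantiles are type-7; background
shift arithmetic is modulo L on the concatenated axis; the ±30 coefficient
cap bounds fold changes at ±43 log2 units; PCA uses exact SVD.

## Known limitations

* Structurally unresolved rRNA segments are excluded; a single structure is
  used (no conformational ensembles).
* Two-condition designs only; no paired or time-course models, no log2FC
  shrinkage.
* Contact-set definition is deliberately crude (global τ, hard cap); refined
  data-driven definitions are future work.
* Neighbouring RPs share rRNA neighbourhoods, so a true change at one RP can
  co-flag its neighbours; the method does not deconvolve them.
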
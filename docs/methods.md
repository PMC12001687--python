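# Methods

## Model

The pipeline scores genes by how far their mean raw count λ_j sits above
the value predicted from their positive ratio f_j (the fraction of cells
with count ≥ 1). For a gene whose counts are i.i.d. Poisson(λ) across
cells, f = 1 − e^(−λ) exactly, so λ(f) = −ln(1 − f); at low expression
the curve degenerates to λ ≈ f. Real data deviate from the Poisson curve
in a smooth, dataset-specific way, so the prediction is estimated
nonparametrically: a LOESS regression of λ on f fitted on the genes
themselves, using the local gene background as the reference. A gene whose
λ exceeds the local prediction beyond what its neighborhood's residual
spread explains is treated as carrying biological signal (typically,
expression restricted to a cell subpopulation).

The statistics are computed on **raw counts**. Per gene j over c cells:
λ_j = (1/c)·Σ_i X_ij and f_j = (1/c)·Σ_i min(1, X_ij). Genes detected in
fewer than `min_cells = 3` cells are removed before any fitting and never
scored.

## The smoother

LOESS here is local-linear (degree 1) with the tricube kernel
w(d) = (1 − (d/h)³)³. For each evaluation point the window holds the
q = max(⌈α·n⌉, 4) nearest genes by |f_k − f_j| (ties broken toward the
lower index in the f-sorted order), h being the largest distance in the
window. Degree 1 is the default because the curve is monotone with mild
curvature, 200-gene windows make local quadratics noisy, and the low-f
limit is exactly linear; the degree is exposed as `loess_degree` for
experimentation. Positive ratios are lattice-valued (f = k/c), so windows
and fitted values depend on f_j only through its value; the engine solves
one local weighted least squares problem per *unique* f and broadcasts,
which keeps genome-scale fits (20,000 genes) in single-digit seconds
without changing any result (oracle-verified against a per-point solve).

Degenerate windows are handled explicitly: if all window f-values
coincide, the fit is the local weighted mean; if masking empties a window
of positive weight, the prediction falls back to the nearest
positively-weighted genes. Every gene always receives a finite fitted
value.

## Span selection by BIC

Candidate spans are α ∈ {0.01, 0.02, …, 0.10}. At ~20,000 genes this
brackets local windows of roughly 200 to 2,000 genes — small enough to
track curvature at high f, large enough to avoid interpolation. For each
candidate the smoother is fitted with unit weights and scored by

    BIC = n·ln(RSS/n) + k·ln(n)

where n is the number of genes in the regression, RSS the sum of squared
residuals, and k the equivalent degrees of freedom, computed as the trace
of the smoother's hat matrix (accumulated point-wise from each local fit's
own hat diagonal; no n×n matrix is materialized). The minimizing span
wins; exact ties go to the larger (smoother) span. Span selection happens
once, on the unmasked configuration, and the same span is reused for both
regression rounds. RSS = 0 marks a span as degenerate (interpolating) and
excludes it. A user-supplied span bypasses the search.

## Two-round robustness

The round-1 fit is contaminated by exactly the genes the method wants to
find, so a second round masks them. A gene is flagged as an outlier when
its round-1 residual deviates from the **local median** by more than
`outlier_k = 6` times the **local MAD**, the locality being all genes
within `outlier_halfwidth = 0.1` of its f. Choices embedded here:

* the rule is two-sided (deviation from the median, not raw residual
  magnitude), the standard robust reading, protecting the refit against
  both inflated and deflated residuals;
* the MAD is unscaled (no 1.4826 consistency factor) — the large
  multiplier 6 absorbs the scale;
* the inequality is strict: a deviation exactly at 6×MAD is not flagged;
* round-1 robustness is exactly this hard 0/1 masking rule, not a
  continuous biweight downweighting.

Round 2 refits with weight 0 on flagged genes and on near-saturated genes
(f > `fmax` = 0.99, where f carries almost no information about λ), weight
1 elsewhere. Masking affects **fitting only**: masked genes still receive
round-2 fitted values, residuals, Z-scores and ranks — the top of the final
ranking is typically dominated by round-1 outliers, by design.

## Standardization and ranking

Residual spread grows with f, so raw residuals are not comparable across
the axis. Genes are sorted by f (ties by λ, then gene id, making window
membership a deterministic function of the data rather than of input row
order), and each gene's residual is standardized against the mean and
sample (n−1) standard deviation of the residuals in a window of
`z_window = 100` genes on either side (201 genes interior; truncated, not
shifted, at the edges). A zero-spread window yields Z = 0, with a relative
tolerance of 1e−13 on the window sd so that bitwise-constant residuals do
not produce noise-driven Z-scores. Ranking uses **signed** Z descending
(ties: λ descending, then gene id) — the working hypothesis concerns genes
*above* the curve, so under-expressed deviations are not promoted — and
the selection is the top `n_top = 1000` genes, or all genes when fewer are
scored.

## Synthetic data

The generator emulates the two regimes the model distinguishes:

* **background**: per-gene rate log-uniform on [0.001, 10] (spanning the
  empty-to-saturated f range), counts i.i.d. Poisson per cell — these
  genes populate the curve λ = −ln(1 − f);
* **markers**: a two-population on/off model — Poisson(rate 20) in a fixed
  random 5% of cells, zero elsewhere — the simplest mechanism that
  decouples λ (≈ 1.0) from f (≈ 0.05) and places a gene above the curve
  (the curve value at f = 0.05 is ≈ 0.051).

Defaults for recovery experiments: 5,000 background genes, 100 markers,
1,000 cells. All draws flow through NumPy's PCG64 generator, so a fixed
seed reproduces matrices bit-identically across platforms; combined
datasets derive sub-seeds via `SeedSequence`.

What the generator deliberately omits: library-size variation, negative
binomial overdispersion, batch effects, ambient RNA, gene–gene
correlation. Passing the recovery tests therefore shows the pipeline
correctly implements its model and separates its two regimes — not that it
outperforms alternatives on real tissue, where overdispersion lifts the
whole cloud above the Poisson curve and the empirical LOESS reference (not
the closed form) is what absorbs it.

## Numerical choices and edge cases

* Local WLS in closed form (centered at the evaluation point, so the
  prediction is the intercept); near-singular spread (Sxx ≤ 1e−12 relative)
  falls back to the weighted mean.
* Hat diagonals are clipped conceptually to [0, 1] by construction of the
  tricube weights; edf is their sum over positively-weighted genes.
* Minimum window of 4 genes guards tiny inputs; fewer than 4 genes passing
  the filter (or retaining positive weight after masking) is an error with
  a clear diagnostic, not a silent degenerate fit.
* The pipeline contains no randomness: identical input and configuration
  produce byte-identical output, and permuting input gene rows leaves the
  selected set unchanged.

## Problem sizes used in validation

Curve-recovery checks run at 20,000 genes × 2,000 cells (one simulation,
shared across checks); marker-recovery checks at 5,100 genes × 1,000 cells
over 10 seeds. Both complete in well under a minute on one CPU. These
sizes match the regimes the span grid was designed around
(mammalian-genome gene counts) while keeping the validation suite quick.

## Known limitations

* The Poisson assumption is a noise floor, not a data model; systematic
  overdispersion shifts the fitted curve rather than breaking the method,
  but genes informative through *variance* at an unremarkable mean are
  invisible to it.
* Near f = 1 the positive ratio saturates and carries no information about
  λ; such genes are masked from fitting (f > 0.99) and effectively cannot
  be selected on merit there.
* Windowed Z-scores at the extreme low-f edge are standardized against
  few, highly discrete neighbors; isolated low-f genes can reach large Z
  from tiny absolute residuals. The detection filter (≥ 3 cells) bounds,
  but does not eliminate, this effect.
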
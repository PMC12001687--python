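# glp-select

Feature selection for single-cell RNA-seq: pick the genes whose mean
expression exceeds what their **positive ratio** predicts.

## The problem and the idea

Downstream single-cell analysis (clustering, trajectory inference,
differential expression) works best on a small subset of informative genes.
Most selection methods rank genes by variance-style statistics. This
package instead exploits the tight relationship between a gene's **mean
raw count** λ and its **positive ratio** f — the fraction of cells in
which the gene is detected at all (1 − dropout rate).

Under a Poisson noise model with per-gene rate λ,

```
f = P(X ≥ 1) = 1 − e^(−λ)        ⇔        λ = −ln(1 − f)
```

and for small λ, f ≈ λ (first-order Taylor expansion). A gene expressed
uniformly across cells therefore sits *on* this curve; a gene expressed
strongly in a cell subpopulation has a high mean at a low positive ratio
and sits *above* it. Those are the genes worth keeping.

The pipeline makes the curve empirical rather than parametric:

1. **Span selection.** A LOESS smoother (local-linear, tricube kernel) of
   λ on f is fitted at each span α ∈ {0.01, …, 0.10}; the span minimizing
   `BIC = n·ln(RSS/n) + k·ln(n)` is chosen, where k is the equivalent
   degrees of freedom (trace of the smoother's hat matrix).
2. **Round-1 fit** with that span, all genes weighted equally.
3. **Robust masking.** Genes whose round-1 residual deviates from the
   local median by more than 6× the local MAD (neighborhood: all genes
   within ±0.1 in f), and genes with f > 0.99, get weight zero.
4. **Round-2 fit** with the masked weights, same span. Every gene — masked
   or not — still receives a fitted value and residual e_j = λ_j − λ̂_j.
5. **Local standardization and ranking.** Residuals are converted to
   Z-scores within a sliding window of 100 f-sorted neighbors on each
   side; genes are ranked by Z descending and the top 1,000 are selected.

Genes detected in fewer than 3 cells are excluded up front.

## Worked example

`examples/simulate_and_select.py` simulates 5,000 Poisson background genes
plus 100 marker genes (Poisson rate 20 in 5% of 1,000 cells, zero
elsewhere) and runs the pipeline with defaults:

```
selected span: 0.04
genes scored: 4541 (of 5100 input)
round-1 outliers: 564, zero-weighted in round 2: 882
markers recovered in top-1000: 100/100
```

All 100 planted markers are recovered: their means lie far above the
fitted curve at their positive ratio, so their windowed residual Z-scores
dominate the ranking. `examples/span_selection.py` prints the BIC trace
behind step 1, and `examples/curve_recovery.py` shows that on
background-only data the fitted curve tracks −ln(1 − f) to a mean absolute
error of ~0.005.

## Library and command line

The package is a library first:

```python
from glp import GLPConfig, read_counts, run_glp, write_ranking

matrix = read_counts("filtered_feature_bc_matrix/")   # 10x-style mtx dir or dense TSV
scores = run_glp(matrix, GLPConfig())                  # defaults as above
write_ranking(scores, "scores.tsv", top_path="scores.top.tsv")
scores.selected_genes                                  # top-1,000 gene ids
```

A thin CLI wraps the same calls:

```sh
glp select --counts filtered_feature_bc_matrix/ --out scores.tsv
glp select --counts dense.tsv --format dense --span 0.07 --n-top 500 --out scores.tsv
glp simulate --genes 5000 --cells 1000 --markers 100 --seed 7 --out-dir sim/
```

`glp select` writes the full rank-ordered score table, a top-N companion
file, and a flat-text manifest recording every resolved parameter and the
per-span BIC table, so any run is reproducible from its manifest.

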
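"""Span selection: the BIC trace over the candidate grid.

Fits the smoother at each span in the default grid (0.01..0.10) on a
simulated background-only dataset and prints the BIC per span. The chosen
span minimizes BIC, trading local flexibility (small spans, more equivalent
degrees of freedom) against smoothness.
"""

from glp import GLPConfig, run_glp, simulate_background

matrix, _ = simulate_background(n_genes=8000, n_cells=1000, seed=11)
scores = run_glp(matrix, GLPConfig())

print("span    BIC")
for span, bic in sorted(scores.span_bics.items()):
    marker = "  <- selected" if span == scores.span else ""
    print(f"{span:.2f}  {bic:10.1f}{marker}")
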
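"""The gene-selection pipeline: two-round robust LOESS on the f-lambda curve.

The working hypothesis: under a Poisson noise model the positive ratio f
of a gene with mean expression lambda satisfies f = 1 - exp(-lambda), so
mean expression is predictable from the positive ratio alone. Genes whose
mean lies well above the locally-fitted curve at their positive ratio are
carrying signal beyond sampling noise (e.g. genes expressed strongly in a
cell subpopulation) and are the ones worth keeping.

Pipeline stages, in order:

1. span selection by BIC over the default grid (unit weights);
2. round-1 LOESS fit of lambda on f;
3. outlier flagging: |residual - local median| > k * local MAD, the local
   neighborhood being all genes within ``halfwidth`` of the gene's f;
4. round-2 LOESS with zero weight on outliers and near-saturated genes
   (f > 0.99), the same span; every gene, masked or not, still receives a
   round-2 fitted value and residual;
5. residual standardization in a sliding window of 100 f-sorted neighbors
   on either side, then ranking by Z-score descending and selection of the
   top 1,000 genes (defaults throughout).

Masking affects fitting only, never eligibility: the top-ranked genes are
typically exactly the round-1 outliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import CountMatrix
from .loess import DEFAULT_SPAN_GRID, LoessFit, loess_fit, select_span
from .stats import compute_gene_stats, filter_low_detection

__all__ = [
    "GLPConfig",
    "GLPScores",
    "detect_outliers",
    "second_round_weights",
    "standardize_residuals",
    "rank_genes",
    "run_glp",
]


@dataclass
class GLPConfig:
    """Tunable parameters of the selection pipeline (defaults as published).

    Attributes
    ----------
    span
        LOESS span, or ``"auto"`` to minimize BIC over ``span_grid``.
    span_grid
        Candidate spans for automatic selection (0.01..0.10 step 0.01).
    min_cells
        Detection filter: genes seen in fewer cells are dropped (3).
    outlier_k
        Robust outlier multiplier: flag genes whose round-1 residual
        deviates from the local median by more than k * local MAD (6).
    outlier_halfwidth
        Half-width, on the positive-ratio axis, of the MAD neighborhood (0.1).
    fmax
        Genes with positive ratio strictly above this are masked out of the
        round-2 fit (0.99).
    z_window
        Number of f-sorted neighbor genes on either side used to
        standardize residuals (100).
    n_top
        Size of the selected gene set (1000).
    loess_degree
        Local polynomial degree of the smoother (1).
    """

    span: float | str = "auto"
    span_grid: tuple[float, ...] = DEFAULT_SPAN_GRID
    min_cells: int = 3
    outlier_k: float = 6.0
    outlier_halfwidth: float = 0.1
    fmax: float = 0.99
    z_window: int = 100
    n_top: int = 1000
    loess_degree: int = 1

    def __post_init__(self) -> None:
        if self.span != "auto":
            s = float(self.span)
            if not 0 < s <= 1:
                raise ValidationError(f"span must be in (0, 1] or 'auto', got {self.span}")
            self.span = s
        if self.min_cells < 1 or self.n_top < 1 or self.z_window < 1:
            raise ValidationError("min_cells, n_top and z_window must be positive")
        if self.outlier_k <= 0 or self.outlier_halfwidth <= 0:
            raise ValidationError("outlier_k and outlier_halfwidth must be positive")
        if not 0 < self.fmax < 1:
            raise ValidationError(f"fmax must be in (0, 1), got {self.fmax}")


@dataclass
class GLPScores:
    """Complete per-gene scoring output, rank-ordered.

    ``table`` columns: gene, positive_ratio, mean_expr, fitted, residual,
    outlier, z_score, rank — sorted by rank (Z-score descending). The
    selected set is the first ``min(n_top, n)`` rows.
    """

    table: pd.DataFrame
    n_top: int
    span: float = None
    span_bics: dict = field(default_factory=dict)
    n_filtered_out: int = 0
    n_outliers: int = 0
    n_zero_weight: int = 0
    round2: LoessFit = field(default=None, repr=False)

    @property
    def selected(self) -> pd.DataFrame:
        """The top-``n_top`` genes by residual Z-score."""
        return self.table.head(min(self.n_top, len(self.table)))

    @property
    def selected_genes(self) -> list[str]:
        return self.selected["gene"].tolist()


def detect_outliers(
    f: np.ndarray,
    residuals: np.ndarray,
    k: float = 6.0,
    halfwidth: float = 0.1,
) -> np.ndarray:
    """Flag genes whose residual deviates from the local median by > k * MAD.

    The neighborhood of gene j is every gene with |f - f_j| <= halfwidth
    (always including j). MAD is the unscaled median absolute deviation
    from the local median; the inequality is strict, so a deviation exactly
    at k * MAD is not flagged.
    """
    f = np.asarray(f, dtype=np.float64)
    residuals = np.asarray(residuals, dtype=np.float64)
    if f.size != residuals.size:
        raise ValidationError("f and residuals lengths differ")
    if k <= 0 or halfwidth <= 0:
        raise ValidationError("k and halfwidth must be positive")
    flags = np.zeros(f.size, dtype=bool)
    # neighborhoods depend on f only through its value: one median/MAD per
    # unique positive ratio
    for f0 in np.unique(f):
        in_win = np.abs(f - f0) <= halfwidth
        r = residuals[in_win]
        med = np.median(r)
        mad = np.median(np.abs(r - med))
        here = f == f0
        flags[here] = np.abs(residuals[here] - med) > k * mad
    return flags


def second_round_weights(
    outliers: np.ndarray, f: np.ndarray, fmax: float = 0.99
) -> np.ndarray:
    """Round-2 masking weights: 0 for outliers and for f > fmax, else 1."""
    outliers = np.asarray(outliers, dtype=bool)
    f = np.asarray(f, dtype=np.float64)
    if outliers.size != f.size:
        raise ValidationError("outliers and f lengths differ")
    w = np.where(outliers | (f > fmax), 0.0, 1.0)
    if np.count_nonzero(w) < 4:
        raise ValidationError(
            "fewer than 4 genes retain positive weight after masking; cannot refit"
        )
    return w


def standardize_residuals(
    f: np.ndarray, residuals: np.ndarray, window: int = 100
) -> np.ndarray:
    """Sliding-window Z-scores of residuals along the f-sorted gene order.

    For the gene at sorted position j the window is positions
    max(0, j-window) .. min(n-1, j+window) inclusive (truncated at the
    edges, never shifted). Z_j = (e_j - mean) / sd with the sample (n-1)
    standard deviation; a zero-spread window gives Z_j = 0.
    """
    f = np.asarray(f, dtype=np.float64)
    e = np.asarray(residuals, dtype=np.float64)
    if np.any(np.diff(f) < 0):
        raise ValidationError("genes must be sorted ascending by positive ratio")
    if window < 1:
        raise ValidationError("window must be >= 1")
    n = e.size
    z = np.zeros(n)
    for j in range(n):
        lo, hi = max(0, j - window), min(n - 1, j + window)
        seg = e[lo : hi + 1]
        if seg.size < 2:
            continue
        mu = seg.mean()
        sd = seg.std(ddof=1)
        # zero-spread convention, robust to float noise in the window sd
        if sd > 1e-13 * np.abs(seg).max():
            z[j] = (e[j] - mu) / sd
    return z


def rank_genes(table: pd.DataFrame, n_top: int = 1000) -> pd.DataFrame:
    """Order genes by Z-score descending and assign ranks 1..n.

    Ties break by mean expression descending, then gene id ascending, so
    the ranking is a deterministic function of the score table alone.
    """
    order = np.lexsort(
        (
            table["gene"].to_numpy(),
            -table["mean_expr"].to_numpy(),
            -table["z_score"].to_numpy(),
        )
    )
    ranked = table.iloc[order].reset_index(drop=True)
    ranked["rank"] = np.arange(1, len(ranked) + 1)
    return ranked


def run_glp(m: CountMatrix, cfg: GLPConfig | None = None) -> GLPScores:
    """Run the full selection pipeline on a raw count matrix.

    Stages: per-gene stats -> detection filter -> sort by positive ratio ->
    span selection (skipped for a numeric ``cfg.span``) -> round-1 fit ->
    local-MAD outlier flags -> round-2 masked fit -> residual Z-scores ->
    ranking. Fully deterministic: identical input and config give
    byte-identical output.
    """
    cfg = cfg or GLPConfig()
    stats = compute_gene_stats(m)
    kept = filter_low_detection(stats, cfg.min_cells)
    n_filtered_out = len(stats) - len(kept)
    if len(kept) < 4:
        raise ValidationError(
            f"only {len(kept)} genes detected in >= {cfg.min_cells} cells; "
            "at least 4 are required to fit the expression curve"
        )

    # deterministic f-ascending order; ties by mean then gene id so window
    # membership never depends on input row order
    gene_id = kept["gene_id"].to_numpy()
    lam = kept["lambda_mean"].to_numpy()
    f = kept["positive_ratio"].to_numpy()
    order = np.lexsort((gene_id, lam, f))
    gene_id, lam, f = gene_id[order], lam[order], f[order]

    span_bics: dict[float, float] = {}
    if cfg.span == "auto":
        span, span_bics = select_span(f, lam, cfg.span_grid, degree=cfg.loess_degree)
    else:
        span = float(cfg.span)

    round1 = loess_fit(f, lam, span, degree=cfg.loess_degree)
    outliers = detect_outliers(f, round1.residuals, cfg.outlier_k, cfg.outlier_halfwidth)
    weights = second_round_weights(outliers, f, cfg.fmax)
    round2 = loess_fit(f, lam, span, obs_weights=weights, degree=cfg.loess_degree)
    z = standardize_residuals(f, round2.residuals, cfg.z_window)

    table = pd.DataFrame(
        {
            "gene": gene_id,
            "positive_ratio": f,
            "mean_expr": lam,
            "fitted": round2.fitted,
            "residual": round2.residuals,
            "outlier": outliers,
            "z_score": z,
        }
    )
    ranked = rank_genes(table, cfg.n_top)
    return GLPScores(
        table=ranked,
        n_top=cfg.n_top,
        span=span,
        span_bics=span_bics,
        n_filtered_out=n_filtered_out,
        n_outliers=int(outliers.sum()),
        n_zero_weight=int(np.count_nonzero(weights == 0)),
        round2=round2,
    )
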
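"""Synthetic count matrices with known ground truth.

Two generators mirror the statistical structure the selection pipeline is
built on:

* background genes: counts drawn i.i.d. Poisson per gene, rates log-uniform
  over several orders of magnitude, so the (f, lambda) cloud traces the
  curve lambda = -ln(1 - f);
* marker genes: a two-population (on/off) model — Poisson at a high rate in
  a fixed small fraction of cells, zero elsewhere — the simplest mechanism
  that decouples mean expression from positive ratio and places a gene
  above the curve.

All randomness flows through :func:`numpy.random.default_rng` (PCG64), so a
fixed seed reproduces matrices bit-identically across platforms.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ValidationError
from .io import CountMatrix

__all__ = [
    "theoretical_curve",
    "simulate_background",
    "simulate_markers",
    "simulate_dataset",
]

_CHUNK = 512  # genes per dense block while building the sparse matrix


def theoretical_curve(f):
    """Poisson mean implied by a positive ratio: lambda = -ln(1 - f).

    Inverts f = P(X >= 1) = 1 - exp(-lambda). For small f this is ~ f
    (the Taylor regime where mean expression and positive ratio coincide).
    """
    f = np.asarray(f, dtype=np.float64)
    if np.any(f < 0) or np.any(f >= 1):
        raise ValidationError("positive ratio must lie in [0, 1)")
    out = -np.log1p(-f)
    return float(out) if out.ndim == 0 else out


def _cell_ids(n_cells: int) -> list[str]:
    return [f"cell_{i:06d}" for i in range(1, n_cells + 1)]


def _rows_to_csr(blocks: list[np.ndarray], n_cells: int) -> sp.csr_matrix:
    return sp.vstack([sp.csr_matrix(b) for b in blocks], format="csr")


def simulate_background(
    n_genes: int,
    n_cells: int,
    rate_range: tuple[float, float] = (0.001, 10.0),
    seed: int = 0,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Pure-Poisson background genes with log-uniform rates.

    Each gene j gets a rate drawn log-uniformly on ``rate_range`` and
    counts X_ij ~ Poisson(rate_j) independently across cells. Returns the
    count matrix and a truth table (gene_id, is_marker=False, true_rate,
    expressing_fraction=1).
    """
    lo, hi = rate_range
    if not (0 < lo < hi):
        raise ValidationError(f"need 0 < lo < hi, got rate_range={rate_range}")
    if n_genes < 1 or n_cells < 1:
        raise ValidationError("n_genes and n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    rates = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_genes))
    blocks = []
    for start in range(0, n_genes, _CHUNK):
        block_rates = rates[start : start + _CHUNK]
        counts = rng.poisson(block_rates[:, None], size=(block_rates.size, n_cells))
        blocks.append(counts.astype(np.int64))
    matrix = CountMatrix(
        gene_ids=[f"bg_{i:06d}" for i in range(1, n_genes + 1)],
        cell_ids=_cell_ids(n_cells),
        counts=_rows_to_csr(blocks, n_cells),
    )
    truth = pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "is_marker": False,
            "true_rate": rates,
            "expressing_fraction": 1.0,
        }
    )
    return matrix, truth


def simulate_markers(
    n_markers: int,
    n_cells: int,
    expressing_fraction: float = 0.05,
    rate_hi: float = 20.0,
    seed: int = 0,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Two-population marker genes: high Poisson rate in a small cell subset.

    Each marker draws counts ~ Poisson(rate_hi) in a fixed random subset of
    round(expressing_fraction * n_cells) cells and is exactly zero in all
    others, so its expected mean expressing_fraction * rate_hi sits far
    above the Poisson curve at its positive ratio when rate_hi is large.
    """
    if not 0 < expressing_fraction < 1:
        raise ValidationError("expressing_fraction must be in (0, 1)")
    if rate_hi <= 0:
        raise ValidationError("rate_hi must be positive")
    if n_markers < 1 or n_cells < 1:
        raise ValidationError("n_markers and n_cells must be >= 1")
    n_expr = int(round(expressing_fraction * n_cells))
    if n_expr == 0:
        raise ValidationError(
            f"expressing_fraction {expressing_fraction} rounds to zero cells of {n_cells}"
        )
    rng = np.random.default_rng(seed)
    rows = np.zeros((n_markers, n_cells), dtype=np.int64)
    for j in range(n_markers):
        on = rng.choice(n_cells, size=n_expr, replace=False)
        rows[j, on] = rng.poisson(rate_hi, size=n_expr)
    matrix = CountMatrix(
        gene_ids=[f"marker_{i:04d}" for i in range(1, n_markers + 1)],
        cell_ids=_cell_ids(n_cells),
        counts=sp.csr_matrix(rows),
    )
    truth = pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "is_marker": True,
            "true_rate": rate_hi,
            "expressing_fraction": expressing_fraction,
        }
    )
    return matrix, truth


def simulate_dataset(
    n_background: int,
    n_markers: int,
    n_cells: int,
    rate_range: tuple[float, float] = (0.001, 10.0),
    expressing_fraction: float = 0.05,
    rate_hi: float = 20.0,
    seed: int = 0,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Stack background and marker genes over a shared set of cells.

    Sub-seeds for the two generators derive deterministically from *seed*
    via :class:`numpy.random.SeedSequence`, so the combined matrix is fully
    reproducible. With ``n_markers=0`` this reduces to the background alone.
    """
    s_bg, s_mk = np.random.SeedSequence(seed).generate_state(2)
    bg, bg_truth = simulate_background(n_background, n_cells, rate_range, seed=int(s_bg))
    if n_markers == 0:
        return bg, bg_truth
    mk, mk_truth = simulate_markers(
        n_markers, n_cells, expressing_fraction, rate_hi, seed=int(s_mk)
    )
    matrix = CountMatrix(
        gene_ids=bg.gene_ids + mk.gene_ids,
        cell_ids=bg.cell_ids,
        counts=sp.vstack([bg.counts, mk.counts], format="csr"),
    )
    truth = pd.concat([bg_truth, mk_truth], ignore_index=True)
    return matrix, truth
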
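"""Per-gene summary statistics and the detection filter.

For gene j over c cells with counts X_ij, the pipeline works on two
per-gene summaries:

    lambda_j = (1/c) * sum_i X_ij          (mean raw count per cell)
    f_j      = (1/c) * sum_i min(1, X_ij)  (positive ratio, = 1 - dropout rate)

For integer counts every nonzero entry is >= 1, so lambda_j >= f_j always.
Genes detected (count >= 1) in fewer than ``min_cells`` cells carry too
little information to place on the f-lambda curve and are dropped before
any fitting.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import CountMatrix

__all__ = ["compute_gene_stats", "filter_low_detection"]


def compute_gene_stats(m: CountMatrix) -> pd.DataFrame:
    """Compute mean expression, positive ratio and detection count per gene.

    Returns a DataFrame with columns ``gene_id``, ``lambda_mean``,
    ``positive_ratio``, ``n_detected``, one row per gene in input order.
    """
    c = m.n_cells
    if c < 1:
        raise ValidationError("count matrix has zero cells")
    counts = m.counts
    lam = np.asarray(counts.sum(axis=1)).ravel() / c
    n_detected = counts.getnnz(axis=1)  # explicit zeros already eliminated
    f = n_detected / c
    table = pd.DataFrame(
        {
            "gene_id": m.gene_ids,
            "lambda_mean": lam,
            "positive_ratio": f,
            "n_detected": n_detected.astype(np.int64),
        }
    )
    # integer counts guarantee mean >= positive ratio; violation means
    # the matrix slipped past validation
    if np.any(table["lambda_mean"].to_numpy() < table["positive_ratio"].to_numpy()):
        raise ValidationError("mean expression below positive ratio: non-count input?")
    return table


def filter_low_detection(table: pd.DataFrame, min_cells: int = 3) -> pd.DataFrame:
    """Drop genes detected in fewer than *min_cells* cells.

    Keeps exactly the rows with ``n_detected >= min_cells``, preserving the
    original gene order. The default of 3 detected cells is the threshold
    below which a gene is excluded from all further analysis.
    """
    if min_cells < 1:
        raise ValidationError(f"min_cells must be >= 1, got {min_cells}")
    kept = table[table["n_detected"] >= min_cells]
    return kept.reset_index(drop=True)
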
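"""Independent brute-force oracles for the numeric engine.

Each function recomputes a pipeline quantity from its definition by direct
enumeration — per-point weighted least squares for the smoother, a double
loop for local-MAD outliers, explicit slicing for windowed Z-scores —
sharing no code with the implementation under test.
"""

import math

import numpy as np


def wls_window_oracle(x, j, span):
    """Window of gene j: sort all points by (distance, index), take q."""
    x = np.asarray(x, dtype=float)
    n = x.size
    q = min(n, max(math.ceil(span * n), 4))
    d = np.abs(x - x[j])
    order = np.lexsort((np.arange(n), d))  # primary: distance, tie: index
    idx = order[:q]
    return idx, d[idx].max()


def loess_fitted_oracle(x, y, span, obs_weights=None):
    """Per-point local-linear WLS fit, solved independently with lstsq."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    obs_weights = np.ones(n) if obs_weights is None else np.asarray(obs_weights, float)
    fitted = np.empty(n)
    hat = np.zeros(n)
    for j in range(n):
        idx, h = wls_window_oracle(x, j, span)
        d = np.abs(x[idx] - x[j])
        kw = np.ones(idx.size) if h <= 0 else np.clip(1 - (d / h) ** 3, 0, None) ** 3
        w = kw * obs_weights[idx]
        if w.sum() <= 0:
            pos = np.flatnonzero(obs_weights > 0)
            dp = np.abs(x[pos] - x[j])
            porder = np.lexsort((pos, dp))
            take = pos[porder][: min(idx.size, pos.size)]
            idx, w = take, obs_weights[take].astype(float)
        xc = x[idx] - x[j]
        X = np.column_stack([np.ones(idx.size), xc])
        if np.allclose(xc, 0):
            X = X[:, :1]
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(X * sw[:, None], y[idx] * sw, rcond=None)
        fitted[j] = coef[0]
        if obs_weights[j] > 0 and j in idx:
            M = X.T @ (X * w[:, None])
            Minv = np.linalg.pinv(M)
            hat[j] = obs_weights[j] * Minv[0, 0]
    return fitted, hat


def bic_oracle(n_obs, rss, edf):
    return n_obs * math.log(rss / n_obs) + edf * math.log(n_obs)


def span_grid_oracle(x, y, grid):
    """Refit at every grid value, recompute BIC, pick the argmin by hand."""
    best_span, best_bic = None, math.inf
    for span in sorted(grid):
        fitted, hat = loess_fitted_oracle(x, y, span)
        rss = float(np.sum((np.asarray(y, float) - fitted) ** 2))
        if rss <= 0:
            continue
        bic = bic_oracle(len(x), rss, float(hat.sum()))
        if bic <= best_bic:
            best_span, best_bic = span, bic
    return best_span


def local_mad_oracle(f, residuals, k=6.0, halfwidth=0.1):
    """Double loop over genes: local median/MAD and the strict threshold."""
    f = np.asarray(f, float)
    e = np.asarray(residuals, float)
    flags = np.zeros(f.size, dtype=bool)
    for j in range(f.size):
        members = [i for i in range(f.size) if abs(f[i] - f[j]) <= halfwidth]
        r = e[members]
        med = np.median(r)
        mad = np.median(np.abs(r - med))
        flags[j] = abs(e[j] - med) > k * mad
    return flags


def window_z_oracle(residuals, window=100):
    """Explicit slicing for the sliding-window Z-scores."""
    e = np.asarray(residuals, float)
    n = e.size
    z = np.zeros(n)
    for j in range(n):
        seg = e[max(0, j - window): min(n - 1, j + window) + 1]
        if seg.size >= 2 and seg.std(ddof=1) > 0:
            z[j] = (e[j] - seg.mean()) / seg.std(ddof=1)
    return z
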
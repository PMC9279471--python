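"""Shared numerical helpers: seeding, smoothing, thresholds, hashing."""

from __future__ import annotations

import hashlib
import zlib

import numpy as np
from statsmodels.stats.multitest import multipletests

MAX_SEED = 2**31 - 1


def derive_seed(seed: int, name: str) -> int:
    """Derive a stable per-stage seed below 2**31 from a global seed."""
    return zlib.crc32(f"{int(seed)}:{name}".encode()) & MAX_SEED


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def tricube_smooth(x, y, x_eval, span: float = 0.6) -> np.ndarray:
    """Tricube-weighted local linear regression.

    For each evaluation point the nearest ``span``-fraction of the data
    points receive tricube weights and a weighted straight line is fitted.
    Degenerate windows (zero x-spread) fall back to the weighted mean.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x_eval = np.atleast_1d(np.asarray(x_eval, dtype=float))
    n = x.size
    k = max(2, int(np.ceil(span * n)))
    out = np.empty(x_eval.size)
    for i, x0 in enumerate(x_eval):
        d = np.abs(x - x0)
        idx = np.argsort(d, kind="stable")[:k]
        dmax = d[idx].max()
        if dmax == 0:
            out[i] = y[idx].mean()
            continue
        w = (1.0 - (d[idx] / dmax) ** 3) ** 3
        w = np.clip(w, 0.0, None)
        xs, ys = x[idx], y[idx]
        sw = w.sum()
        xm = (w * xs).sum() / sw
        ym = (w * ys).sum() / sw
        sxx = (w * (xs - xm) ** 2).sum()
        if sxx <= 1e-12:
            out[i] = ym
        else:
            slope = (w * (xs - xm) * (ys - ym)).sum() / sxx
            out[i] = ym + slope * (x0 - xm)
    return out


def kde_valley_thresholds(values, n_thresholds: int, grid_size: int = 512):
    """Locate up to ``n_thresholds`` density valleys of a 1-D sample.

    Used for automatic flow-cytometry-style gating: modes of the (log)
    intensity distribution are separated at local minima of a Gaussian KDE.
    Returns thresholds sorted ascending; falls back to quantile cuts when
    the KDE has fewer interior minima than requested.
    """
    from scipy.stats import gaussian_kde

    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 5 or np.ptp(v) == 0:
        return list(np.quantile(v, np.linspace(0, 1, n_thresholds + 2)[1:-1]))
    kde = gaussian_kde(v)
    grid = np.linspace(v.min(), v.max(), grid_size)
    dens = kde(grid)
    interior = np.arange(1, grid_size - 1)
    minima = interior[(dens[interior] < dens[interior - 1]) & (dens[interior] <= dens[interior + 1])]
    if minima.size < n_thresholds:
        qs = np.quantile(v, np.linspace(0, 1, n_thresholds + 2)[1:-1])
        return list(np.sort(qs))
    if minima.size > n_thresholds:
        # keep the deepest valleys
        order = np.argsort(dens[minima], kind="stable")[:n_thresholds]
        minima = np.sort(minima[order])
    return list(grid[minima])


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()
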
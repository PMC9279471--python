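"""Spike-in-aware normalization and highly-variable-gene selection.

Technical size factors come from ERCC spike-in totals, biological size
factors from ring-pooled endogenous counts (deconvolution of pooled
profiles into per-cell factors). Counts are log2(x/factor + 1) normalized;
a smooth mean-variance trend fitted to the spike-ins estimates the
technical component of every endogenous gene's variance, and genes whose
biological (total minus technical) variance clears a threshold at
controlled FDR are selected as highly variable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import bh_adjust, tricube_smooth

DEFAULT_POOL_SIZES = (21, 41, 61, 81, 101)


# ---------------------------------------------------------------------------
# size factors


def spike_size_factors(counts: np.ndarray, spike_mask: np.ndarray,
                       cell_ids=None) -> np.ndarray:
    """Technical size factors: per-cell spike-in totals rescaled to mean 1."""
    spike_mask = np.asarray(spike_mask, bool)
    if spike_mask.sum() < 1:
        raise ValueError("need at least one spike-in row")
    totals = np.asarray(counts)[spike_mask].sum(axis=0).astype(float)
    zero = np.flatnonzero(totals <= 0)
    if zero.size:
        name = cell_ids[zero[0]] if cell_ids is not None else f"column {zero[0]}"
        raise ValueError(f"cell {name} has zero spike-in counts")
    return totals / totals.mean()


def pooled_size_factors(counts: np.ndarray,
                        pool_sizes=DEFAULT_POOL_SIZES) -> np.ndarray:
    """Biological size factors by deconvolution of ring pools.

    Cells are ordered by library size on a ring; each contiguous pool
    contributes one linear equation sum(factors in pool) = median ratio of
    the pooled profile to the average pseudo-cell. The stacked system is
    solved by least squares (with low-weight library-size anchor equations
    for identifiability) and rescaled to mean 1. Falls back to library-size
    factors when there are fewer cells than the smallest pool.
    """
    X = np.asarray(counts, dtype=float)
    n_genes, n_cells = X.shape
    lib = X.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("every cell must have positive library size")
    lib_factors = lib / lib.mean()
    sizes = sorted({min(s, n_cells) for s in pool_sizes})
    if n_cells < min(pool_sizes):
        warnings.warn("fewer cells than the smallest pool size: "
                      "using library-size factors")
        return lib_factors

    order = np.argsort(lib, kind="stable")
    ring = X[:, order]
    pseudo = ring.mean(axis=1)
    expressed = pseudo > 0

    rows, cols, b = [], [], []
    eq = 0
    for k in sizes:
        csum = np.cumsum(np.concatenate([ring, ring[:, : k - 1]], axis=1), axis=1)
        for start in range(n_cells):
            end = start + k
            pooled = csum[:, end - 1] - (csum[:, start - 1] if start else 0)
            ratio = pooled[expressed] / pseudo[expressed]
            r = float(np.median(ratio))
            members = [(start + t) % n_cells for t in range(k)]
            rows.extend([eq] * k)
            cols.extend(members)
            b.append(r)
            eq += 1
    # anchor equations keep the system full rank
    w = 0.1
    A = np.zeros((eq + n_cells, n_cells))
    A[rows, cols] = 1.0
    for c in range(n_cells):
        A[eq + c, c] = w
        b.append(w * lib_factors[order][c])
    sol, *_ = np.linalg.lstsq(A, np.asarray(b), rcond=None)

    factors = np.empty(n_cells)
    factors[order] = sol
    bad = factors <= 0
    if bad.any():
        warnings.warn(f"{int(bad.sum())} non-positive deconvolved factors "
                      "replaced by library-size factors")
        factors[bad] = lib_factors[bad]
    return factors / factors.mean()


def normalize(counts: np.ndarray, factors: np.ndarray,
              spike_mask: np.ndarray | None = None,
              spike_factors: np.ndarray | None = None) -> np.ndarray:
    """log2(count/factor + 1); spike rows use the technical factors."""
    factors = np.asarray(factors, float)
    if (factors <= 0).any():
        raise ValueError("size factors must be positive")
    X = np.asarray(counts, float)
    out = np.log2(X / factors + 1.0)
    if spike_mask is not None and spike_factors is not None:
        spike_factors = np.asarray(spike_factors, float)
        if (spike_factors <= 0).any():
            raise ValueError("size factors must be positive")
        sm = np.asarray(spike_mask, bool)
        out[sm] = np.log2(X[sm] / spike_factors + 1.0)
    return out


# ---------------------------------------------------------------------------
# technical trend


@dataclass
class TrendFit:
    """Smooth mean->variance function on log-normalized expression.

    Evaluation outside the fitted domain returns the boundary value.
    """

    grid: np.ndarray
    values: np.ndarray

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.grid[0]), float(self.grid[-1])

    def __call__(self, x) -> np.ndarray:
        return np.interp(np.asarray(x, float), self.grid, self.values)


def fit_technical_trend(spike_means, spike_vars, span: float = 0.6,
                        method: str = "loess") -> TrendFit:
    """Fit the spike-in mean-variance trend.

    ``loess``: tricube-weighted local linear smooth, clipped at zero, with a
    monotone-decreasing tail enforced by isotonic projection above the
    variance peak. ``parametric``: least-squares fit of
    var = a*m / (m^n + b).
    """
    m = np.asarray(spike_means, float)
    v = np.asarray(spike_vars, float)
    distinct = np.unique(m)
    if distinct.size < 5:
        raise ValueError(
            "need >= 5 spike-ins with distinct means; consider the parametric "
            "fallback (method='parametric', var = a*m/(m^n + b))"
            if distinct.size > 1 else "need >= 5 spike-ins with distinct means")
    order = np.argsort(m, kind="stable")
    m, v = m[order], v[order]
    grid = np.unique(np.concatenate([m, np.linspace(m[0], m[-1], 128)]))

    if method == "parametric":
        from scipy.optimize import curve_fit

        def fam(x, a, b, n):
            return a * x / (x ** n + b)

        p0 = (v.max() * 2, 1.0, 1.5)
        try:
            popt, _ = curve_fit(fam, m, v, p0=p0, maxfev=20000)
            fitted = np.clip(fam(grid, *popt), 0.0, None)
        except RuntimeError as err:  # pragma: no cover - pathological inputs
            raise ValueError(f"parametric trend fit failed: {err}") from err
        return TrendFit(grid=grid, values=fitted)

    fitted = np.clip(tricube_smooth(m, v, grid, span=span), 0.0, None)
    peak = int(np.argmax(fitted))
    if peak < grid.size - 1:
        from sklearn.isotonic import IsotonicRegression

        iso = IsotonicRegression(increasing=False)
        fitted[peak:] = iso.fit_transform(grid[peak:], fitted[peak:])
    return TrendFit(grid=grid, values=fitted)


# ---------------------------------------------------------------------------
# variance decomposition and HVG selection


def decompose_variance(log_expr: np.ndarray, trend: TrendFit,
                       gene_names=None) -> pd.DataFrame:
    """Split each gene's variance into technical (trend) and biological parts.

    The one-sided p-value tests the variance ratio total/technical with the
    smoothed trend treated as the true technical variance, i.e.
    (n-1)*total/tech against a chi-squared(n-1) reference (the limit of the
    F ratio as the denominator degrees of freedom grow; the trend averages
    many spike-ins, so its estimation error is negligible relative to a
    single gene's). FDR is Benjamini-Hochberg across genes.
    """
    if trend is None:
        raise ValueError("technical trend required")
    X = np.asarray(log_expr, float)
    n_genes, n_cells = X.shape
    if n_cells < 2:
        raise ValueError("need >= 2 cells")
    mean = X.mean(axis=1)
    total = X.var(axis=1, ddof=1)
    tech = trend(mean)
    bio = total - tech
    df = n_cells - 1
    p = np.empty(n_genes)
    pos = tech > 0
    p[pos] = stats.chi2.sf(df * total[pos] / tech[pos], df)
    p[~pos] = np.where(total[~pos] > 0, 0.0, 1.0)  # zero-trend edge
    out = pd.DataFrame(
        {
            "mean": mean,
            "total_var": total,
            "tech_var": tech,
            "bio_var": bio,
            "p_value": p,
            "fdr": bh_adjust(p),
        },
        index=(gene_names if gene_names is not None else np.arange(n_genes)),
    )
    return out


def select_hvgs(decomposition: pd.DataFrame, bio_min: float = 0.5,
                fdr_max: float = 0.05) -> list[str]:
    """Genes with bio_var strictly above ``bio_min`` at FDR <= ``fdr_max``.

    Ordered by descending biological variance, ties broken by name.
    """
    if len(decomposition) == 0:
        return []
    keep = decomposition[(decomposition["bio_var"] > bio_min)
                         & (decomposition["fdr"] <= fdr_max)]
    order = np.lexsort((keep.index.astype(str), -keep["bio_var"].to_numpy()))
    return keep.index[order].tolist()
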
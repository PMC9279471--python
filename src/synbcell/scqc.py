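"""Quality filtering of cells along the first principal component of QC metrics.

Low-quality cells resemble the empty control wells that every plate carries.
All per-cell quality metrics (read counts, Q30, failed-FastQC count, mapped
reads/genes/length, spike-in reads) are standardized and projected on PC1,
which in practice captures overall library quality; the PC is oriented so
control wells sit at the low end, and cells scoring within the control-well
distribution (mean + k*SD) are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

COUNT_METRICS = (
    "n_raw_reads",
    "n_failed_fastqc",
    "n_mapped_reads",
    "n_mapped_genes",
    "n_spike_reads",
)
METRIC_COLUMNS = (
    "n_raw_reads",
    "q30_fraction",
    "n_failed_fastqc",
    "n_mapped_reads",
    "mean_mapped_length",
    "n_mapped_genes",
    "n_spike_reads",
)


@dataclass
class QcPc1:
    scores: pd.Series  # per cell, oriented
    loadings: pd.Series  # per metric
    orientation_sign: int


@dataclass
class QcFilterResult:
    scores: pd.Series
    threshold: float
    keep_mask: pd.Series
    orientation_sign: int


def compute_qc_pc1(metrics: pd.DataFrame) -> QcPc1:
    """Oriented PC1 scores of the standardized QC metrics.

    Count-valued metrics are log1p-transformed before z-standardization.
    The sign is chosen so the mean score of control wells
    (``is_control_well`` column) is at the low end; without controls the
    orientation falls back to a positive loading on ``n_mapped_genes``.
    """
    if len(metrics) < 3:
        raise ValueError("need at least 3 cells for the QC PCA")
    cols = [c for c in METRIC_COLUMNS if c in metrics.columns]
    X = metrics[cols].astype(float).copy()
    for c in COUNT_METRICS:
        if c in X.columns:
            X[c] = np.log1p(X[c])
    sd = X.std(ddof=0)
    variable = sd[sd > 0].index.tolist()
    if len(variable) < 2:
        raise ValueError("no variable metrics: need >= 2 metrics with nonzero variance")
    Z = (X[variable] - X[variable].mean()) / sd[variable]
    # PC1 via SVD of the centered standardized matrix
    _, _, vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
    loading = vt[0]
    scores = Z.to_numpy() @ loading

    sign = 1
    ctrl = metrics["is_control_well"].to_numpy(bool) if "is_control_well" in metrics \
        else np.zeros(len(metrics), bool)
    if ctrl.any() and not ctrl.all():
        if scores[ctrl].mean() > scores[~ctrl].mean():
            sign = -1
    else:
        warnings.warn("no control wells: orienting PC1 by n_mapped_genes loading")
        if "n_mapped_genes" in variable:
            if loading[variable.index("n_mapped_genes")] < 0:
                sign = -1
    return QcPc1(
        scores=pd.Series(sign * scores, index=metrics.index, name="pc1"),
        loadings=pd.Series(sign * loading, index=variable, name="loading"),
        orientation_sign=sign,
    )


def filter_cells(scores: pd.Series, control_ids, k: float = 3.0) -> QcFilterResult:
    """Keep cells scoring above mean(control) + k*SD(control) on oriented PC1.

    With no controls the threshold falls back to the 5th percentile of all
    scores (with a warning). Ties at exactly the threshold are excluded.
    """
    control_ids = list(control_ids)
    if control_ids:
        ctrl = scores.loc[control_ids]
        sd = float(ctrl.std(ddof=0)) if len(ctrl) > 1 else 0.0
        threshold = float(ctrl.mean()) + k * sd
        sign = 1
    else:
        warnings.warn("no control wells given: threshold at 5th percentile of scores")
        threshold = float(np.percentile(scores.to_numpy(), 5))
        sign = 1
    keep = scores > threshold
    return QcFilterResult(scores=scores, threshold=threshold,
                          keep_mask=keep, orientation_sign=sign)


def run_qc(metrics: pd.DataFrame, k: float = 3.0,
           threshold: float | None = None) -> QcFilterResult:
    """Convenience wrapper: PC1 + control-referenced filter in one call."""
    pc1 = compute_qc_pc1(metrics)
    controls = metrics.index[metrics["is_control_well"].astype(bool)] \
        if "is_control_well" in metrics else []
    if threshold is not None:
        keep = pc1.scores > threshold
        return QcFilterResult(pc1.scores, float(threshold), keep, pc1.orientation_sign)
    res = filter_cells(pc1.scores, controls, k=k)
    return QcFilterResult(res.scores, res.threshold, res.keep_mask, pc1.orientation_sign)
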
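"""Embedding, 5->3 k-means clustering, top-20 DEGs and flow-gate back-mapping.

Cells are clustered with k-means (k=5 by default) in top-PC space of the
highly-variable-gene expression; each of the five clusters is assigned the
marker program (naive / memory / plasma) with the highest mean scaled
signature score, and clusters sharing a program are merged — emulating the
visual 5-to-3 merge of the original analysis with an explicit, testable
rule. Index-sort intensities are gated on IgD/CD27 (with a CD27++ stratum
taking precedence) so transcriptomic clusters can be cross-tabulated
against flow phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import kde_valley_thresholds
from .synth import DEFAULT_MARKER_PROGRAMS

GATES = (
    "naive IgD+CD27-",
    "classical memory IgD-CD27+",
    "CD27++",
    "unswitched IgD+CD27+",
    "double-negative IgD-CD27-",
)


@dataclass
class ClusterAssignment:
    kmeans_label: pd.Series  # 1..k
    merged_label: pd.Series  # program names
    embedding: pd.DataFrame | None = None
    program_scores: pd.DataFrame | None = None  # kmeans cluster x program


def embed(expr: pd.DataFrame, seed: int, n_neighbors: int = 15,
          min_dist: float = 0.1) -> pd.DataFrame:
    """2-D UMAP of cells x HVG log-expression; deterministic given seed."""
    X = expr.to_numpy(float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in expression matrix")
    if X.shape[0] < n_neighbors + 1:
        raise ValueError(f"need at least {n_neighbors + 1} cells")
    import umap

    emb = umap.UMAP(n_neighbors=n_neighbors, min_dist=min_dist,
                    random_state=seed).fit_transform(X)
    return pd.DataFrame(emb, index=expr.index, columns=["UMAP1", "UMAP2"])


def _signature_scores(expr: pd.DataFrame, marker_programs) -> pd.DataFrame:
    """Per-cell mean z-scored expression of each program's genes."""
    scores = {}
    sd = expr.std(ddof=0).replace(0.0, 1.0)
    Z = (expr - expr.mean()) / sd
    for prog, spec in marker_programs.items():
        genes = [g for g in (spec[0] if isinstance(spec, tuple) else spec)
                 if g in expr.columns]
        if not genes:
            raise ValueError(f"no marker genes of program {prog} in the matrix")
        scores[prog] = Z[genes].mean(axis=1)
    return pd.DataFrame(scores, index=expr.index)


def kmeans_merge(expr: pd.DataFrame, marker_programs=None, k: int = 5,
                 seed: int = 0, cluster_on: str = "pca",
                 n_pcs: int = 10,
                 embedding: pd.DataFrame | None = None) -> ClusterAssignment:
    """k-means with k=5 merged to the 3 marker-program identities.

    Clustering runs in top-PC space of the expression by default
    (``cluster_on='umap'`` clusters the provided 2-D embedding instead).
    Each k-means cluster is assigned the program with maximal mean scaled
    signature score; clusters sharing a program are merged.
    """
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    if marker_programs is None:
        marker_programs = DEFAULT_MARKER_PROGRAMS
    if cluster_on == "umap":
        if embedding is None:
            raise ValueError("cluster_on='umap' requires an embedding")
        space = embedding.to_numpy(float)
    else:
        X = expr.to_numpy(float)
        space = PCA(n_components=min(n_pcs, min(X.shape) - 1),
                    random_state=seed).fit_transform(X)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(space)
    raw = pd.Series(km.labels_ + 1, index=expr.index, name="kmeans")

    cell_scores = _signature_scores(expr, marker_programs)
    cluster_scores = cell_scores.groupby(raw).mean()
    winner = cluster_scores.idxmax(axis=1)
    unused = set(marker_programs) - set(winner)
    if unused:
        raise ValueError(
            f"programs {sorted(unused)} win no cluster; scores:\n{cluster_scores}")
    merged = raw.map(winner).rename("merged")
    return ClusterAssignment(kmeans_label=raw, merged_label=merged,
                             program_scores=cluster_scores)


def top20_deg(expr: pd.DataFrame, labels: pd.Series, n_top: int = 20):
    """Per-cluster top genes by average pairwise log2 fold change.

    For cluster c the score of a gene is the mean over other clusters o of
    (mean_c - mean_o) on the log2 scale; the detection fraction (>0) per
    cluster is reported as the robustness of expression.
    """
    labels = labels.loc[expr.index]
    clusters = sorted(labels.unique())
    if len(clusters) < 2:
        raise ValueError("need >= 2 clusters")
    sizes = labels.value_counts()
    small = sizes[sizes < 2]
    if len(small):
        raise ValueError(f"clusters with < 2 cells: {small.index.tolist()}")
    means = expr.groupby(labels).mean()
    frac = expr.gt(0).groupby(labels).mean()
    out = {}
    for c in clusters:
        others = [o for o in clusters if o != c]
        avg_fc = sum(means.loc[c] - means.loc[o] for o in others) / len(others)
        order = np.lexsort((means.columns.astype(str), -avg_fc.to_numpy()))
        top = means.columns[order][:n_top]
        tbl = pd.DataFrame({"avg_log2fc": avg_fc[top]})
        for cl in clusters:
            tbl[f"frac_expr_{cl}"] = frac.loc[cl, top]
        out[c] = tbl
    return out


def classify_gates(index_table: pd.DataFrame,
                   igd_threshold: float | None = None,
                   cd27_threshold: float | None = None,
                   cd27_hi_threshold: float | None = None) -> pd.DataFrame:
    """Assign IgD/CD27 flow gates; CD27++ takes precedence over the 2x2 split.

    Thresholds default to valley detection on a KDE of log10 intensities
    (per the whole table; the original gates were manual). Returns a frame
    with the gate per cell and the thresholds used.
    """
    for col in ("IgD", "CD27"):
        if col not in index_table.columns:
            raise ValueError(f"missing marker column {col}")
    ligd = np.log10(index_table["IgD"].astype(float))
    lcd27 = np.log10(index_table["CD27"].astype(float))
    if igd_threshold is None:
        igd_threshold = kde_valley_thresholds(ligd, 1)[0]
    else:
        igd_threshold = np.log10(igd_threshold)
    if cd27_threshold is None or cd27_hi_threshold is None:
        lo, hi = kde_valley_thresholds(lcd27, 2)
        cd27_threshold = lo if cd27_threshold is None else np.log10(cd27_threshold)
        cd27_hi_threshold = hi if cd27_hi_threshold is None else np.log10(cd27_hi_threshold)
    else:
        cd27_threshold = np.log10(cd27_threshold)
        cd27_hi_threshold = np.log10(cd27_hi_threshold)
    if not cd27_threshold < cd27_hi_threshold:
        raise ValueError("cd27_threshold must be below cd27_hi_threshold")

    igd_pos = ligd > igd_threshold
    cd27_pos = lcd27 > cd27_threshold
    cd27_hi = lcd27 > cd27_hi_threshold
    gate = np.where(
        cd27_hi, "CD27++",
        np.where(igd_pos & ~cd27_pos, "naive IgD+CD27-",
                 np.where(~igd_pos & cd27_pos, "classical memory IgD-CD27+",
                          np.where(igd_pos & cd27_pos, "unswitched IgD+CD27+",
                                   "double-negative IgD-CD27-"))))
    out = pd.DataFrame({"gate": gate}, index=index_table.index)
    out.attrs["thresholds"] = {
        "igd_log10": float(igd_threshold),
        "cd27_log10": float(cd27_threshold),
        "cd27_hi_log10": float(cd27_hi_threshold),
    }
    return out


def gate_fractions(gates: pd.DataFrame, donors: pd.Series | None = None) -> pd.DataFrame:
    """Percent of cells per gate, per donor when donor labels are given."""
    if donors is None:
        frac = gates["gate"].value_counts(normalize=True) * 100
        return frac.reindex(GATES, fill_value=0.0).to_frame("all").T
    tab = pd.crosstab(donors.loc[gates.index], gates["gate"], normalize="index") * 100
    return tab.reindex(columns=GATES, fill_value=0.0)


def crosstab_clusters_gates(assignment: ClusterAssignment,
                            gates: pd.DataFrame) -> pd.DataFrame:
    """Contingency table of merged cluster x flow gate over shared cells."""
    shared = assignment.merged_label.index.intersection(gates.index)
    if len(shared) == 0:
        raise ValueError("cluster assignment and gate table share no cells")
    return pd.crosstab(assignment.merged_label.loc[shared],
                       gates.loc[shared, "gate"])


def cluster_fractions(sizes: dict[str, int]) -> dict[str, int]:
    """Cluster sizes to integer percentages of the total."""
    total = sum(sizes.values())
    if total == 0:
        raise ValueError("empty clustering")
    return {k: int(round(100.0 * v / total)) for k, v in sizes.items()}
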
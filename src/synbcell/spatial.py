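"""Spatial-section normalization, integration, SNN clustering, DEGs and NMF.

Each section is normalized to Pearson residuals of a regularized
negative-binomial regression on sequencing depth; sections are merged in a
shared PC space with an iterative per-batch centroid correction; spots are
clustered on a shared-nearest-neighbor (Jaccard) graph with Louvain
modularity; cluster markers come from one-vs-rest rank-sum tests, and
tissue-wide expression programs from a 20-factor non-negative matrix
factorization with over-representation analysis of the top factor genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import bh_adjust, tricube_smooth


# ---------------------------------------------------------------------------
# per-section normalization (regularized NB Pearson residuals)


def normalize_section(counts: pd.DataFrame, max_theta: float = 1e6) -> pd.DataFrame:
    """Pearson residuals of a per-gene NB regression on log10 depth.

    For every gene a Poisson log-linear model mu = exp(b0 + b1*log10(depth))
    is fitted by Newton iterations; an NB dispersion is then estimated by
    method of moments and regularized by a smooth over log gene mean.
    Residuals (y-mu)/sqrt(mu + mu^2/theta) are clipped to +-sqrt(n_spots).
    All-zero genes are dropped with a warning.
    """
    if counts.shape[0] < 20:
        raise ValueError("need >= 20 spots")
    zero = counts.columns[(counts.sum(axis=0) == 0)]
    if len(zero):
        warnings.warn(f"dropping {len(zero)} all-zero genes")
        counts = counts.drop(columns=zero)
    Y = counts.to_numpy(float)
    n_spots, n_genes = Y.shape
    depth = Y.sum(axis=1)
    x = np.log10(depth)
    xc = x - x.mean()

    # vectorized per-gene Newton iterations for (b0, b1)
    gmean = Y.mean(axis=0)
    b0 = np.log(np.clip(gmean, 1e-8, None))
    b1 = np.full(n_genes, np.log(10.0))  # proportional-to-depth start
    for _ in range(50):
        eta = b0[None, :] + b1[None, :] * xc[:, None]
        mu = np.exp(np.clip(eta, -30, 30))
        r = Y - mu
        g0 = r.sum(axis=0)
        g1 = (r * xc[:, None]).sum(axis=0)
        h00 = mu.sum(axis=0)
        h01 = (mu * xc[:, None]).sum(axis=0)
        h11 = (mu * (xc ** 2)[:, None]).sum(axis=0)
        det = np.clip(h00 * h11 - h01 ** 2, 1e-12, None)
        d0 = (h11 * g0 - h01 * g1) / det
        d1 = (h00 * g1 - h01 * g0) / det
        step = np.clip(np.stack([d0, d1]), -2, 2)
        b0 += step[0]
        b1 += step[1]
        if np.max(np.abs(step)) < 1e-8:
            break
    eta = b0[None, :] + b1[None, :] * xc[:, None]
    mu = np.exp(np.clip(eta, -30, 30))

    # method-of-moments dispersion, regularized over log mean
    excess = ((Y - mu) ** 2 - mu).sum(axis=0)
    mu2 = (mu ** 2).sum(axis=0)
    with np.errstate(divide="ignore"):
        theta = np.where(excess > 0, mu2 / np.clip(excess, 1e-12, None), max_theta)
    theta = np.clip(theta, 1e-2, max_theta)
    log_gmean = np.log10(np.clip(gmean, 1e-8, None))
    log_theta_smooth = tricube_smooth(log_gmean, np.log10(theta), log_gmean, span=0.5)
    theta = np.clip(10.0 ** log_theta_smooth, 1e-2, max_theta)

    resid = (Y - mu) / np.sqrt(mu + mu ** 2 / theta[None, :])
    clip = np.sqrt(n_spots)
    return pd.DataFrame(np.clip(resid, -clip, clip),
                        index=counts.index, columns=counts.columns)


# ---------------------------------------------------------------------------
# batch-aware joint embedding


def integrate_sections(residuals: list[pd.DataFrame], n_pcs: int = 30,
                       seed: int = 0, tol: float = 1e-4,
                       max_iter: int = 20, n_clusters: int = 10) -> pd.DataFrame:
    """PCA on concatenated common-gene residuals + iterative batch correction.

    Batches are first centered on the global mean (the whole-embedding
    special case of a per-cluster shift), then soft k-means responsibilities
    in PC space drive per-cluster, per-batch centroid shifts toward the
    global cluster centroid, repeated until the largest shift falls below
    ``tol``. A single section returns plain PCA with a warning.
    """
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    if len(residuals) == 0:
        raise ValueError("no sections given")
    common = residuals[0].columns
    for r in residuals[1:]:
        common = common.intersection(r.columns)
    if len(residuals) > 1 and len(common) < 50:
        raise ValueError(f"only {len(common)} shared genes (< 50)")
    X = pd.concat([r[common] for r in residuals])
    batch = np.concatenate([np.full(len(r), i) for i, r in enumerate(residuals)])
    n_pcs = min(n_pcs, min(X.shape) - 1)
    Z = PCA(n_components=n_pcs, random_state=seed).fit_transform(X.to_numpy(float))
    if len(residuals) == 1:
        warnings.warn("single section: returning plain PCA, no batch correction")
        return pd.DataFrame(Z, index=X.index,
                            columns=[f"PC{i+1}" for i in range(n_pcs)])

    # k=1 shift first: remove each batch's global offset
    gmean = Z.mean(axis=0)
    for b in np.unique(batch):
        m = batch == b
        Z[m] -= Z[m].mean(axis=0) - gmean

    k = min(n_clusters, len(X) - 1)
    centers = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(Z).cluster_centers_
    batches = np.unique(batch)
    batch_frac = {b: (batch == b).mean() for b in batches}
    theta = 1.0  # diversity-penalty strength
    for _ in range(max_iter):
        d2 = np.sum((Z[:, None, :] - centers[None]) ** 2, axis=2)
        # temperature at the within-cluster scale keeps assignments sharp
        tau = max(float(d2.min(axis=1).mean()), 1e-9)
        logit = -d2 / (2 * tau)
        logit -= logit.max(axis=1, keepdims=True)
        R = np.exp(logit)
        R /= R.sum(axis=1, keepdims=True)
        # diversity penalty: batch-pure clusters repel their own batch and
        # attract the others, so twin clusters across batches merge
        for _inner in range(3):
            size_k = R.sum(axis=0) + 1e-9
            for b in batches:
                m = batch == b
                observed = R[m].sum(axis=0) + 1.0
                expected = batch_frac[b] * size_k + 1.0
                R[m] *= (expected / observed) ** theta
            R /= R.sum(axis=1, keepdims=True)
        shift = np.zeros_like(Z)
        max_shift = 0.0
        for kk in range(k):
            w = R[:, kk]
            tot = w.sum()
            if tot < 1e-9:
                continue
            c_k = (w[:, None] * Z).sum(axis=0) / tot
            for b in np.unique(batch):
                m = batch == b
                wb = w[m].sum()
                if wb < 1e-9:
                    continue
                c_kb = (w[m, None] * Z[m]).sum(axis=0) / wb
                delta = c_kb - c_k
                shift[m] += np.outer(w[m], delta)
                max_shift = max(max_shift, float(np.abs(delta).max()))
        Z = Z - shift
        centers = np.stack([(R[:, kk, None] * Z).sum(axis=0)
                            / max(R[:, kk].sum(), 1e-9) for kk in range(k)])
        if max_shift < tol:
            break
    return pd.DataFrame(Z, index=X.index,
                        columns=[f"PC{i+1}" for i in range(n_pcs)])


# ---------------------------------------------------------------------------
# SNN graph clustering


def snn_cluster(embedding: pd.DataFrame, k_nn: int = 20,
                resolution: float = 0.8, seed: int = 0,
                prune: float = 1.0 / 15.0) -> pd.Series:
    """Louvain communities on the shared-nearest-neighbor Jaccard graph.

    Edge weights are the Jaccard overlap of k-NN neighbor sets; edges below
    ``prune`` are removed. Labels are ordered by community size descending.
    Deterministic given ``seed``.
    """
    import random

    import igraph
    from sklearn.neighbors import NearestNeighbors

    X = embedding.to_numpy(float)
    n = X.shape[0]
    if n <= k_nn:
        raise ValueError(f"k_nn={k_nn} must be below the number of spots ({n})")
    nn = NearestNeighbors(n_neighbors=k_nn + 1).fit(X)
    _, idx = nn.kneighbors(X)
    neigh = idx[:, 1:]  # drop self
    sets = [set(row) for row in neigh]
    edges, weights = [], []
    for i in range(n):
        for j in neigh[i]:
            j = int(j)
            if j <= i:
                continue
            inter = len(sets[i] & sets[j])
            jac = inter / (2 * k_nn - inter)
            if jac >= prune:
                edges.append((i, j))
                weights.append(jac)
    g = igraph.Graph(n=n, edges=edges)
    # igraph draws from Python's global random module
    state = random.getstate()
    random.seed(seed)
    try:
        part = g.community_multilevel(weights=weights, resolution=resolution)
    finally:
        random.setstate(state)
    labels = np.asarray(part.membership)
    order = pd.Series(labels).value_counts().index.tolist()
    remap = {old: new for new, old in enumerate(order)}
    return pd.Series([remap[l] for l in labels], index=embedding.index,
                     name="spot_cluster")


# ---------------------------------------------------------------------------
# cluster DEGs


def spatial_deg(counts: pd.DataFrame, labels: pd.Series,
                logfc_min: float = 1.0, p_max: float = 0.05) -> dict:
    """One-vs-rest Wilcoxon rank-sum upregulated genes per spot cluster.

    Tests run on log1p depth-scaled counts; fold changes on expm1 means;
    BH adjustment per cluster. Rows kept satisfy log2FC > logfc_min and
    adjusted p < p_max. Clusters with < 3 spots are skipped with a warning.
    """
    labels = labels.loc[counts.index]
    depth = counts.sum(axis=1).to_numpy(float)
    scale = np.median(depth) / np.clip(depth, 1, None)
    lognorm = np.log1p(counts.to_numpy(float) * scale[:, None])
    eps = 1e-9
    out = {}
    for cl in sorted(labels.unique()):
        m = (labels == cl).to_numpy()
        if m.sum() < 3:
            warnings.warn(f"cluster {cl} has < 3 spots: skipped")
            continue
        res = stats.mannwhitneyu(lognorm[m], lognorm[~m], axis=0,
                                 alternative="two-sided")
        p_adj = bh_adjust(res.pvalue)
        mean_in = np.expm1(lognorm[m]).mean(axis=0)
        mean_out = np.expm1(lognorm[~m]).mean(axis=0)
        log2fc = np.log2((mean_in + eps) / (mean_out + eps))
        keep = (log2fc > logfc_min) & (p_adj < p_max)
        tbl = pd.DataFrame({"log2fc": log2fc[keep], "adj_p": p_adj[keep]},
                           index=counts.columns[keep])
        out[cl] = tbl.sort_values("log2fc", ascending=False, kind="stable")
    return out


# ---------------------------------------------------------------------------
# NMF factorization


@dataclass
class FactorModel:
    W: pd.DataFrame  # spots x factors
    H: pd.DataFrame  # factors x genes
    errors: list[float] = field(default_factory=list)  # Frobenius per iteration

    def top_genes(self, n: int = 20) -> dict[int, list[str]]:
        out = {}
        for f in range(self.H.shape[0]):
            row = self.H.iloc[f]
            order = np.lexsort((self.H.columns.astype(str), -row.to_numpy()))
            out[f] = self.H.columns[order][:n].tolist()
        return out

    def relative_error(self, X: pd.DataFrame) -> float:
        """Final Frobenius reconstruction error relative to ||X||."""
        A = X.to_numpy(float)
        return float(np.linalg.norm(A - self.W.to_numpy() @ self.H.to_numpy(), "fro")
                     / np.linalg.norm(A, "fro"))


def shift_nonnegative(residuals: pd.DataFrame) -> pd.DataFrame:
    """Shift a residual matrix by its global minimum to make it NMF-ready."""
    return residuals - min(float(residuals.to_numpy().min()), 0.0)


def nmf_factorize(X: pd.DataFrame, n_factors: int = 20, seed: int = 0,
                  max_iter: int = 500, tol: float = 1e-6) -> FactorModel:
    """Multiplicative-update NMF minimizing Frobenius error.

    The per-iteration objective is recorded (it is non-increasing for
    multiplicative updates). Deterministic given ``seed``.
    """
    A = X.to_numpy(float)
    if (A < 0).any():
        raise ValueError("input must be non-negative (see shift_nonnegative)")
    n, m = A.shape
    if n_factors > min(n, m):
        raise ValueError(f"n_factors={n_factors} exceeds min(dims)={min(n, m)}")
    rng = np.random.default_rng(seed)
    scale = np.sqrt(A.mean() / n_factors)
    W = rng.uniform(1e-4, 1.0, size=(n, n_factors)) * scale
    H = rng.uniform(1e-4, 1.0, size=(n_factors, m)) * scale
    eps = 1e-10
    errors = []
    prev = None
    for _ in range(max_iter):
        H *= (W.T @ A) / (W.T @ W @ H + eps)
        W *= (A @ H.T) / (W @ H @ H.T + eps)
        err = float(np.linalg.norm(A - W @ H, "fro"))
        errors.append(err)
        if prev is not None and prev - err < tol * max(prev, 1.0):
            break
        prev = err
    return FactorModel(
        W=pd.DataFrame(W, index=X.index,
                       columns=[f"factor_{i}" for i in range(n_factors)]),
        H=pd.DataFrame(H, index=[f"factor_{i}" for i in range(n_factors)],
                       columns=X.columns),
        errors=errors,
    )


# ---------------------------------------------------------------------------
# over-representation analysis


def read_gmt(path) -> dict[str, set[str]]:
    terms = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                terms[parts[0]] = set(g for g in parts[2:] if g)
    return terms


def ora_pathways(genes, gene_sets, universe) -> pd.DataFrame:
    """Hypergeometric over-representation of ``genes`` in each term.

    ``gene_sets`` is a mapping term -> gene set (or a GMT path). p-values
    are upper-tail P(X >= overlap); BH adjustment across terms.
    """
    if isinstance(gene_sets, (str,)) or hasattr(gene_sets, "read"):
        gene_sets = read_gmt(gene_sets)
    universe = set(universe)
    query = set(genes) & universe
    if not set(genes) <= universe:
        missing = sorted(set(genes) - universe)[:5]
        raise ValueError(f"query genes outside universe, e.g. {missing}")
    if not query:
        return pd.DataFrame(columns=["term", "overlap", "term_size", "p", "q"])
    N = len(universe)
    n = len(query)
    rows = []
    for term, members in gene_sets.items():
        K = len(members & universe)
        k = len(members & query)
        p = stats.hypergeom.sf(k - 1, N, K, n) if K else 1.0
        rows.append({"term": term, "overlap": k, "term_size": K, "p": float(p)})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"])
    return out.sort_values("p", kind="stable").reset_index(drop=True)
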
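"""Signature derivation, cross-dataset overlap, spot scoring, co-localization.

Cluster-enriched genes are found by Kruskal-Wallis with Dunn pairwise
post-hoc z-tests (Bonferroni-adjusted over the pairwise family), keeping
genes with fold change > 1 against every comparator at adjusted p < 0.01.
Signature overlap between two datasets is assessed with Fisher's exact
test; per-spot cell-type content is estimated by non-negative least squares
of spot expression against cell-type mean profiles over the signature gene
union, and co-localization by Spearman correlation of the resulting scores.
"""

from __future__ import annotations

import difflib
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn enrichment


def _kw_dunn(X: np.ndarray, groups: list[np.ndarray]):
    """Vectorized KW H (tie-corrected) and Dunn pairwise z-stats per gene.

    ``X`` is cells x genes over the included cells only; ``groups`` indexes
    rows of X. Returns (H, kw_p, mean_ranks dict, dunn machinery inputs).
    """
    n_cells, n_genes = X.shape
    ranks = stats.rankdata(X, axis=0)
    N = n_cells
    # tie correction per gene
    tie_sum = np.zeros(n_genes)
    for g in range(n_genes):
        _, counts = np.unique(X[:, g], return_counts=True)
        t = counts[counts > 1]
        tie_sum[g] = float(np.sum(t ** 3 - t))
    mean_ranks = {i: ranks[idx].mean(axis=0) for i, idx in enumerate(groups)}
    ns = {i: len(idx) for i, idx in enumerate(groups)}
    H = np.zeros(n_genes)
    for i, idx in enumerate(groups):
        H += ns[i] * (mean_ranks[i] - (N + 1) / 2.0) ** 2
    H *= 12.0 / (N * (N + 1))
    correction = 1.0 - tie_sum / max(N ** 3 - N, 1)
    H = np.where(correction > 0, H / correction, 0.0)
    kw_p = stats.chi2.sf(H, df=len(groups) - 1)
    # Dunn variance term with tie correction
    var_term = N * (N + 1) / 12.0 - tie_sum / (12.0 * (N - 1))
    return H, kw_p, mean_ranks, ns, var_term


def kruskal_wallis_h(samples) -> float:
    """Tie-corrected Kruskal-Wallis H for a list of 1-D samples."""
    X = np.concatenate([np.asarray(s, float) for s in samples])[:, None]
    groups, start = [], 0
    for s in samples:
        groups.append(np.arange(start, start + len(s)))
        start += len(s)
    H, _, _, _, _ = _kw_dunn(X, groups)
    return float(H[0])


@dataclass
class SignatureSet:
    """Per-cluster enriched genes with fold changes and adjusted p-values."""

    table: pd.DataFrame  # columns: cluster, gene, fold_change, adj_p, kw_p

    def genes(self, cluster) -> list[str]:
        return self.table.loc[self.table["cluster"] == cluster, "gene"].tolist()


def signature_enrichment(expr: pd.DataFrame, labels: pd.Series,
                         targets, comparators,
                         fc_min: float = 1.0, p_max: float = 0.01) -> SignatureSet:
    """Cluster-enriched genes by KW + Dunn + Bonferroni.

    Only cells of ``targets`` and ``comparators`` clusters enter the test
    (non-listed clusters are excluded entirely). A gene is enriched for a
    target when its fold change (ratio of expm1 means) exceeds ``fc_min``
    against every comparator and the largest Bonferroni-adjusted Dunn p
    across comparators is below ``p_max``.
    """
    comparators = list(comparators)
    targets = list(targets)
    if not comparators:
        raise ValueError("comparator set is empty")
    included = list(dict.fromkeys(targets + comparators))
    labels = labels.loc[expr.index]
    mask = labels.isin(included).to_numpy()
    sub = expr.loc[mask]
    sub_labels = labels[mask]
    sizes = sub_labels.value_counts()
    if (sizes.reindex(included).fillna(0) < 3).any():
        raise ValueError("every included cluster needs >= 3 cells")
    X = sub.to_numpy(float)
    groups = [np.flatnonzero((sub_labels == cl).to_numpy()) for cl in included]
    H, kw_p, mean_ranks, ns, var_term = _kw_dunn(X, groups)

    expm1_means = {cl: np.expm1(X[groups[i]]).mean(axis=0)
                   for i, cl in enumerate(included)}
    pair_list = [(t, c) for t in targets for c in comparators if t != c]
    n_family = len(pair_list)
    idx_of = {cl: i for i, cl in enumerate(included)}

    rows = []
    eps = 1e-9
    for t in targets:
        fcs, adj_ps = [], []
        for c in comparators:
            if c == t:
                continue
            i, j = idx_of[t], idx_of[c]
            z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(
                var_term * (1.0 / ns[i] + 1.0 / ns[j]))
            p_pair = 2.0 * stats.norm.sf(np.abs(z))
            adj_ps.append(np.minimum(p_pair * n_family, 1.0))
            fcs.append((expm1_means[t] + eps) / (expm1_means[c] + eps))
        min_fc = np.min(fcs, axis=0)
        max_adj = np.max(adj_ps, axis=0)
        keep = (min_fc > fc_min) & (max_adj < p_max)
        for g_idx in np.flatnonzero(keep):
            rows.append({"cluster": t, "gene": expr.columns[g_idx],
                         "fold_change": float(min_fc[g_idx]),
                         "adj_p": float(max_adj[g_idx]),
                         "kw_p": float(kw_p[g_idx])})
    return SignatureSet(pd.DataFrame(
        rows, columns=["cluster", "gene", "fold_change", "adj_p", "kw_p"]))


# ---------------------------------------------------------------------------
# Fisher overlap


@dataclass
class FisherResult:
    table: np.ndarray  # 2x2: [[both, A only], [B only, neither]]
    odds_ratio: float
    p_value: float


def fisher_exact_table(a: int, b: int, c: int, d: int) -> FisherResult:
    """Two-sided Fisher's exact test of a 2x2 table [[a, b], [c, d]].

    The sample odds ratio is ad/bc (inf when bc = 0 and ad > 0, 0 when
    ad = 0 and bc > 0, error when both vanish); the p-value sums all
    hypergeometric probabilities not exceeding the observed one.
    """
    ad, bc = a * d, b * c
    if ad == 0 and bc == 0:
        raise ValueError("odds ratio undefined: both diagonal products are zero")
    odds = np.inf if bc == 0 else ad / bc
    N, K, n = a + b + c + d, a + b, a + c
    lo = max(0, K + n - N)
    support = np.arange(lo, min(K, n) + 1)
    pmf = stats.hypergeom.pmf(support, N, K, n)
    observed = pmf[a - lo]
    p = float(pmf[pmf <= observed * (1 + 1e-7)].sum())
    return FisherResult(table=np.array([[a, b], [c, d]]),
                        odds_ratio=float(odds), p_value=min(p, 1.0))


def fisher_overlap(set_a, set_b, universe) -> FisherResult:
    """Fisher's exact test for the overlap of two gene sets in a universe."""
    A, B, U = set(set_a), set(set_b), set(universe)
    if not A <= U or not B <= U:
        raise ValueError("sets must be subsets of the universe")
    a = len(A & B)
    b = len(A - B)
    c = len(B - A)
    d = len(U) - a - b - c
    return fisher_exact_table(a, b, c, d)


# ---------------------------------------------------------------------------
# spot scoring and co-localization


def score_spots(spot_expr: pd.DataFrame, profiles: pd.DataFrame,
                signature_genes=None) -> pd.DataFrame:
    """Per-spot cell-type scores by non-negative least squares.

    Each spot's expression over the signature-gene union is regressed on
    the cell-type mean profiles; non-negative coefficients are renormalized
    to sum to one (uniform scores for an all-zero solution).
    """
    if profiles.shape[1] < 2:
        raise ValueError("need >= 2 cell types")
    genes = list(signature_genes) if signature_genes is not None \
        else profiles.index.tolist()
    genes = [g for g in genes if g in spot_expr.columns and g in profiles.index]
    if not genes:
        raise ValueError("signature gene union is empty in the spot matrix")
    P = profiles.loc[genes].to_numpy(float)
    if np.linalg.matrix_rank(P) < P.shape[1]:
        warnings.warn("profile matrix rank-deficient: adding ridge term 1e-6")
        P = np.vstack([P, np.sqrt(1e-6) * np.eye(P.shape[1])])
        pad = True
    else:
        pad = False
    Y = spot_expr[genes].to_numpy(float)
    scores = np.zeros((len(spot_expr), profiles.shape[1]))
    zero_spots = 0
    for i in range(len(spot_expr)):
        y = Y[i]
        if pad:
            y = np.concatenate([y, np.zeros(P.shape[1])])
        coef, _ = nnls(P, y)
        s = coef.sum()
        if s <= 0:
            zero_spots += 1
            scores[i] = 1.0 / profiles.shape[1]
        else:
            scores[i] = coef / s
    if zero_spots:
        warnings.warn(f"{zero_spots} spots had all-zero solutions: uniform scores")
    return pd.DataFrame(scores, index=spot_expr.index, columns=profiles.columns)


def colocalize(scores: pd.DataFrame, reference: str,
               sections: pd.Series | None = None,
               pooling: str = "all-spots") -> pd.Series:
    """Spearman correlation of the reference type's scores with every type.

    ``pooling='per-section-mean'`` computes R per section and averages;
    the default pools all spots. Constant score vectors give missing R
    with a warning.
    """
    if len(scores) < 10:
        raise ValueError("need >= 10 spots")
    if reference not in scores.columns:
        raise ValueError(f"unknown reference type {reference}")

    def _spear(df):
        ref = df[reference].to_numpy()
        out = {}
        for col in df.columns:
            x = df[col].to_numpy()
            if np.ptp(ref) == 0 or np.ptp(x) == 0:
                warnings.warn(f"constant score vector for {col}: R undefined")
                out[col] = np.nan
            else:
                out[col] = stats.spearmanr(ref, x).statistic
        return pd.Series(out)

    if pooling == "per-section-mean":
        if sections is None:
            raise ValueError("per-section pooling requires section labels")
        parts = [_spear(scores.loc[sections == s]) for s in sections.unique()]
        return pd.concat(parts, axis=1).mean(axis=1).rename(reference)
    return _spear(scores).rename(reference)


def gene_overlay(counts: pd.DataFrame, positions: pd.DataFrame,
                 gene: str) -> pd.DataFrame:
    """Raw per-spot counts of one gene keyed by array position (for plotting)."""
    if gene not in counts.columns:
        near = difflib.get_close_matches(gene, counts.columns, n=5)
        raise ValueError(f"unknown gene {gene}; close matches: {near}")
    out = positions.loc[counts.index, ["array_row", "array_col"]].copy()
    out[gene] = counts[gene].to_numpy()
    return out


def read_reference_signatures(path) -> dict[str, list[str]]:
    """Cluster -> gene list from a 2-column TSV (cluster, gene)."""
    df = pd.read_csv(path, sep="\t")
    cl_col, gene_col = df.columns[:2]
    return {cl: sub[gene_col].tolist() for cl, sub in df.groupby(cl_col, sort=True)}
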
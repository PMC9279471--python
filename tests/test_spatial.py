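"""Section normalization, integration, SNN clustering, DEGs, NMF, ORA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from synbcell import spatial, synth


class TestNormalizeSection:
    def test_poisson_depth_gene_gives_unit_residuals(self):
        """A gene proportional to depth under Poisson noise: mean~0, var~1."""
        rng = np.random.default_rng(0)
        n_spots, n_genes = 400, 60
        depth_factor = rng.lognormal(0, 0.3, n_spots)
        base = rng.gamma(3, 3, n_genes)
        counts = rng.poisson(np.outer(depth_factor, base))
        counts = pd.DataFrame(counts, columns=[f"g{i}" for i in range(n_genes)])
        res = spatial.normalize_section(counts)
        assert abs(res.mean().mean()) <= 0.2
        assert res.var(ddof=1).mean() == pytest.approx(1.0, abs=0.2)

    def test_all_zero_gene_dropped(self):
        counts = pd.DataFrame(np.random.default_rng(1).poisson(5, (30, 5)),
                              columns=list("abcde"))
        counts["dead"] = 0
        with pytest.warns(UserWarning, match="all-zero"):
            res = spatial.normalize_section(counts)
        assert "dead" not in res.columns

    def test_residuals_clipped(self, residuals):
        for r in residuals:
            assert (r.abs().to_numpy() <= np.sqrt(len(r)) + 1e-9).all()

    def test_too_few_spots(self):
        with pytest.raises(ValueError, match=">= 20 spots"):
            spatial.normalize_section(pd.DataFrame(np.ones((5, 5))))


class TestIntegrateSections:
    def test_batch_mixing_after_correction(self):
        """Two sections from identical mixtures + planted offset get mixed."""
        rng = np.random.default_rng(2)
        n, g = 150, 80
        base = rng.normal(0, 1, size=(n, g))
        a = pd.DataFrame(base + rng.normal(0, 0.1, (n, g)),
                         index=[f"a{i}" for i in range(n)])
        b = pd.DataFrame(base + 3.0 + rng.normal(0, 0.1, (n, g)),
                         index=[f"b{i}" for i in range(n)])
        emb = spatial.integrate_sections([a, b], n_pcs=10, seed=2)
        from sklearn.neighbors import NearestNeighbors

        nn = NearestNeighbors(n_neighbors=21).fit(emb)
        _, idx = nn.kneighbors(emb)
        batch = np.r_[np.zeros(n), np.ones(n)]
        ent = []
        for row in idx[:, 1:]:
            p = batch[row].mean()
            if 0 < p < 1:
                ent.append(-(p * np.log2(p) + (1 - p) * np.log2(1 - p)))
            else:
                ent.append(0.0)
        assert np.mean(ent) >= 0.9

    def test_single_section_plain_pca(self, residuals):
        with pytest.warns(UserWarning, match="plain PCA"):
            emb = spatial.integrate_sections([residuals[0]], seed=2)
        assert len(emb) == len(residuals[0])

    def test_deterministic(self, residuals, embedding):
        again = spatial.integrate_sections(residuals, seed=9)
        pd.testing.assert_frame_equal(again, embedding)

    def test_too_few_shared_genes(self):
        a = pd.DataFrame(np.ones((30, 10)), columns=[f"x{i}" for i in range(10)])
        b = pd.DataFrame(np.ones((30, 10)), columns=[f"y{i}" for i in range(10)])
        with pytest.raises(ValueError, match="shared genes"):
            spatial.integrate_sections([a, b])


class TestSnnCluster:
    def test_recovers_planted_regions(self, spot_labels, spatial_data):
        truth = spatial_data["truth"]["region"]
        assert adjusted_rand_score(truth, spot_labels) >= 0.8

    def test_knn_exceeding_spots_rejected(self, embedding):
        with pytest.raises(ValueError, match="k_nn"):
            spatial.snn_cluster(embedding.iloc[:10], k_nn=20)

    def test_duplicated_spots_co_clustered(self):
        rng = np.random.default_rng(3)
        pts = np.r_[rng.normal(0, 0.1, (40, 3)), rng.normal(8, 0.1, (40, 3))]
        emb = pd.DataFrame(np.r_[pts, pts[:1]],
                           index=[f"s{i}" for i in range(81)])
        labels = spatial.snn_cluster(emb, k_nn=10, seed=1)
        assert labels.iloc[0] == labels.iloc[-1]

    def test_labels_ordered_by_size(self, spot_labels):
        sizes = spot_labels.value_counts()
        assert list(sizes.index) == sorted(sizes.index)
        assert (sizes.sort_index(ascending=True).diff().dropna() <= 0).all()


class TestSpatialDeg:
    def test_exclusive_gene_found(self):
        rng = np.random.default_rng(4)
        counts = pd.DataFrame(rng.poisson(5, (60, 20)),
                              columns=[f"g{i:02d}" for i in range(20)])
        labels = pd.Series([0] * 30 + [1] * 30, index=counts.index)
        counts.loc[labels == 0, "g00"] = 60
        degs = spatial.spatial_deg(counts, labels)
        assert "g00" in degs[0].index

    def test_cutoffs_respected_on_every_row(self, spatial_data, spot_labels):
        counts = pd.concat([s.counts for s in spatial_data["sections"]])
        degs = spatial.spatial_deg(counts, spot_labels)
        for tbl in degs.values():
            assert (tbl["log2fc"] > 1.0).all()
            assert (tbl["adj_p"] < 0.05).all()

    def test_permuted_labels_yield_few_genes(self, spatial_data, spot_labels):
        counts = pd.concat([s.counts for s in spatial_data["sections"]])
        rng = np.random.default_rng(5)
        perm = pd.Series(rng.permutation(spot_labels.to_numpy()),
                         index=spot_labels.index)
        degs = spatial.spatial_deg(counts, perm)
        for tbl in degs.values():
            assert len(tbl) <= 0.05 * counts.shape[1]

    def test_singleton_cluster_skipped(self):
        counts = pd.DataFrame(np.random.default_rng(6).poisson(5, (31, 10)))
        labels = pd.Series([0] * 30 + [1], index=counts.index)
        with pytest.warns(UserWarning, match="skipped"):
            degs = spatial.spatial_deg(counts, labels)
        assert 1 not in degs


class TestNmf:
    @staticmethod
    def _rank2(n=60, m=40, seed=7):
        rng = np.random.default_rng(seed)
        W = rng.uniform(0.5, 2.0, (n, 2))
        H = rng.uniform(0.5, 2.0, (2, m))
        return pd.DataFrame(W @ H)

    def test_rank2_reconstruction(self):
        X = self._rank2()
        fm = spatial.nmf_factorize(X, n_factors=2, seed=1, max_iter=5000,
                                   tol=1e-14)
        assert fm.relative_error(X) <= 1e-3

    def test_objective_monotone_nonincreasing(self):
        X = self._rank2()
        fm = spatial.nmf_factorize(X, n_factors=3, seed=1, max_iter=200)
        assert (np.diff(fm.errors) <= 1e-8).all()

    def test_deterministic(self):
        X = self._rank2()
        a = spatial.nmf_factorize(X, n_factors=3, seed=2, max_iter=50)
        b = spatial.nmf_factorize(X, n_factors=3, seed=2, max_iter=50)
        pd.testing.assert_frame_equal(a.W, b.W)
        pd.testing.assert_frame_equal(a.H, b.H)

    def test_agrees_with_sklearn_reference(self):
        """Independent route: sklearn's MU solver reaches the same objective."""
        from sklearn.decomposition import NMF

        X = self._rank2(seed=8)
        ours = spatial.nmf_factorize(X, n_factors=2, seed=3, max_iter=2000,
                                     tol=1e-12)
        ref = NMF(n_components=2, solver="mu", init="random", random_state=3,
                  max_iter=2000, tol=1e-10).fit(X.to_numpy())
        ref_err = np.linalg.norm(
            X.to_numpy() - ref.transform(X.to_numpy()) @ ref.components_, "fro")
        assert ours.errors[-1] == pytest.approx(ref_err, rel=0.05, abs=1e-6)

    def test_too_many_factors(self):
        with pytest.raises(ValueError, match="n_factors"):
            spatial.nmf_factorize(pd.DataFrame(np.ones((4, 4))), n_factors=5)

    def test_negative_input_rejected_and_shift_helper(self):
        X = pd.DataFrame(np.array([[1.0, -2.0], [0.0, 3.0]]))
        with pytest.raises(ValueError, match="non-negative"):
            spatial.nmf_factorize(X, n_factors=1)
        assert spatial.shift_nonnegative(X).min().min() == 0.0


class TestOra:
    def test_self_term_is_extreme(self):
        genes = [f"g{i}" for i in range(20)]
        universe = [f"g{i}" for i in range(1000)]
        out = spatial.ora_pathways(genes, {"self": set(genes)}, universe)
        assert out.loc[0, "overlap"] == 20
        assert out.loc[0, "p"] < 1e-10

    def test_disjoint_term_p_is_one(self):
        universe = [f"g{i}" for i in range(100)]
        out = spatial.ora_pathways(universe[:10], {"other": set(universe[50:60])},
                                   universe)
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_matches_bruteforce_tail_sum(self):
        """20-gene query, 50-gene term, overlap 5 of universe 1000."""
        from math import comb

        universe = [f"g{i}" for i in range(1000)]
        term = set(universe[:50])
        query = universe[:5] + universe[500:515]
        out = spatial.ora_pathways(query, {"t": term}, universe)
        N, K, n = 1000, 50, 20
        brute = sum(comb(K, k) * comb(N - K, n - k) for k in range(5, n + 1)) \
            / comb(N, n)
        assert out.loc[0, "p"] == pytest.approx(brute, rel=1e-10)

    def test_empty_gene_list(self):
        out = spatial.ora_pathways([], {"t": {"a"}}, ["a", "b"])
        assert len(out) == 0

    def test_gmt_roundtrip(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("term1\tdesc\ta\tb\tc\nterm2\tdesc\tb\td\n")
        sets = spatial.read_gmt(p)
        assert sets == {"term1": {"a", "b", "c"}, "term2": {"b", "d"}}
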
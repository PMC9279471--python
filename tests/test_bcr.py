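"""Pair filtering, clonotype grouping, clonality, SHM, sequons, trees."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synbcell import bcr, synth


def _chain(cell, locus, v, j, seq, expr=100.0, c="IGHG1", productive=True,
           complete=True):
    return {
        "cell_id": cell, "donor_id": "A2", "locus": locus, "v_call": v,
        "d_call": "", "j_call": j, "c_call": c, "junction": "TGTGCG",
        "junction_aa": "CA", "sequence": seq, "germline_alignment": seq,
        "v_germline_end": len(seq) - 10, "productive": productive,
        "complete_vdj": complete, "consensus_count": expr,
        "plate_id": "P1", "well_row": 0, "well_col": 0,
    }


class TestFilterPairs:
    def test_simple_pair(self):
        chains = pd.DataFrame([
            _chain("c1", "IGH", "IGHV1-2*01", "IGHJ4*02", "AAAA"),
            _chain("c1", "IGK", "IGKV1-5*01", "IGKJ1*01", "CCCC"),
        ])
        pairs, disp = bcr.filter_pairs(chains)
        assert len(pairs) == 1 and disp["c1"] == "paired"

    def test_highest_expression_heavy_wins(self):
        chains = pd.DataFrame([
            _chain("c1", "IGH", "IGHV1-2*01", "IGHJ4*02", "AAAA", expr=100),
            _chain("c1", "IGH", "IGHV3-7*01", "IGHJ4*02", "GGGG", expr=10),
            _chain("c1", "IGK", "IGKV1-5*01", "IGKJ1*01", "CCCC"),
        ])
        pairs, _ = bcr.filter_pairs(chains)
        assert pairs.loc["c1", "heavy_nt"] == "AAAA"

    def test_heavy_only_logged_unpaired(self):
        chains = pd.DataFrame([_chain("c1", "IGH", "IGHV1-2*01", "IGHJ4*02", "AAAA")])
        pairs, disp = bcr.filter_pairs(chains)
        assert len(pairs) == 0 and disp["c1"] == "unpaired"

    def test_duplicates_deduplicated_with_warning(self):
        row = _chain("c1", "IGH", "IGHV1-2*01", "IGHJ4*02", "AAAA")
        chains = pd.DataFrame([row, row,
                               _chain("c1", "IGK", "IGKV1-5*01", "IGKJ1*01", "C")])
        with pytest.warns(UserWarning, match="duplicate"):
            pairs, _ = bcr.filter_pairs(chains)
        assert len(pairs) == 1


class TestGroupClonotypes:
    def test_recovers_planted_families_exactly(self, bcr_data):
        from sklearn.metrics import adjusted_rand_score

        pairs, _ = bcr.filter_pairs(bcr_data["chains"])
        cts = bcr.group_clonotypes(pairs)
        assign = {}
        for i, ct in enumerate(cts):
            for cid in ct.members.index:
                assign[cid] = i
        truth = bcr_data["truth"]
        pred = [assign[c] for c in truth.index]
        assert adjusted_rand_score(truth["clone_family"], pred) == 1.0

    def test_allele_suffix_stripped(self):
        pairs = pd.DataFrame({
            "donor_id": ["A2", "A2"],
            "heavy_v_call": ["IGHV5-51*01", "IGHV5-51*02"],
            "heavy_j_call": ["IGHJ4*02", "IGHJ4*02"],
            "light_v_call": ["IGKV2-40*01", "IGKV2-40*01"],
            "light_j_call": ["IGKJ5*01", "IGKJ5*01"],
            "heavy_nt": ["AA", "AT"], "light_nt": ["CC", "CC"],
        }, index=["x", "y"])
        assert len(bcr.group_clonotypes(pairs)) == 1
        assert len(bcr.group_clonotypes(pairs, key_level="allele")) == 2

    def test_donor_scoping(self):
        pairs = pd.DataFrame({
            "donor_id": ["A2", "A3"],
            "heavy_v_call": ["IGHV5-51*01"] * 2,
            "heavy_j_call": ["IGHJ4*02"] * 2,
            "light_v_call": ["IGKV2-40*01"] * 2,
            "light_j_call": ["IGKJ5*01"] * 2,
            "heavy_nt": ["AA", "AA"], "light_nt": ["CC", "CC"],
        }, index=["x", "y"])
        assert len(bcr.group_clonotypes(pairs)) == 2

    def test_clone_numbering_by_multiplicity(self):
        pairs = pd.DataFrame({
            "donor_id": ["A2"] * 3,
            "heavy_v_call": ["IGHV5-51*01"] * 3,
            "heavy_j_call": ["IGHJ4*02"] * 3,
            "light_v_call": ["IGKV2-40*01"] * 3,
            "light_j_call": ["IGKJ5*01"] * 3,
            "heavy_nt": ["AA", "AA", "AT"], "light_nt": ["CC", "CC", "CC"],
        }, index=["x", "y", "z"])
        ct = bcr.group_clonotypes(pairs)[0]
        assert ct.clone_ids.tolist() == [1, 1, 2]

    def test_idempotent_and_order_invariant(self, bcr_data):
        pairs, _ = bcr.filter_pairs(bcr_data["chains"])
        a = bcr.group_clonotypes(pairs)
        b = bcr.group_clonotypes(pairs.sample(frac=1.0, random_state=5))
        keys_a = sorted((c.donor_id, c.key, tuple(sorted(c.members.index)))
                        for c in a)
        keys_b = sorted((c.donor_id, c.key, tuple(sorted(c.members.index)))
                        for c in b)
        assert keys_a == keys_b

    def test_member_conservation(self, bcr_data):
        pairs, _ = bcr.filter_pairs(bcr_data["chains"])
        cts = bcr.group_clonotypes(pairs)
        assert sum(c.size for c in cts) == len(pairs)


class TestSharedClonality:
    @staticmethod
    def _clonotype(rows):
        pairs = pd.DataFrame(rows).set_index("cell_id")
        pairs["donor_id"] = "A2"
        for col, val in (("heavy_v_call", "IGHV5-51*01"),
                         ("heavy_j_call", "IGHJ4*02"),
                         ("light_v_call", "IGKV2-40*01"),
                         ("light_j_call", "IGKJ5*01")):
            pairs[col] = val
        return bcr.group_clonotypes(pairs)

    def test_identical_sibling_detected(self):
        cts = self._clonotype([
            {"cell_id": "pc", "heavy_nt": "AA", "light_nt": "CC",
             "heavy_c_call": "IGHG1", "compartment": "plasma"},
            {"cell_id": "mem", "heavy_nt": "AA", "light_nt": "CC",
             "heavy_c_call": "IGHG1", "compartment": "memory"},
        ])
        report, _ = bcr.shared_clonality(cts)
        assert report.loc[0, "n_identical_cross_siblings"] == 1
        assert report.loc[0, "spans_compartments"]

    def test_similar_member_not_identical(self):
        cts = self._clonotype([
            {"cell_id": "pc", "heavy_nt": "AA", "light_nt": "CC",
             "heavy_c_call": "IGHG1", "compartment": "plasma"},
            {"cell_id": "mem", "heavy_nt": "AT", "light_nt": "CC",
             "heavy_c_call": "IGHG1", "compartment": "memory"},
        ])
        report, summary = bcr.shared_clonality(cts)
        assert report.loc[0, "n_identical_cross_siblings"] == 0
        assert report.loc[0, "n_similar_members"] == 1
        assert summary["n_spanning_memory_plasma"] == 1

    def test_planted_splits_reproduced_exactly(self, bcr_data):
        pairs, _ = bcr.filter_pairs(bcr_data["chains"])
        truth = bcr_data["truth"]
        pairs = pairs.join(truth["compartment"])
        cts = bcr.group_clonotypes(pairs)
        report, _ = bcr.shared_clonality(cts, truth["compartment"])
        fam_of = truth.groupby("clone_family")
        for _, row in report.iterrows():
            members = cts[row["clonotype"]].members.index
            fam = truth.loc[members, "clone_family"].iloc[0]
            planted = truth[truth["clone_family"] == fam]["compartment"]
            assert row["n_memory"] == (planted == "memory").sum()
            assert row["n_plasma"] == (planted == "plasma").sum()


class TestClonalityFraction:
    @pytest.mark.parametrize("members,total,pct", [
        (70, 753, 9), (82, 371, 22), (38, 377, 10), (0, 100, 0)])
    def test_percent_rounding(self, members, total, pct):
        _, percent = bcr.clonality_fraction(members, total)
        assert percent == pct

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            bcr.clonality_fraction(1, 0)


class TestShmCount:
    def test_identical_is_zero(self):
        assert bcr.shm_count("ACGT", "ACGT") == 0

    def test_planted_substitutions(self, bcr_data):
        chains = bcr_data["chains"]
        truth = bcr_data["truth"]
        heavy = chains[chains["locus"] == "IGH"].set_index("cell_id")
        for cid in truth.index:
            row = heavy.loc[cid]
            assert bcr.shm_count(row["sequence"], row["germline_alignment"],
                                 (0, int(row["v_germline_end"]))) \
                == truth.loc[cid, "n_shm_heavy"]

    def test_substitution_outside_v_not_counted(self):
        assert bcr.shm_count("ACGTT", "ACGTA", v_region=(0, 4)) == 0

    def test_gaps_excluded(self):
        assert bcr.shm_count("A-GT", "ACGT") == 0

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            bcr.shm_count("ACG", "AC")


class TestIsotypeRank:
    @pytest.mark.parametrize("iso,rank", [("IGHM", 0), ("IGHA2", 8)])
    def test_locus_order(self, iso, rank):
        assert bcr.isotype_rank(iso) == rank

    def test_g1_before_a1(self):
        assert bcr.isotype_rank("IGHG1") < bcr.isotype_rank("IGHA1")

    def test_na_is_missing(self):
        assert bcr.isotype_rank("NA") is None
        assert bcr.isotype_rank(None) is None

    def test_unknown_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            bcr.isotype_rank("IGHZ9")


class TestGlycoSites:
    @pytest.mark.parametrize("seq,n", [("NAS", 1), ("NPS", 0), ("NAT", 1),
                                       ("NASNAS", 2), ("NNSS", 2)])
    def test_sequon_definition(self, seq, n):
        assert bcr.glyco_sites(seq)[0] == n

    def test_introduced_by_mutation(self):
        assert bcr.glyco_sites("NAS", "QAS") == (1, 1)
        assert bcr.glyco_sites("NAS", "NAS") == (1, 0)

    def test_non_aa_rejected(self):
        with pytest.raises(ValueError, match="non-amino-acid"):
            bcr.glyco_sites("NA1")

    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=0, max_size=30))
    @settings(max_examples=60, derandomize=True)
    def test_matches_regex_oracle(self, seq):
        import re

        expected = len([m for m in re.finditer(r"(?=(N[^P][ST]))", seq)])
        assert bcr.glyco_sites(seq)[0] == expected


class TestNjTree:
    def test_identical_leaves_form_zero_length_cherry(self):
        pairs = pd.DataFrame({
            "heavy_nt": ["AAAA", "AAAA", "TTTT"],
            "light_nt": ["CC", "CC", "GG"],
        }, index=["a", "b", "c"])
        nwk = bcr.nj_tree(pairs)
        import io

        from skbio import TreeNode

        tree = TreeNode.read(io.StringIO(nwk))
        a = tree.find("a")
        assert a.length == 0.0
        siblings = {n.name for n in a.parent.children}
        assert {"a", "b"} <= siblings

    def test_additive_four_taxon_topology_recovered(self):
        """NJ reconstructs the generating split of an additive matrix."""
        import io

        from skbio import TreeNode

        # ((a,b),(c,d)) with internal edge 2
        D = pd.DataFrame(
            [[0, 2, 7, 7], [2, 0, 7, 7], [7, 7, 0, 2], [7, 7, 2, 0]],
            index=list("abcd"), columns=list("abcd"), dtype=float)
        from skbio import DistanceMatrix
        from skbio.tree import nj

        tree = nj(DistanceMatrix(D.to_numpy(), list("abcd")), neg_as_zero=True)
        tree = TreeNode.read(io.StringIO(str(tree)))
        tips = {frozenset(n.name for n in clade.tips())
                for clade in tree.non_tips(include_self=False)}
        assert frozenset("ab") in tips or frozenset("cd") in tips

    def test_newick_roundtrip_preserves_labels(self, bcr_data):
        pairs, _ = bcr.filter_pairs(bcr_data["chains"])
        sub = pairs.iloc[:6]
        nwk = bcr.nj_tree(sub)
        import io

        from skbio import TreeNode

        tree = TreeNode.read(io.StringIO(nwk))
        assert {t.name for t in tree.tips()} == set(sub.index)

    def test_too_few_sequences(self):
        with pytest.raises(ValueError, match=">= 3"):
            bcr.nj_tree(pd.DataFrame({"heavy_nt": ["A"], "light_nt": ["C"]}))


class TestIndexHop:
    @staticmethod
    def _wells(n=300, seed=0):
        rng = np.random.default_rng(seed)
        rows = rng.integers(0, 16, n)
        cols = rng.integers(0, 24, n)
        return pd.DataFrame({"plate_id": "P1", "well_row": rows, "well_col": cols})

    def test_dispersed_members_large_p(self):
        occupied = self._wells()
        members = pd.DataFrame({"plate_id": "P1",
                                "well_row": [0, 8, 15, 0, 8],
                                "well_col": [0, 12, 23, 23, 0]})
        out = bcr.index_hop_check(members, occupied, n_perm=400, seed=1)
        assert out["p_value"] > 0.5

    def test_adjacent_block_small_p(self):
        occupied = self._wells()
        members = pd.DataFrame({"plate_id": "P1",
                                "well_row": [0, 0, 1, 1, 0],
                                "well_col": [0, 1, 0, 1, 2]})
        out = bcr.index_hop_check(members, occupied, n_perm=400, seed=1)
        assert out["p_value"] <= 0.05

    def test_p_value_bounds(self):
        occupied = self._wells()
        members = occupied.iloc[:4]
        out = bcr.index_hop_check(members, occupied, n_perm=50, seed=2)
        assert 0 < out["p_value"] <= 1

    def test_single_well_rejected(self):
        members = pd.DataFrame({"plate_id": ["P1", "P1"],
                                "well_row": [0, 0], "well_col": [0, 0]})
        with pytest.raises(ValueError, match="single well"):
            bcr.index_hop_check(members, self._wells(), n_perm=10)
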
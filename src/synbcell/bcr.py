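"""Paired-BCR filtering, clonotypes, clonality, SHM, isotypes, trees.

A clonotype groups cells of one donor sharing heavy- and light-chain V and
J gene usage (allele suffixes stripped); within a clonotype, each distinct
heavy+light nucleotide sequence pair is a numbered clone. "Identical
siblings" across the memory and plasma compartments share the exact
receptor sequence and isotype — the paper-level evidence for local B cell
maturation. Somatic hypermutation is counted over the aligned V segment,
N-linked glycosylation sequons (N-X-[S/T], X != P) are compared against the
germline, and a neighbor-joining tree over concatenated chain p-distances
summarizes one donor's repertoire.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ISOTYPE_RANKS = {
    "IGHM": 0,
    "IGHD": 1,
    "IGHG3": 2,
    "IGHG1": 3,
    "IGHA1": 4,
    "IGHG2": 5,
    "IGHG4": 6,
    "IGHE": 7,
    "IGHA2": 8,
}

_AA = set("ACDEFGHIKLMNPQRSTVWY")


# ---------------------------------------------------------------------------
# pairing


def filter_pairs(chains: pd.DataFrame, min_expression: float = 0.0):
    """Build one heavy+light pair per cell from a chain table.

    Keeps productive, full-length chains with expression >= the cutoff;
    when several chains share a locus the highest-expression one wins; a
    pair is emitted only when exactly one heavy and one light survive.
    Returns ``(pairs DataFrame, disposition Series)`` where the disposition
    logs every cell's outcome (paired / unpaired / no_heavy / ...).
    """
    df = chains.copy()
    dup = df.duplicated(subset=["cell_id", "locus", "sequence"])
    if dup.any():
        warnings.warn(f"removed {int(dup.sum())} duplicate (cell, locus, sequence) rows")
        df = df[~dup]
    expr_col = "consensus_count" if "consensus_count" in df.columns else "expression"
    complete = df["complete_vdj"] if "complete_vdj" in df.columns else True
    ok = df["productive"].astype(bool) & pd.Series(complete, index=df.index).astype(bool) \
        & (df[expr_col].astype(float) >= min_expression)
    df = df[ok]

    pairs, disposition = [], {}
    for cid, sub in chains.groupby("cell_id", sort=True):
        kept = df[df["cell_id"] == cid]
        heavies = kept[kept["locus"] == "IGH"]
        lights = kept[kept["locus"].isin(["IGK", "IGL"])]
        if len(heavies) == 0 and len(lights) == 0:
            disposition[cid] = "no_chains"
            continue
        if len(heavies) == 0:
            disposition[cid] = "no_heavy"
            continue
        if len(lights) == 0:
            disposition[cid] = "unpaired"
            continue
        h = heavies.sort_values(expr_col, ascending=False, kind="stable").iloc[0]
        l = lights.sort_values(expr_col, ascending=False, kind="stable").iloc[0]
        disposition[cid] = "paired"
        row = {"cell_id": cid, "donor_id": h.get("donor_id", "NA")}
        for tag, ch in (("heavy", h), ("light", l)):
            for colsrc, coldst in (
                ("v_call", "v_call"), ("j_call", "j_call"), ("c_call", "c_call"),
                ("sequence", "nt"), ("germline_alignment", "germline"),
                ("junction_aa", "cdr3"), ("v_germline_end", "v_end"),
            ):
                row[f"{tag}_{coldst}"] = ch.get(colsrc)
        for col in ("plate_id", "well_row", "well_col"):
            if col in chains.columns:
                row[col] = h.get(col)
        pairs.append(row)
    pairs_df = pd.DataFrame(pairs)
    if len(pairs_df):
        pairs_df = pairs_df.set_index("cell_id")
    return pairs_df, pd.Series(disposition, name="disposition")


# ---------------------------------------------------------------------------
# clonotypes


def strip_allele(call: str) -> str:
    """IGHV5-51*01 -> IGHV5-51; ambiguous multi-allele calls keep one gene."""
    return str(call).split(",")[0].split("*")[0]


@dataclass
class Clonotype:
    donor_id: str
    key: tuple  # (heavy V, heavy J, light V, light J), gene level
    members: pd.DataFrame  # pairs, indexed by cell_id
    clone_ids: pd.Series = field(default_factory=pd.Series)  # member -> int
    expanded: bool = False

    @property
    def size(self) -> int:
        return len(self.members)


def group_clonotypes(pairs: pd.DataFrame, key_level: str = "gene") -> list[Clonotype]:
    """Group pairs into clonotypes within donors by heavy/light V/J keys.

    Within a clonotype, clone ids number the distinct heavy+light
    nucleotide sequence pairs, by descending multiplicity then sequence
    order; clonotypes with >= 2 members are flagged expanded.
    """
    if len(pairs) == 0:
        return []
    strip = (lambda c: str(c)) if key_level == "allele" else strip_allele
    keyed = pairs.assign(
        _key=[(strip(r.heavy_v_call), strip(r.heavy_j_call),
               strip(r.light_v_call), strip(r.light_j_call))
              for r in pairs.itertuples()])
    out = []
    for (donor, key), sub in sorted(
            keyed.groupby(["donor_id", "_key"], sort=False),
            key=lambda kv: (kv[0][0], kv[0][1])):
        seqs = sub["heavy_nt"] + "|" + sub["light_nt"]
        counts = seqs.value_counts()
        ordered = sorted(counts.index, key=lambda s: (-counts[s], s))
        clone_of = {s: i + 1 for i, s in enumerate(ordered)}
        clone_ids = seqs.map(clone_of)
        out.append(Clonotype(donor_id=donor, key=key,
                             members=sub.drop(columns="_key"),
                             clone_ids=clone_ids, expanded=len(sub) >= 2))
    return out


# ---------------------------------------------------------------------------
# compartment sharing and clonality


def shared_clonality(clonotypes: list[Clonotype],
                     compartments: pd.Series | None = None):
    """Memory/plasma composition and identical-sibling counts per clonotype.

    An identical sibling is a member of the other compartment with
    byte-identical heavy+light nucleotide sequences AND the same heavy
    constant-gene call; a similar member shares the clonotype but not the
    sequence. Returns ``(per-clonotype DataFrame, summary dict)``.
    """
    rows = []
    n_na = 0
    for ci, ct in enumerate(clonotypes):
        comp = compartments.reindex(ct.members.index) if compartments is not None \
            else ct.members.get("compartment", pd.Series("NA", index=ct.members.index))
        comp = comp.fillna("NA")
        n_na += int((comp == "NA").sum())
        known = ct.members[comp != "NA"]
        kcomp = comp[comp != "NA"]
        counts = kcomp.value_counts()
        n_mem = int(counts.get("memory", 0))
        n_pc = int(counts.get("plasma", 0))
        spans = n_mem > 0 and n_pc > 0
        # plasma-reference view: memory members identical to (sequence +
        # isotype) or merely clonally related to some plasma member
        sigs = (known["heavy_nt"] + "|" + known["light_nt"] + "|"
                + known["heavy_c_call"].astype(str))
        plasma_sigs = set(sigs[kcomp == "plasma"])
        n_identical = 0
        n_similar = 0
        if n_pc > 0:
            for cid in known.index[kcomp == "memory"]:
                if sigs.loc[cid] in plasma_sigs:
                    n_identical += 1
                else:
                    n_similar += 1
        rows.append({"clonotype": ci, "donor_id": ct.donor_id,
                     "key": "|".join(ct.key), "size": ct.size,
                     "n_memory": n_mem, "n_plasma": n_pc,
                     "spans_compartments": spans,
                     "n_identical_cross_siblings": n_identical,
                     "n_similar_members": n_similar})
    report = pd.DataFrame(rows)
    summary = {
        "n_clonotypes": len(clonotypes),
        "n_spanning_memory_plasma": int(report["spans_compartments"].sum())
        if len(report) else 0,
        "n_members_excluded_na_compartment": n_na,
    }
    return report, summary


def clonality_fraction(n_members: int, total: int):
    """Clonotype members as a fraction of the donor's memory+plasma cells.

    Returns ``(fraction, percent)`` with the percent rounded to the nearest
    integer, the form quoted in per-donor clonality summaries.
    """
    if total <= 0:
        raise ValueError("donor cell total must be positive")
    frac = n_members / total
    return frac, int(round(100.0 * frac))


# ---------------------------------------------------------------------------
# per-chain sequence features


def shm_count(sequence_nt: str, germline_nt: str,
              v_region: tuple[int, int] | None = None) -> int:
    """Mutations vs germline over the aligned V segment.

    Counts aligned positions where both residues are non-gap and differ,
    restricted to ``v_region`` (half-open; default: the whole alignment).
    """
    if len(sequence_nt) != len(germline_nt):
        raise ValueError("sequence and germline alignments differ in length")
    start, end = v_region if v_region is not None else (0, len(sequence_nt))
    n = 0
    for i in range(start, min(end, len(sequence_nt))):
        s, g = sequence_nt[i], germline_nt[i]
        if s != "-" and g != "-" and s != g:
            n += 1
    return n


def isotype_rank(c_call) -> int | None:
    """Class-switch order of a heavy constant gene (IGHM=0 ... IGHA2=8)."""
    if c_call is None or (isinstance(c_call, float) and np.isnan(c_call)) \
            or c_call in ("", "NA"):
        return None
    name = strip_allele(c_call)
    if name not in ISOTYPE_RANKS:
        raise ValueError(f"unknown heavy constant gene {c_call}")
    return ISOTYPE_RANKS[name]


def _sequon_positions(aa: str) -> set[int]:
    out = set()
    for i in range(len(aa) - 2):
        if aa[i] == "N" and aa[i + 1] != "P" and aa[i + 2] in "ST":
            out.add(i)
    return out


def glyco_sites(aa_sequence: str, germline_aa: str | None = None):
    """Count N-X-[S/T] sequons (X != P) and those absent from the germline.

    Returns ``(n_sites, n_introduced)``; ``n_introduced`` compares each
    mature sequon position against the aligned germline.
    """
    for seq in (aa_sequence, germline_aa or ""):
        bad = set(seq) - _AA
        if bad:
            raise ValueError(f"non-amino-acid characters: {sorted(bad)}")
    sites = _sequon_positions(aa_sequence)
    if germline_aa is None:
        return len(sites), 0
    germ_sites = _sequon_positions(germline_aa)
    return len(sites), len(sites - germ_sites)


# ---------------------------------------------------------------------------
# neighbor-joining tree


def nj_tree(pairs: pd.DataFrame) -> str:
    """Neighbor-joining newick over concatenated heavy+light p-distances.

    Sequences are gap-padded to equal length; p-distance counts mismatches
    over positions where both sequences are non-gap. Negative branch
    lengths are clamped at zero.
    """
    if len(pairs) < 3:
        raise ValueError("need >= 3 paired sequences")
    from skbio import DistanceMatrix
    from skbio.tree import nj

    seqs = (pairs["heavy_nt"] + pairs["light_nt"]).to_dict()
    width = max(len(s) for s in seqs.values())
    mats = {k: np.frombuffer(s.ljust(width, "-").encode(), dtype="S1")
            for k, s in seqs.items()}
    ids = list(pairs.index)
    n = len(ids)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = mats[ids[i]], mats[ids[j]]
            both = (a != b"-") & (b != b"-")
            total = int(both.sum())
            D[i, j] = D[j, i] = (np.sum(a[both] != b[both]) / total) if total else 0.0
    tree = nj(DistanceMatrix(D, ids), neg_as_zero=True)
    return str(tree).strip()


# ---------------------------------------------------------------------------
# index-hopping permutation test


def index_hop_check(members: pd.DataFrame, occupied_wells: pd.DataFrame,
                    n_perm: int = 10000, seed: int = 0) -> dict:
    """Permutation test for well adjacency of a clonotype's members.

    The statistic is the number of member pairs in 8-neighborhood-adjacent
    wells of the same plate. Under the null, member positions are permuted
    uniformly over the occupied wells of their plate. Add-one p-value
    (always in (0, 1]).
    """
    req = ("plate_id", "well_row", "well_col")
    for c in req:
        if c not in members.columns or c not in occupied_wells.columns:
            raise ValueError(f"missing column {c}")
    uniq = members[list(req)].drop_duplicates()
    if len(uniq) <= 1:
        raise ValueError("members occupy a single well: adjacency undefined")

    def stat(pos: np.ndarray, plates: np.ndarray) -> int:
        s = 0
        for i in range(len(pos)):
            for j in range(i + 1, len(pos)):
                if plates[i] != plates[j]:
                    continue
                dr = abs(pos[i, 0] - pos[j, 0])
                dc = abs(pos[i, 1] - pos[j, 1])
                if max(dr, dc) == 1:
                    s += 1
        return s

    plates = members["plate_id"].to_numpy()
    pos = members[["well_row", "well_col"]].to_numpy(int)
    observed = stat(pos, plates)

    rng = np.random.default_rng(seed)
    wells_by_plate = {p: sub[["well_row", "well_col"]].drop_duplicates().to_numpy(int)
                      for p, sub in occupied_wells.groupby("plate_id")}
    counts_by_plate = pd.Series(plates).value_counts()
    n_ge = 0
    for _ in range(n_perm):
        perm_pos = np.empty_like(pos)
        perm_plates = []
        row = 0
        for p, cnt in counts_by_plate.items():
            pool = wells_by_plate[p]
            take = rng.choice(len(pool), size=cnt, replace=False)
            perm_pos[row:row + cnt] = pool[take]
            perm_plates += [p] * cnt
            row += cnt
        if stat(perm_pos, np.asarray(perm_plates)) >= observed:
            n_ge += 1
    p = (1 + n_ge) / (n_perm + 1)
    return {"statistic": int(observed), "p_value": float(p), "n_perm": int(n_perm)}
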
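"""End-to-end orchestration: config validation, staged runs, manifest.

Stages communicate only through serialized artifacts under
``out/<stage>/``; a manifest JSON records every artifact with its SHA-256
content hash, so byte-identical reruns are checkable. The global seed is
propagated to every stochastic stage through stable derived seeds.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bcr, integrate, scnorm, scqc, spatial, synth
from ._utils import derive_seed, sha256_file
from .sccluster import (classify_gates, crosstab_clusters_gates, embed,
                        gate_fractions, kmeans_merge, top20_deg)

_SYNTH_SCALARS = (
    "n_genes", "n_spike_genes", "capture_efficiency_sd", "dropout_rate",
    "n_empty_wells", "bad_cell_fraction", "batch_effect_sd", "cxcl12_factor",
    "n_background_cells",
)


def make_synth_config(seed: int, overrides: dict | None = None) -> synth.SynthConfig:
    """SynthConfig from a pipeline config block (scalar overrides only)."""
    overrides = dict(overrides or {})
    kwargs = {}
    grid = overrides.pop("section_grid", None)
    if grid is not None:
        kwargs["sections"] = synth.default_sections(int(grid[0]), int(grid[1]))
    if "n_cells_per_cluster" in overrides:
        kwargs["n_cells_per_cluster"] = {
            str(k): int(v) for k, v in overrides.pop("n_cells_per_cluster").items()}
    for key in list(overrides):
        if key in _SYNTH_SCALARS:
            kwargs[key] = overrides.pop(key)
    if overrides:
        raise ValueError(f"unknown synth config keys: {sorted(overrides)}")
    return synth.SynthConfig(seed=seed, **kwargs)


def validate_config(config: dict) -> dict:
    """Schema and cross-reference diagnostics; returns {'errors', 'warnings'}."""
    errors, warns = [], []
    if not isinstance(config, dict) or not config:
        return {"errors": ["empty config"], "warnings": []}
    seed = config.get("seed")
    if not isinstance(seed, int) or isinstance(seed, bool):
        errors.append("field 'seed' must be an integer")
    known = {"seed", "out_dir", "synth", "inputs", "scqc", "scnorm",
             "sccluster", "spatial", "integrate", "bcr"}
    for key in set(config) - known:
        warns.append(f"unknown top-level key '{key}'")
    if "synth" in config and config["synth"] is not None:
        try:
            make_synth_config(seed if isinstance(seed, int) else 0, config["synth"])
        except (ValueError, TypeError) as err:
            errors.append(f"synth block: {err}")
    inputs = config.get("inputs") or {}
    for name, path in inputs.items():
        if not Path(path).exists():
            errors.append(f"input '{name}' does not exist: {path}")
    if "synth" not in config and not inputs:
        errors.append("either a 'synth' block or an 'inputs' block is required")
    if "integrate" in config and "spatial" not in config:
        errors.append("integrate stage requires the spatial stage")
    return {"errors": errors, "warnings": warns}


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _write_json(obj, path):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if dataclasses.is_dataclass(x):
        return dataclasses.asdict(x)
    raise TypeError(f"not JSON-serializable: {type(x)}")


def run_all(config: dict, out_dir=None) -> dict:
    """Execute synth -> scqc -> scnorm -> sccluster [-> spatial -> integrate]
    [-> bcr], writing artifacts and a hash manifest.

    Optional stages are skipped (and noted in the manifest) when their
    config block is absent. Returns the manifest dict.
    """
    diag = validate_config(config)
    if diag["errors"]:
        raise ValueError("invalid config: " + "; ".join(diag["errors"]))
    for w in diag["warnings"]:
        warnings.warn(w)
    seed = int(config["seed"])
    out = Path(out_dir if out_dir is not None else config.get("out_dir", "out"))
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": seed, "stages": [], "skipped": [], "artifacts": {}}

    def record(stage):
        manifest["stages"].append(stage)
        d = out / stage
        for f in sorted(d.rglob("*")):
            if f.is_file():
                manifest["artifacts"][str(f.relative_to(out))] = sha256_file(f)

    # ---- synth ------------------------------------------------------------
    scfg = make_synth_config(seed, config.get("synth"))
    d = out / "synth"
    d.mkdir(exist_ok=True)
    cem, qc = synth.generate_sc_counts(scfg)
    synth.write_sc_counts(cem, d / "sc")
    qc.to_csv(d / "qc_metrics.csv")
    real = cem.obs[~cem.obs["is_control"]]
    index = synth.generate_index_sort(real["true_cluster"], scfg)
    index.to_csv(d / "index_sort.csv")
    sections, sp_truth = synth.generate_spatial(scfg)
    synth.write_spatial(sections, d / "sections")
    sp_truth.to_csv(d / "spatial_truth.csv")
    chains, bcr_truth = synth.generate_bcr(scfg)
    synth.write_airr(chains, d / "chains.tsv")
    bcr_truth.to_csv(d / "bcr_truth.csv")
    # external-reference stand-ins: per-type signature lists and mean profiles
    model = synth.gene_model(scfg)
    profiles = model.profiles()
    profiles.to_csv(d / "reference_profiles.tsv", sep="\t")
    sig_rows = []
    for cl, (genes, _fc) in {**scfg.marker_programs, **scfg.extra_celltypes}.items():
        for g in genes:
            sig_rows.append({"cluster": cl, "gene": g})
    pd.DataFrame(sig_rows).to_csv(d / "reference_signatures.tsv", sep="\t", index=False)
    record("synth")

    # ---- scqc -------------------------------------------------------------
    qcfg = config.get("scqc") or {}
    d = out / "scqc"
    d.mkdir(exist_ok=True)
    metrics = pd.read_csv(out / "synth" / "qc_metrics.csv", index_col=0)
    res = scqc.run_qc(metrics, k=float(qcfg.get("margin", 3.0)),
                      threshold=qcfg.get("threshold"))
    pd.DataFrame({"pc1": res.scores, "keep": res.keep_mask}).to_csv(d / "keep_mask.csv")
    _write_json({"threshold": res.threshold,
                 "orientation_sign": res.orientation_sign,
                 "n_kept": int(res.keep_mask.sum()),
                 "n_excluded": int((~res.keep_mask).sum())}, d / "report.json")
    record("scqc")

    # ---- scnorm -----------------------------------------------------------
    ncfg = config.get("scnorm") or {}
    d = out / "scnorm"
    d.mkdir(exist_ok=True)
    cem = synth.read_sc_counts(out / "synth" / "sc")
    keep = pd.read_csv(out / "scqc" / "keep_mask.csv", index_col=0)["keep"]
    kept_cells = [c for c in cem.cell_ids if keep.get(c, False)]
    col_idx = [cem.cell_ids.index(c) for c in kept_cells]
    counts = cem.counts[:, col_idx]
    spike_mask = cem.is_spike
    tech = scnorm.spike_size_factors(counts, spike_mask, kept_cells)
    bio = scnorm.pooled_size_factors(counts[~spike_mask])
    pd.DataFrame({"technical": tech, "biological": bio},
                 index=pd.Index(kept_cells, name="cell_id")).to_csv(d / "factors.csv")
    lognorm = scnorm.normalize(counts, bio, spike_mask, tech)
    gene_names = np.asarray(cem.gene_names)
    spike_expr = lognorm[spike_mask]
    trend = scnorm.fit_technical_trend(spike_expr.mean(axis=1),
                                       spike_expr.var(axis=1, ddof=1))
    dec = scnorm.decompose_variance(lognorm[~spike_mask], trend,
                                    gene_names[~spike_mask])
    dec.to_csv(d / "decomposition.csv")
    hvgs = scnorm.select_hvgs(dec, bio_min=float(ncfg.get("bio_min", 0.5)),
                              fdr_max=float(ncfg.get("fdr_max", 0.05)))
    Path(d / "hvgs.txt").write_text("\n".join(hvgs) + ("\n" if hvgs else ""))
    expr = pd.DataFrame(lognorm[~spike_mask].T, index=kept_cells,
                        columns=gene_names[~spike_mask])
    expr.round(6).to_csv(d / "lognorm.csv")
    record("scnorm")

    # ---- sccluster --------------------------------------------------------
    ccfg = config.get("sccluster") or {}
    d = out / "sccluster"
    d.mkdir(exist_ok=True)
    expr = pd.read_csv(out / "scnorm" / "lognorm.csv", index_col=0)
    hvgs = [g for g in Path(out / "scnorm" / "hvgs.txt").read_text().split() if g]
    hv_expr = expr[[g for g in hvgs if g in expr.columns]]
    emb = embed(hv_expr, seed=derive_seed(seed, "umap"),
                n_neighbors=min(15, len(hv_expr) - 1))
    emb.round(6).to_csv(d / "embedding.csv")
    assignment = kmeans_merge(hv_expr, k=int(ccfg.get("k", 5)),
                              seed=derive_seed(seed, "kmeans"),
                              cluster_on=ccfg.get("cluster_on", "pca"),
                              n_pcs=int(ccfg.get("n_pcs", 10)))
    labels_df = pd.DataFrame({"kmeans": assignment.kmeans_label,
                              "merged": assignment.merged_label})
    labels_df.to_csv(d / "labels.csv")
    degs = top20_deg(expr, assignment.merged_label)
    for cl, tbl in degs.items():
        tbl.round(6).to_csv(d / f"deg_{cl}.csv")
    index = pd.read_csv(out / "synth" / "index_sort.csv", index_col=0)
    index = index.loc[index.index.intersection(expr.index)]
    gates = classify_gates(index)
    gates.to_csv(d / "gates.csv")
    obs = pd.read_csv(out / "synth" / "sc" / "obs.csv", index_col=0)
    gate_fractions(gates, obs["donor_id"]).round(3).to_csv(d / "gate_fractions.csv")
    crosstab_clusters_gates(assignment, gates).to_csv(d / "contingency.csv")
    # linear-scale cluster mean profiles for spot scoring downstream
    cluster_means = np.expm1(expr).groupby(assignment.merged_label).mean().T
    cluster_means.round(6).to_csv(d / "cluster_profiles.tsv", sep="\t")
    record("sccluster")

    # ---- spatial ----------------------------------------------------------
    if "spatial" not in config:
        manifest["skipped"] += ["spatial", "integrate"]
    else:
        pcfg = config.get("spatial") or {}
        d = out / "spatial"
        d.mkdir(exist_ok=True)
        sections = synth.read_spatial(out / "synth" / "sections")
        residuals = [spatial.normalize_section(s.counts) for s in sections]
        emb = spatial.integrate_sections(residuals,
                                         n_pcs=int(pcfg.get("n_pcs", 30)),
                                         seed=derive_seed(seed, "harmony"))
        emb.round(6).to_csv(d / "embedding.csv")
        labels = spatial.snn_cluster(emb, k_nn=int(pcfg.get("k_nn", 20)),
                                     resolution=float(pcfg.get("resolution", 0.8)),
                                     seed=derive_seed(seed, "snn"))
        labels.to_csv(d / "spot_clusters.csv")
        counts_all = pd.concat([s.counts for s in sections])
        degs = spatial.spatial_deg(counts_all, labels)
        for cl, tbl in degs.items():
            tbl.round(6).to_csv(d / f"deg_cluster{cl}.csv")
        common = residuals[0].columns
        for r in residuals[1:]:
            common = common.intersection(r.columns)
        shifted = spatial.shift_nonnegative(pd.concat([r[common] for r in residuals]))
        n_factors = int(pcfg.get("n_factors", 20))
        fm = spatial.nmf_factorize(shifted, n_factors=n_factors,
                                   seed=derive_seed(seed, "nmf"),
                                   max_iter=int(pcfg.get("nmf_max_iter", 200)))
        fm.W.round(6).to_csv(d / "nmf_W.tsv", sep="\t")
        fm.H.round(6).to_csv(d / "nmf_H.tsv", sep="\t")
        _write_json({f"factor_{k}": v for k, v in fm.top_genes(20).items()},
                    d / "factor_top_genes.json")
        record("spatial")

        # ---- integrate ----------------------------------------------------
        icfg = config.get("integrate") or {}
        d = out / "integrate"
        d.mkdir(exist_ok=True)
        expr = pd.read_csv(out / "scnorm" / "lognorm.csv", index_col=0)
        labels_df = pd.read_csv(out / "sccluster" / "labels.csv", index_col=0)
        merged = labels_df["merged"]
        sigs = integrate.signature_enrichment(
            expr, merged, targets=["memory", "plasma"],
            comparators=["naive", "memory", "plasma"])
        sigs.table.round(6).to_csv(d / "signatures.csv", index=False)
        ref_lists = integrate.read_reference_signatures(
            out / "synth" / "reference_signatures.tsv")
        universe = expr.columns.tolist()
        fisher = {}
        for ours, theirs in (("memory", "memory"), ("plasma", "plasma")):
            try:
                fr = integrate.fisher_overlap(sigs.genes(ours),
                                              ref_lists[theirs], universe)
                fisher[ours] = {"odds_ratio": fr.odds_ratio, "p_value": fr.p_value,
                                "table": fr.table}
            except ValueError as err:
                fisher[ours] = {"error": str(err)}
        _write_json(fisher, d / "fisher.json")

        profiles = pd.read_csv(out / "synth" / "reference_profiles.tsv",
                               sep="\t", index_col=0)
        sig_union = sorted({g for gs in ref_lists.values() for g in gs})
        sections = synth.read_spatial(out / "synth" / "sections")
        counts_all = pd.concat([s.counts for s in sections])
        depth = counts_all.sum(axis=1).to_numpy(float)
        spot_norm = counts_all * (np.median(depth) / np.clip(depth, 1, None))[:, None]
        scores = integrate.score_spots(spot_norm, profiles, sig_union)
        scores.round(6).to_csv(d / "spot_scores.csv")
        sec_labels = pd.Series(
            np.concatenate([[s.section_id] * len(s.counts) for s in sections]),
            index=counts_all.index)
        coloc = pd.DataFrame({
            ref: integrate.colocalize(scores, ref, sections=sec_labels,
                                      pooling=icfg.get("pooling", "all-spots"))
            for ref in ("memory", "plasma")})
        coloc.round(6).to_csv(d / "colocalization.csv")
        positions = pd.concat([s.positions for s in sections])
        for gene in icfg.get("overlay_genes", ("CXCL12", "VIM")):
            integrate.gene_overlay(counts_all, positions, gene).to_csv(
                d / f"overlay_{gene}.csv")
        record("integrate")

    # ---- bcr --------------------------------------------------------------
    if "bcr" not in config:
        manifest["skipped"].append("bcr")
    else:
        bcfg = config.get("bcr") or {}
        d = out / "bcr"
        d.mkdir(exist_ok=True)
        chains = synth.read_airr(out / "synth" / "chains.tsv")
        truth = pd.read_csv(out / "synth" / "bcr_truth.csv", index_col=0)
        pairs, disposition = bcr.filter_pairs(
            chains, min_expression=float(bcfg.get("min_expression", 0.0)))
        disposition.rename_axis("cell_id").to_csv(d / "disposition.csv")
        pairs = pairs.join(truth["compartment"])
        clonotypes = bcr.group_clonotypes(pairs)
        report, summary = bcr.shared_clonality(clonotypes,
                                               truth["compartment"])
        report.to_csv(d / "clonotypes.csv", index=False)
        totals = pairs[pairs["compartment"].isin(["memory", "plasma"])] \
            .groupby("donor_id").size()
        clonality = {}
        for ct in clonotypes:
            if ct.size >= 2:
                frac, pct = bcr.clonality_fraction(ct.size,
                                                   int(totals[ct.donor_id]))
                clonality[f"{ct.donor_id}:{'|'.join(ct.key)}"] = {
                    "members": ct.size, "fraction": frac, "percent": pct}
        summary["clonality"] = clonality
        shm = pd.DataFrame({
            "shm_heavy": [bcr.shm_count(r.heavy_nt, r.heavy_germline,
                                        (0, int(r.heavy_v_end)))
                          for r in pairs.itertuples()],
            "shm_light": [bcr.shm_count(r.light_nt, r.light_germline,
                                        (0, int(r.light_v_end)))
                          for r in pairs.itertuples()],
            "isotype_rank": [bcr.isotype_rank(c) for c in pairs["heavy_c_call"]],
        }, index=pairs.index)
        shm.to_csv(d / "chain_features.csv")
        Path(d / "tree.nwk").write_text(bcr.nj_tree(pairs) + "\n")
        largest = max(clonotypes, key=lambda c: c.size)
        hop = bcr.index_hop_check(largest.members, chains,
                                  n_perm=int(bcfg.get("n_perm", 2000)),
                                  seed=derive_seed(seed, "indexhop"))
        summary["index_hop_largest_clone"] = hop
        _write_json(summary, d / "summary.json")
        record("bcr")

    _write_json(manifest, out / "manifest.json")
    return manifest


def dataset_summary(per_donor_counts: dict[str, int],
                    n_control_wells: int) -> dict:
    """Accounting totals of a sequencing run: cells and total wells."""
    n_cells = int(sum(per_donor_counts.values()))
    return {"n_cells": n_cells, "n_files": n_cells + int(n_control_wells)}
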
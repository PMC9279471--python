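import warnings

import numpy as np
import pandas as pd
import pytest

from synbcell import scnorm, scqc, synth

warnings.filterwarnings("ignore", category=UserWarning, module="umap")


@pytest.fixture(scope="session")
def small_cfg():
    return synth.SynthConfig(
        seed=11,
        n_genes=400,
        n_spike_genes=30,
        n_cells_per_cluster={"naive": 60, "memory": 90, "plasma": 50},
        n_empty_wells=6,
        sections=synth.default_sections(18, 18),
    )


@pytest.fixture(scope="session")
def sc_data(small_cfg):
    cem, qc = synth.generate_sc_counts(small_cfg)
    return {"cem": cem, "qc": qc, "cfg": small_cfg}


@pytest.fixture(scope="session")
def normalized(sc_data):
    """QC-filtered, normalized expression with HVGs and planted labels."""
    cem, qc = sc_data["cem"], sc_data["qc"]
    res = scqc.run_qc(qc)
    keep = res.keep_mask & ~cem.obs["is_control"]
    idx = np.flatnonzero(keep.to_numpy())
    counts = cem.counts[:, idx]
    tech = scnorm.spike_size_factors(counts, cem.is_spike)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bio = scnorm.pooled_size_factors(counts[~cem.is_spike])
    lognorm = scnorm.normalize(counts, bio, cem.is_spike, tech)
    spike_expr = lognorm[cem.is_spike]
    trend = scnorm.fit_technical_trend(spike_expr.mean(axis=1),
                                       spike_expr.var(axis=1, ddof=1))
    genes = np.asarray(cem.gene_names)
    dec = scnorm.decompose_variance(lognorm[~cem.is_spike], trend,
                                    genes[~cem.is_spike])
    hvgs = scnorm.select_hvgs(dec)
    expr = pd.DataFrame(lognorm[~cem.is_spike].T,
                        index=np.asarray(cem.cell_ids)[idx],
                        columns=genes[~cem.is_spike])
    return {
        "expr": expr,
        "hvgs": hvgs,
        "decomposition": dec,
        "trend": trend,
        "truth": cem.obs["true_cluster"].iloc[idx],
        "efficiency": cem.obs["true_efficiency"].to_numpy()[idx],
        "tech_factors": tech,
        "bio_factors": bio,
    }


@pytest.fixture(scope="session")
def spatial_data(small_cfg):
    sections, truth = synth.generate_spatial(small_cfg)
    return {"sections": sections, "truth": truth, "cfg": small_cfg}


@pytest.fixture(scope="session")
def residuals(spatial_data):
    from synbcell import spatial

    return [spatial.normalize_section(s.counts) for s in spatial_data["sections"]]


@pytest.fixture(scope="session")
def embedding(residuals):
    from synbcell import spatial

    return spatial.integrate_sections(residuals, seed=9)


@pytest.fixture(scope="session")
def spot_labels(embedding):
    from synbcell import spatial

    return spatial.snn_cluster(embedding, seed=9)


PIPELINE_CONFIG = {
    "seed": 7,
    "synth": {
        "n_genes": 400,
        "n_spike_genes": 30,
        "n_cells_per_cluster": {"naive": 60, "memory": 90, "plasma": 50},
        "section_grid": [12, 12],
    },
    "spatial": {"n_factors": 8, "nmf_max_iter": 100},
    "integrate": {},
    "bcr": {"n_perm": 300},
}


@pytest.fixture(scope="session")
def pipeline_runs(tmp_path_factory):
    """The same small end-to-end run executed twice."""
    from synbcell import pipeline

    manifests = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for tag in ("run1", "run2"):
            out = tmp_path_factory.mktemp(tag)
            manifests.append((out, pipeline.run_all(dict(PIPELINE_CONFIG), out)))
    return manifests


@pytest.fixture(scope="session")
def bcr_data():
    cfg = synth.SynthConfig(seed=13)
    chains, truth = synth.generate_bcr(cfg)
    return {"chains": chains, "truth": truth, "cfg": cfg}
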
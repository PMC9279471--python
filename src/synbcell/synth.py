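"""Synthetic inputs with the statistical structure the downstream analysis assumes.

The generators emulate the study design end to end: index-sorted Smart-seq2
B cells on 384-well plates with ERCC spike-ins and empty control wells;
three transcriptional programs (naive / memory / plasma); Visium-like
multi-section spot grids with infiltrate, plasma-niche and stromal regions
and a CXCL12-high niche; and paired-BCR clone families that span the memory
and plasma compartments with somatic hypermutation and isotype structure.
Every generator is deterministic given the config seed, and every planted
truth (cluster labels, mixture weights, clone families, mutation positions)
is returned alongside the data so recovery can be scored exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import derive_seed

# ---------------------------------------------------------------------------
# configuration


DEFAULT_MARKER_PROGRAMS: dict[str, tuple[tuple[str, ...], float]] = {
    "naive": (("IGHD", "IL4R", "FCER2"), 6.0),
    "memory": (("ITGAM", "GPR183", "CD27", "TNFRSF13B"), 6.0),
    "plasma": (("XBP1", "SDC1", "PRDM1", "SLAMF7", "JCHAIN"), 8.0),
}

# co-regulated program genes beyond the canonical markers: transcriptional
# programs span dozens of genes, which is what makes clusters separable
_N_PROGRAM_AUX = 40


def _augment_programs(programs):
    out = {}
    for cl, (genes, fc) in programs.items():
        aux = tuple(f"{cl.upper()[:3]}X{i:03d}" for i in range(_N_PROGRAM_AUX))
        out[cl] = (tuple(genes) + aux, fc)
    return out

# additional tissue cell types used only by the spatial generator
DEFAULT_EXTRA_CELLTYPES: dict[str, tuple[tuple[str, ...], float]] = {
    "fibroblast": (("VIM", "COL1A1", "PDGFRB", "THY1"), 8.0),
    "tcell": (("CD3D", "CD3E", "TRAC", "IL7R"), 8.0),
}

_NAMED_GENES = ("CXCL12",)  # always present in the shared namespace

ISOTYPE_ORDER = (
    "IGHM",
    "IGHD",
    "IGHG3",
    "IGHG1",
    "IGHA1",
    "IGHG2",
    "IGHG4",
    "IGHE",
    "IGHA2",
)


@dataclass
class RegionSpec:
    """Rectangular block of a section grid with a cell-type mixture."""

    name: str
    row0: int
    row1: int  # half-open
    col0: int
    col1: int
    weights: dict[str, float] = field(default_factory=dict)


@dataclass
class SectionSpec:
    section_id: str
    donor_id: str
    serostatus: str  # "ACPA+" or "ACPA-"
    n_rows: int
    n_cols: int
    regions: list[RegionSpec] = field(default_factory=list)
    depth: float = 8000.0  # expected UMIs per spot, typical Visium
    depth_sd: float = 0.3  # log-scale spot-to-spot depth spread (tissue density)


@dataclass
class CloneSpec:
    """One planted clone family.

    Members sharing a ``sequence_groups`` id receive byte-identical mutated
    heavy and light chains ("identical siblings"); distinct groups get
    distinct mutation positions.
    """

    size: int
    compartments: list[str]  # per member, "plasma"/"memory"
    n_shm_heavy: int
    n_shm_light: int
    isotypes: list[str]  # heavy-chain constant gene per member
    sequence_groups: list[int] | None = None
    v_heavy: str | None = None
    j_heavy: str | None = None
    v_light: str | None = None
    j_light: str | None = None


def default_sections(n_rows: int = 24, n_cols: int = 24) -> list[SectionSpec]:
    """Two-donor layout with an infiltrate, a plasma niche and a stromal band."""

    # every type has three distinct abundance levels across the regions, as
    # in real synovium where no compartment is exclusive to one cell type
    def regions():
        third = n_rows // 3
        return [
            RegionSpec("infiltrate", 0, third, 0, n_cols,
                       {"memory": 0.40, "tcell": 0.30, "naive": 0.15,
                        "fibroblast": 0.10, "plasma": 0.05}),
            RegionSpec("niche", third, 2 * third, 0, n_cols,
                       {"plasma": 0.55, "memory": 0.18, "fibroblast": 0.15,
                        "tcell": 0.10, "naive": 0.02}),
            RegionSpec("stroma", 2 * third, n_rows, 0, n_cols,
                       {"fibroblast": 0.65, "tcell": 0.20, "memory": 0.08,
                        "naive": 0.05, "plasma": 0.02}),
        ]

    return [
        SectionSpec("S1", "A2", "ACPA+", n_rows, n_cols, regions()),
        SectionSpec("S2", "A4", "ACPA-", n_rows, n_cols, regions()),
    ]


_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def default_germline_segments() -> dict[str, str]:
    """Synthetic reference V/J segment sequences (fixed, seed-independent).

    Stop-free random codons; V segments 294 nt, J segments 48 nt. These are
    stand-ins for IMGT germline alleles, not real sequences.
    """
    rng = np.random.default_rng(20230915)

    def seq(n_codons):
        return "".join(rng.choice(_SENSE_CODONS, size=n_codons))

    segs = {}
    for name in ("IGHV5-51*01", "IGHV1-2*01", "IGHV3-23*01", "IGHV4-34*01",
                 "IGHV3-7*01", "IGHV1-69*01"):
        segs[name] = seq(98)
    for name in ("IGHJ4*02", "IGHJ5*02", "IGHJ6*02"):
        segs[name] = seq(16)
    for name in ("IGKV2-40*01", "IGKV1-5*01", "IGKV3-20*01", "IGKV2-28*01"):
        segs[name] = seq(98)
    for name in ("IGKJ5*01", "IGKJ1*01", "IGKJ2*01"):
        segs[name] = seq(16)
    return segs


def _default_clone_spec() -> list[CloneSpec]:
    return [
        # ACPA-like clonotype: two identical plasma siblings + one similar memory member
        CloneSpec(3, ["plasma", "plasma", "memory"], 39, 27,
                  ["IGHG1", "IGHG1", "IGHG1"], [0, 0, 1],
                  v_heavy="IGHV5-51*01", j_heavy="IGHJ4*02",
                  v_light="IGKV2-40*01", j_light="IGKJ5*01"),
        # large expanded clone with a dominant identical sequence
        CloneSpec(21, ["plasma"] * 5 + ["memory"] * 16, 12, 8,
                  ["IGHG1"] * 18 + ["IGHA1"] * 3,
                  [0] * 16 + [1, 2, 3, 4, 5]),
        CloneSpec(5, ["plasma", "plasma", "memory", "memory", "memory"], 8, 6,
                  ["IGHG3"] * 5, [0, 0, 1, 2, 3]),
        CloneSpec(4, ["plasma", "memory", "memory", "memory"], 10, 7,
                  ["IGHG1"] * 4, [0, 1, 2, 3]),
        CloneSpec(2, ["plasma", "memory"], 6, 4, ["IGHM", "IGHM"], [0, 0]),
        CloneSpec(2, ["plasma", "plasma"], 5, 3, ["IGHA1", "IGHA1"], [0, 1]),
    ]


@dataclass
class SynthConfig:
    """All knobs of the synthetic study, with defaults at study-like settings."""

    seed: int = 0
    n_cells_per_cluster: dict[str, int] = field(
        default_factory=lambda: {"naive": 150, "memory": 300, "plasma": 100})
    n_genes: int = 2000
    n_spike_genes: int = 50
    marker_programs: dict[str, tuple[tuple[str, ...], float]] = field(
        default_factory=lambda: _augment_programs(DEFAULT_MARKER_PROGRAMS))
    extra_celltypes: dict[str, tuple[tuple[str, ...], float]] = field(
        default_factory=lambda: _augment_programs(DEFAULT_EXTRA_CELLTYPES))
    capture_efficiency_sd: float = 0.25
    dropout_rate: float = 0.10
    n_empty_wells: int = 8
    bad_cell_fraction: float = 0.05
    plate_shape: tuple[int, int] = (16, 24)
    donors: tuple[str, ...] = ("A2", "A3", "A4")
    sections: list[SectionSpec] = field(default_factory=default_sections)
    cxcl12_factor: float = 10.0
    niche_region: str = "niche"
    batch_effect_sd: float = 0.1
    clone_spec: list[CloneSpec] = field(default_factory=_default_clone_spec)
    n_background_cells: int = 30
    germline_segments: dict[str, str] = field(default_factory=default_germline_segments)

    def validate(self) -> None:
        if any(v < 0 for v in self.n_cells_per_cluster.values()):
            raise ValueError("non-positive counts in config: n_cells_per_cluster")
        if self.n_genes <= 0 or self.n_spike_genes < 0 or self.n_empty_wells < 0:
            raise ValueError("non-positive counts in config")
        if not 0 <= self.dropout_rate <= 1:
            raise ValueError("dropout_rate must be a probability")
        if self.capture_efficiency_sd < 0:
            raise ValueError("capture_efficiency_sd must be positive")
        seen: dict[str, str] = {}
        for cl, (genes, fc) in self.marker_programs.items():
            if fc <= 0:
                raise ValueError(f"non-positive fold change for {cl}")
            for g in genes:
                if g in seen:
                    warnings.warn(
                        f"marker gene {g} shared by clusters {seen[g]} and {cl}")
                seen[g] = cl
        for sec in self.sections:
            for reg in sec.regions:
                total = sum(reg.weights.values())
                if abs(total - 1.0) > 1e-8:
                    raise ValueError(
                        f"mixture weights of region {reg.name} sum to {total}, not 1")
        for cs in self.clone_spec:
            if cs.size < 1:
                raise ValueError("clone sizes must be >= 1")
            if len(cs.compartments) != cs.size or len(cs.isotypes) != cs.size:
                raise ValueError("clone_spec member lists must match size")
            if cs.sequence_groups is not None and len(cs.sequence_groups) != cs.size:
                raise ValueError("sequence_groups must match clone size")


# ---------------------------------------------------------------------------
# shared gene model


class _GeneModel:
    """Gene namespace, baseline NB parameters and cell-type mean profiles.

    Shared by the single-cell and spatial generators so both speak the same
    gene vocabulary (required for integration).
    """

    def __init__(self, config: SynthConfig):
        named = []
        for genes, _fc in list(config.marker_programs.values()) + list(
                config.extra_celltypes.values()):
            named.extend(genes)
        named.extend(_NAMED_GENES)
        named = list(dict.fromkeys(named))  # stable unique
        if config.n_genes <= len(named):
            raise ValueError(
                f"n_genes={config.n_genes} must exceed the {len(named)} named marker genes")
        fillers = [f"G{i:05d}" for i in range(config.n_genes - len(named))]
        self.genes = named + fillers
        self.spikes = [f"ERCC-{i:05d}" for i in range(config.n_spike_genes)]

        rng = np.random.default_rng(derive_seed(config.seed, "genes"))
        n = config.n_genes
        # NB dispersion fixed per gene from a log-normal prior: gives the
        # technical trend a nontrivial shape for the variance decomposition
        self.base_mean = np.exp(rng.normal(0.3, 1.2, size=n))
        # lineage markers are well-expressed in their lineage: draw program
        # genes from a tighter, higher-mean prior so each program is
        # identifiable rather than occasionally landing near zero
        n_named = len(named)
        self.base_mean[:n_named] = np.exp(rng.normal(1.2, 0.5, size=n_named))
        self.dispersion = np.exp(rng.normal(np.log(2.0), 0.5, size=n))  # NB size r
        self.spike_abundance = np.exp(rng.normal(1.0, 1.4, size=config.n_spike_genes))
        self._index = {g: i for i, g in enumerate(self.genes)}
        self.config = config

    def cluster_profile(self, program: str) -> np.ndarray:
        """Mean expression profile of one cell type (endogenous genes)."""
        progs = {**self.config.marker_programs, **self.config.extra_celltypes}
        genes, fc = progs[program]
        mu = self.base_mean.copy()
        for g in genes:
            mu[self._index[g]] *= fc
        return mu

    def profiles(self, names=None) -> pd.DataFrame:
        """genes x cell-types matrix of mean profiles."""
        if names is None:
            names = list(self.config.marker_programs) + list(self.config.extra_celltypes)
        return pd.DataFrame(
            {t: self.cluster_profile(t) for t in names}, index=self.genes)


def gene_model(config: SynthConfig) -> _GeneModel:
    return _GeneModel(config)


def signature_gene_union(config: SynthConfig) -> list[str]:
    """All program genes of every cell type (B-cell and tissue programs)."""
    progs = {**config.marker_programs, **config.extra_celltypes}
    return list(dict.fromkeys(g for genes, _fc in progs.values() for g in genes))


# ---------------------------------------------------------------------------
# containers


@dataclass
class CellExpressionMatrix:
    """genes x cells raw counts with spike flags and per-cell metadata."""

    counts: np.ndarray  # genes x cells (spike rows appended at the end)
    gene_names: list[str]
    cell_ids: list[str]
    is_spike: np.ndarray  # bool per gene row
    obs: pd.DataFrame  # indexed by cell_id

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def endogenous(self) -> np.ndarray:
        return self.counts[~self.is_spike]


@dataclass
class SpatialSection:
    section_id: str
    donor_id: str
    serostatus: str
    counts: pd.DataFrame  # spots x genes, integer
    positions: pd.DataFrame  # index barcode: array_row, array_col, pixel_x, pixel_y


# ---------------------------------------------------------------------------
# single-cell counts + QC metrics


def generate_sc_counts(config: SynthConfig):
    """Simulate the index-sorted Smart-seq2 plates.

    Returns ``(CellExpressionMatrix, qc_metrics DataFrame)``. Endogenous
    counts are negative binomial with a per-cell log-normal capture
    efficiency; marker genes have their mean multiplied by the configured
    fold change in their own cluster; spike-in rows share fixed abundances
    scaled only by efficiency. Empty control wells (and a planted fraction
    of low-quality cells) receive ~1% background signal and degraded QC
    metrics, defining the target of the QC PC1 filter.
    """
    config.validate()
    model = _GeneModel(config)
    rng = np.random.default_rng(derive_seed(config.seed, "sc"))

    clusters = sorted(config.n_cells_per_cluster)
    labels: list[str] = []
    for cl in clusters:
        labels += [cl] * config.n_cells_per_cluster[cl]
    n_real = len(labels)
    n_total = n_real + config.n_empty_wells

    is_control = np.zeros(n_total, bool)
    is_control[n_real:] = True
    is_bad = np.zeros(n_total, bool)
    if n_real:
        n_bad = int(round(config.bad_cell_fraction * n_real))
        bad_idx = rng.choice(n_real, size=n_bad, replace=False)
        is_bad[bad_idx] = True

    efficiency = np.exp(rng.normal(0.0, config.capture_efficiency_sd, size=n_total))
    signal_scale = efficiency.copy()
    signal_scale[is_control] *= 0.01
    signal_scale[is_bad] *= 0.02 * np.exp(rng.normal(0.0, 0.3, size=int(is_bad.sum())))

    n_genes = config.n_genes
    cluster_mu = {cl: model.cluster_profile(cl) for cl in clusters}
    counts = np.zeros((n_genes + config.n_spike_genes, n_total), dtype=np.int64)
    r = model.dispersion
    for j in range(n_total):
        base = model.base_mean if is_control[j] else cluster_mu[labels[j]]
        mu = base * signal_scale[j]
        counts[:n_genes, j] = rng.negative_binomial(r, r / (r + mu))
        spike_mu = model.spike_abundance * efficiency[j] * (0.01 if is_control[j] else 1.0)
        counts[n_genes:, j] = rng.poisson(spike_mu)

    if config.dropout_rate > 0 and n_total:
        keep = rng.random((n_genes, n_total)) >= config.dropout_rate
        counts[:n_genes] *= keep

    rows, cols = config.plate_shape
    per_plate = rows * cols
    cell_ids, plate_ids, well_rows, well_cols = [], [], [], []
    for j in range(n_total):
        plate = j // per_plate
        w = j % per_plate
        r_, c_ = w // cols, w % cols
        plate_ids.append(f"P{plate + 1}")
        well_rows.append(r_)
        well_cols.append(c_)
        cell_ids.append(f"C{j:04d}")

    donors = rng.choice(list(config.donors), size=n_total) if n_total else []
    obs = pd.DataFrame(
        {
            "donor_id": donors,
            "plate_id": plate_ids,
            "well_row": well_rows,
            "well_col": well_cols,
            "is_control": is_control,
            "is_bad": is_bad,
            "true_cluster": [labels[j] if j < n_real else "" for j in range(n_total)],
            "true_efficiency": efficiency,
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )

    cem = CellExpressionMatrix(
        counts=counts,
        gene_names=model.genes + model.spikes,
        cell_ids=cell_ids,
        is_spike=np.r_[np.zeros(n_genes, bool), np.ones(config.n_spike_genes, bool)],
        obs=obs,
    )
    qc = _generate_qc_metrics(rng, obs, signal_scale, efficiency)
    return cem, qc


def _generate_qc_metrics(rng, obs, signal_scale, efficiency) -> pd.DataFrame:
    n = len(obs)
    degraded = obs["is_control"].to_numpy() | obs["is_bad"].to_numpy()
    # empty and failed wells: reads x~0.01, mapped gene count x~0.02; planted
    # low-quality cells draw from the same degradation distribution as the
    # empty controls — that resemblance is the QC filter's premise
    read_mult = np.where(
        degraded, 0.01 * np.exp(rng.normal(0.0, 0.25, n)), 1.0)
    n_raw = np.exp(rng.normal(np.log(2.5e6), 0.3, n)) * read_mult
    q30 = np.clip(rng.normal(0.93, 0.02, n) - 0.15 * degraded, 0, 1)
    n_failed = rng.poisson(0.5 + 5.0 * degraded)
    n_mapped = n_raw * rng.uniform(0.75, 0.9, n)
    mean_len = rng.normal(95, 3, n) * np.where(degraded, 0.7, 1.0)
    n_genes_det = np.clip(rng.normal(3500, 400, n), 200, None) * np.where(
        degraded, 2.0 * read_mult, 1.0)
    n_spike = np.exp(rng.normal(np.log(5e4), 0.3, n)) * np.where(degraded, 0.8, 1.0)
    return pd.DataFrame(
        {
            "n_raw_reads": np.round(n_raw).astype(np.int64),
            "q30_fraction": q30,
            "n_failed_fastqc": n_failed.astype(np.int64),
            "n_mapped_reads": np.round(n_mapped).astype(np.int64),
            "mean_mapped_length": mean_len,
            "n_mapped_genes": np.round(n_genes_det).astype(np.int64),
            "n_spike_reads": np.round(n_spike).astype(np.int64),
            "is_control_well": obs["is_control"].to_numpy(),
            "plate_id": obs["plate_id"].to_numpy(),
            "well_row": obs["well_row"].to_numpy(),
            "well_col": obs["well_col"].to_numpy(),
        },
        index=obs.index,
    )


# ---------------------------------------------------------------------------
# index-sort intensities

_SUBSET_MEANS = {
    # log10 intensity means per (subset, marker)
    "naive": {"IgD": 3.5, "CD27": 1.0, "CD19": 3.0, "CD138": 1.0},
    "memory": {"IgD": 1.5, "CD27": 2.5, "CD19": 3.0, "CD138": 1.0},
    "plasma": {"IgD": 1.3, "CD27": 4.0, "CD19": 2.3, "CD138": 3.5},
}
_INDEX_SD = 0.22


def generate_index_sort(labels: pd.Series, config: SynthConfig) -> pd.DataFrame:
    """Per-cell flow intensities for IgD/CD27/CD19/CD138 by planted subset.

    ``labels`` maps cell_id -> cluster name for all non-control cells.
    Intensities are log-normal with subset-specific means (naive IgD-high
    CD27-low, memory IgD-low CD27-mid, plasma CD27-very-high CD138-high).
    """
    rng = np.random.default_rng(derive_seed(config.seed, "index"))
    unknown = set(labels.unique()) - set(_SUBSET_MEANS) - set(config.marker_programs)
    if unknown:
        raise ValueError(f"unknown cluster labels: {sorted(unknown)}")
    markers = ["IgD", "CD27", "CD19", "CD138"]
    out = {}
    for m in markers:
        mu = np.array([_SUBSET_MEANS.get(l, _SUBSET_MEANS["memory"])[m] for l in labels])
        out[m] = 10.0 ** rng.normal(mu, _INDEX_SD)
    return pd.DataFrame(out, index=labels.index.copy())


# ---------------------------------------------------------------------------
# spatial sections


def generate_spatial(config: SynthConfig):
    """Simulate Visium-like sections from region-wise cell-type mixtures.

    Spot counts are Poisson draws around the mixture-weighted sum of
    cell-type mean profiles scaled to the section depth. The configured
    niche region has its CXCL12 mean elevated by ``cxcl12_factor``. Returns
    ``(sections, truth)`` where truth holds the per-spot region name and
    true mixture weights.
    """
    config.validate()
    model = _GeneModel(config)
    rng = np.random.default_rng(derive_seed(config.seed, "spatial"))
    cxcl12_idx = model._index["CXCL12"]

    all_types: list[str] = []
    for sec in config.sections:
        for reg in sec.regions:
            for t in reg.weights:
                if t not in all_types:
                    all_types.append(t)
    profiles = {t: model.cluster_profile(t) for t in all_types}
    norm_profiles = {t: p / p.sum() for t, p in profiles.items()}

    sections, truths = [], []
    for sec in config.sections:
        cover = np.full((sec.n_rows, sec.n_cols), -1, dtype=int)
        for ri, reg in enumerate(sec.regions):
            cover[reg.row0:reg.row1, reg.col0:reg.col1] = ri
        if (cover < 0).any():
            raise ValueError(
                f"region layout of section {sec.section_id} does not cover the grid")

        batch = np.exp(rng.normal(0.0, config.batch_effect_sd, size=config.n_genes)) \
            if config.batch_effect_sd > 0 else np.ones(config.n_genes)

        n_spots = sec.n_rows * sec.n_cols
        lam = np.zeros((n_spots, config.n_genes))
        rows = np.repeat(np.arange(sec.n_rows), sec.n_cols)
        cols = np.tile(np.arange(sec.n_cols), sec.n_rows)
        # spot-to-spot depth varies with local tissue density
        spot_depth = sec.depth * np.exp(rng.normal(0.0, sec.depth_sd, n_spots))
        region_names, weights_rows = [], []
        for s in range(n_spots):
            reg = sec.regions[cover[rows[s], cols[s]]]
            mix = np.zeros(config.n_genes)
            for t, w in reg.weights.items():
                mix += w * norm_profiles[t]
            lam_s = spot_depth[s] * mix * batch
            if reg.name == config.niche_region:
                lam_s[cxcl12_idx] *= config.cxcl12_factor
            lam[s] = lam_s
            region_names.append(reg.name)
            weights_rows.append({t: reg.weights.get(t, 0.0) for t in all_types})

        counts = rng.poisson(lam)
        barcodes = [f"{sec.section_id}_spot{s:04d}" for s in range(n_spots)]
        counts_df = pd.DataFrame(counts, index=barcodes, columns=model.genes)
        positions = pd.DataFrame(
            {
                "array_row": rows,
                "array_col": cols,
                "pixel_x": cols * 100,
                "pixel_y": rows * 100,
            },
            index=pd.Index(barcodes, name="barcode"),
        )
        sections.append(SpatialSection(sec.section_id, sec.donor_id,
                                       sec.serostatus, counts_df, positions))
        truth = pd.DataFrame(weights_rows, index=barcodes)
        truth.insert(0, "region", region_names)
        truth.insert(0, "section_id", sec.section_id)
        truths.append(truth)

    return sections, pd.concat(truths)


# ---------------------------------------------------------------------------
# paired BCR repertoire


def _translate(nt: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(nt[: len(nt) - len(nt) % 3]).translate())


def _mutate(seq: str, positions: np.ndarray, rng) -> str:
    s = list(seq)
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != s[pos]]
        s[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(s)


def generate_bcr(config: SynthConfig):
    """Simulate an AIRR-style paired heavy/light chain table.

    Each planted clone family shares heavy and light V/J calls; member
    sequences are the germline V+J concatenation with exactly the configured
    number of point mutations placed in the V segment (identical within a
    sequence group). Singleton background cells with unique V/J combinations
    are appended. Returns ``(chains DataFrame, truth DataFrame)`` where the
    truth maps cell_id -> clone family / compartment / mutation counts.
    """
    config.validate()
    rng = np.random.default_rng(derive_seed(config.seed, "bcr"))
    segs = config.germline_segments
    vh = sorted(k for k in segs if k.startswith("IGHV"))
    jh = sorted(k for k in segs if k.startswith("IGHJ"))
    vl = sorted(k for k in segs if k.startswith(("IGKV", "IGLV")))
    jl = sorted(k for k in segs if k.startswith(("IGKJ", "IGLJ")))
    for cs in config.clone_spec:
        for call in (cs.v_heavy, cs.j_heavy, cs.v_light, cs.j_light):
            if call is not None and call not in segs:
                raise ValueError(f"clone_spec names unknown germline segment {call}")
        for iso in cs.isotypes:
            if iso not in ISOTYPE_ORDER:
                raise ValueError(f"unknown isotype {iso}")

    combos = [(a, b, c, d) for a in vh for b in jh for c in vl for d in jl]
    used = set()
    rows_h, rows_l, truth_rows = [], [], []
    prow, pcol = config.plate_shape
    n_wells = prow * pcol

    def well_for(i):
        w = int(rng.integers(n_wells))
        return "P1", w // pcol, w % pcol

    cell_no = 0
    for fam_i, cs in enumerate(config.clone_spec):
        if cs.v_heavy is None:
            key = next(c for c in combos if c not in used)
        else:
            key = (cs.v_heavy, cs.j_heavy, cs.v_light, cs.j_light)
        used.add(key)
        v_h, j_h, v_l, j_l = key
        groups = cs.sequence_groups or [0] * cs.size
        group_seqs: dict[int, tuple] = {}
        for g in sorted(set(groups)):
            hp = rng.choice(len(segs[v_h]), size=cs.n_shm_heavy, replace=False)
            lp = rng.choice(len(segs[v_l]), size=cs.n_shm_light, replace=False)
            h_seq = _mutate(segs[v_h], hp, rng) + segs[j_h]
            l_seq = _mutate(segs[v_l], lp, rng) + segs[j_l]
            group_seqs[g] = (h_seq, l_seq, sorted(hp.tolist()), sorted(lp.tolist()))
        for m in range(cs.size):
            cid = f"BCR{cell_no:04d}"
            cell_no += 1
            h_seq, l_seq, hp, lp = group_seqs[groups[m]]
            plate, wr, wc = well_for(cell_no)
            junction_h = segs[v_h][-9:] + segs[j_h][:6]
            junction_l = segs[v_l][-9:] + segs[j_l][:6]
            expr_h = float(np.round(np.exp(rng.normal(5.0, 0.5)), 2))
            common = dict(cell_id=cid, donor_id="A2", plate_id=plate,
                          well_row=wr, well_col=wc)
            rows_h.append({**common, "locus": "IGH", "v_call": v_h, "d_call": "",
                           "j_call": j_h, "c_call": cs.isotypes[m],
                           "junction": junction_h, "junction_aa": _translate(junction_h),
                           "sequence": h_seq,
                           "germline_alignment": segs[v_h] + segs[j_h],
                           "v_germline_end": len(segs[v_h]),
                           "productive": True, "complete_vdj": True,
                           "consensus_count": expr_h})
            rows_l.append({**common, "locus": "IGK" if v_l.startswith("IGK") else "IGL",
                           "v_call": v_l, "d_call": "", "j_call": j_l,
                           "c_call": "IGKC" if v_l.startswith("IGK") else "IGLC1",
                           "junction": junction_l, "junction_aa": _translate(junction_l),
                           "sequence": l_seq,
                           "germline_alignment": segs[v_l] + segs[j_l],
                           "v_germline_end": len(segs[v_l]),
                           "productive": True, "complete_vdj": True,
                           "consensus_count": float(np.round(np.exp(rng.normal(5.0, 0.5)), 2))})
            truth_rows.append({"cell_id": cid, "clone_family": f"F{fam_i}",
                               "compartment": cs.compartments[m],
                               "sequence_group": groups[m],
                               "n_shm_heavy": len(hp), "n_shm_light": len(lp),
                               "shm_positions_heavy": ";".join(map(str, hp)),
                               "shm_positions_light": ";".join(map(str, lp))})

    free = [c for c in combos if c not in used]
    if config.n_background_cells > len(free):
        raise ValueError("not enough distinct V/J combinations for background cells")
    for b in range(config.n_background_cells):
        v_h, j_h, v_l, j_l = free[b]
        cid = f"BCR{cell_no:04d}"
        cell_no += 1
        hp = rng.choice(len(segs[v_h]), size=int(rng.integers(2, 15)), replace=False)
        lp = rng.choice(len(segs[v_l]), size=int(rng.integers(1, 10)), replace=False)
        h_seq = _mutate(segs[v_h], hp, rng) + segs[j_h]
        l_seq = _mutate(segs[v_l], lp, rng) + segs[j_l]
        plate, wr, wc = well_for(cell_no)
        compartment = ["memory", "plasma"][int(rng.integers(2))]
        iso = ISOTYPE_ORDER[int(rng.integers(len(ISOTYPE_ORDER)))]
        junction_h = segs[v_h][-9:] + segs[j_h][:6]
        junction_l = segs[v_l][-9:] + segs[j_l][:6]
        common = dict(cell_id=cid, donor_id="A2", plate_id=plate,
                      well_row=wr, well_col=wc)
        rows_h.append({**common, "locus": "IGH", "v_call": v_h, "d_call": "",
                       "j_call": j_h, "c_call": iso, "junction": junction_h,
                       "junction_aa": _translate(junction_h), "sequence": h_seq,
                       "germline_alignment": segs[v_h] + segs[j_h],
                       "v_germline_end": len(segs[v_h]),
                       "productive": True, "complete_vdj": True,
                       "consensus_count": float(np.round(np.exp(rng.normal(5.0, 0.5)), 2))})
        rows_l.append({**common, "locus": "IGK" if v_l.startswith("IGK") else "IGL",
                       "v_call": v_l, "d_call": "", "j_call": j_l,
                       "c_call": "IGKC" if v_l.startswith("IGK") else "IGLC1",
                       "junction": junction_l, "junction_aa": _translate(junction_l),
                       "sequence": l_seq,
                       "germline_alignment": segs[v_l] + segs[j_l],
                       "v_germline_end": len(segs[v_l]),
                       "productive": True, "complete_vdj": True,
                       "consensus_count": float(np.round(np.exp(rng.normal(5.0, 0.5)), 2))})
        truth_rows.append({"cell_id": cid, "clone_family": f"S{b}",
                           "compartment": compartment, "sequence_group": 0,
                           "n_shm_heavy": len(hp), "n_shm_light": len(lp),
                           "shm_positions_heavy": ";".join(map(str, sorted(hp.tolist()))),
                           "shm_positions_light": ";".join(map(str, sorted(lp.tolist())))})

    chains = pd.DataFrame(rows_h + rows_l)
    truth = pd.DataFrame(truth_rows).set_index("cell_id")
    return chains, truth


# ---------------------------------------------------------------------------
# writers (plain-text, byte-stable)


def write_sc_counts(cem: CellExpressionMatrix, outdir) -> None:
    from pathlib import Path

    from scipy.io import mmwrite
    from scipy.sparse import csc_matrix

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    mmwrite(out / "matrix.mtx", csc_matrix(cem.counts))
    pd.DataFrame({"gene": cem.gene_names, "is_spike": cem.is_spike.astype(int)}).to_csv(
        out / "genes.tsv", sep="\t", index=False)
    pd.Series(cem.cell_ids, name="barcode").to_csv(out / "barcodes.tsv",
                                                   sep="\t", index=False)
    cem.obs.to_csv(out / "obs.csv")


def read_sc_counts(indir) -> CellExpressionMatrix:
    from pathlib import Path

    from scipy.io import mmread

    ind = Path(indir)
    counts = np.asarray(mmread(ind / "matrix.mtx").todense())
    genes = pd.read_csv(ind / "genes.tsv", sep="\t")
    barcodes = pd.read_csv(ind / "barcodes.tsv", sep="\t")["barcode"].tolist()
    obs = pd.read_csv(ind / "obs.csv", index_col=0)
    return CellExpressionMatrix(
        counts=counts.astype(np.int64),
        gene_names=genes["gene"].tolist(),
        cell_ids=barcodes,
        is_spike=genes["is_spike"].to_numpy(bool),
        obs=obs,
    )


def write_spatial(sections: list[SpatialSection], outdir) -> None:
    from pathlib import Path

    from scipy.io import mmwrite
    from scipy.sparse import csc_matrix

    out = Path(outdir)
    for sec in sections:
        d = out / sec.section_id
        d.mkdir(parents=True, exist_ok=True)
        mmwrite(d / "matrix.mtx", csc_matrix(sec.counts.to_numpy().T))  # genes x spots
        pd.Series(sec.counts.columns, name="gene").to_csv(d / "genes.tsv",
                                                          sep="\t", index=False)
        pd.Series(sec.counts.index, name="barcode").to_csv(d / "barcodes.tsv",
                                                           sep="\t", index=False)
        sec.positions.to_csv(d / "positions.csv")
        pd.Series({"section_id": sec.section_id, "donor_id": sec.donor_id,
                   "serostatus": sec.serostatus}).to_csv(d / "meta.csv", header=False)


def read_spatial(indir) -> list[SpatialSection]:
    from pathlib import Path

    from scipy.io import mmread

    sections = []
    for d in sorted(p for p in Path(indir).iterdir() if p.is_dir()):
        counts = np.asarray(mmread(d / "matrix.mtx").todense()).T
        genes = pd.read_csv(d / "genes.tsv", sep="\t")["gene"].tolist()
        barcodes = pd.read_csv(d / "barcodes.tsv", sep="\t")["barcode"].tolist()
        positions = pd.read_csv(d / "positions.csv", index_col=0)
        meta = pd.read_csv(d / "meta.csv", header=None, index_col=0)[1]
        sections.append(SpatialSection(
            meta["section_id"], meta["donor_id"], meta["serostatus"],
            pd.DataFrame(counts.astype(np.int64), index=barcodes, columns=genes),
            positions))
    return sections


def write_airr(chains: pd.DataFrame, path) -> None:
    chains.to_csv(path, sep="\t", index=False)


def read_airr(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"d_call": str}, keep_default_na=False,
                       na_values=[])
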
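"""Seeded synthetic MERFISH-like tissue generator with ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, at panel scale (~100-400 genes):

* amyloid plaques as 4-point perimeter quadrilaterals scattered in a
  rectangular tissue region;
* microglia with uniform centroids, lognormal volumes and one of three
  transcriptional states — homeostatic, DAM, or lymphoid-DAM (a DAM cell
  additionally expressing the lymphoid program);
* proximity-dependent state composition: within a cutoff of a plaque edge
  the odds of the DAM and lymphoid-DAM states are multiplied by a
  configurable enrichment factor (a logistic-odds modelling choice);
* negative-binomial (gamma-Poisson) counts with a shared dispersion, where
  genes of a cell's active program(s) have their mean multiplied by
  ``2**effect_log2fc``;
* trimodal lognormal nuclear PU.1 intensities, the component determined by
  the cell state (lymphoid-DAM -> low, homeostatic -> medium, DAM -> high);
* explicitly injected QC-failing cells with known ids, so filter tests have
  exact expected survivor counts.

A single seed drives one RNG stream, split hierarchically per stage, so an
identical config + seed reproduces the dataset byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as scipy_io
from scipy import sparse

from .containers import RAW, ExpressionMatrix, InputError
from .spatial import DEFAULT_CUTOFF_UM, Plaque, RegionPolygon, compute_proximity

STATES = ("homeostatic", "DAM", "lymphoid_DAM")
PROGRAMS = ("homeostatic", "DAM", "lymphoid")
#: Programs whose genes are elevated in each cell state.
ACTIVE_PROGRAMS = {
    "homeostatic": ("homeostatic",),
    "DAM": ("DAM",),
    "lymphoid_DAM": ("DAM", "lymphoid"),
}
#: Intensity mixture component index per state (0=low, 1=medium, 2=high PU.1).
#: Plaque-associated (DAM) microglia split into PU.1-high and PU.1-low
#: (lymphoid) subsets, while the homeostatic bulk sits at medium PU.1.
STATE_COMPONENT = {"lymphoid_DAM": 0, "homeostatic": 1, "DAM": 2}

_PROGRAM_GENE_NAMES = {
    "homeostatic": ("Cx3cr1", "Tmem119", "P2ry12", "Csf1r", "Hexb", "Sall1", "Selplg", "Siglech", "Olfml3", "Gpr34"),
    "DAM": ("Cst7", "Apoe", "Lpl", "Itgax", "Clec7a", "Igf1", "Spp1", "Axl", "Cd9", "Trem2"),
    "lymphoid": ("Cd28", "Cd274", "Pdcd1", "Ctla2a", "Cd5", "Sox5", "Cd48", "Cd52", "Cd72"),
}

# Measured panel genes outside the three programs (baseline expression only):
# the type-I interferon-stimulated genes scored downstream.
_BACKGROUND_GENE_NAMES = (
    "Ifitm3", "Ifit3", "Isg15", "Ifit2", "Ifi27l2a", "Ifi204", "Irf7", "Usp18",
    "Stat2", "Ifitm2", "Rsad2", "Ifit1", "Bst2", "Isg20", "Xaf1",
)

# Default trimodal PU.1 mixture (log-scale mu, sigma, weight).  Component
# means sit a factor 1.25**2 apart so that cutoffs derived from the pooled
# mean with fold change 1.25 fall at the geometric midpoints between
# components (each cutoff a 1.25 ratio from the medium component mean).
_MU_MED = float(np.log(1000.0))
_SPACING = float(2.0 * np.log(1.25))
DEFAULT_INTENSITY_MIXTURE = (
    (_MU_MED - _SPACING, 0.08, 0.10),
    (_MU_MED, 0.08, 0.65),
    (_MU_MED + _SPACING, 0.08, 0.25),
)


class ConfigurationError(InputError):
    """Invalid simulation configuration."""


@dataclass
class SimulationConfig:
    """Parameters of one synthetic MERFISH-like experiment.

    The defaults define the study conditions every downstream stage is
    exercised under; see the methods note for the rationale of each value.
    """

    seed: int = 0
    n_cells: int = 6000
    n_genes: int = 398
    n_plaques: int = 40
    region: tuple[float, float, float, float] = (0.0, 0.0, 1000.0, 1000.0)  # xmin, ymin, xmax, ymax (um)
    plaque_radius_range: tuple[float, float] = (10.0, 20.0)
    frac_states: tuple[float, float, float] = (0.65, 0.25, 0.10)  # homeostatic, DAM, lymphoid-DAM
    proximity_enrichment: float = 10.0
    proximity_cutoff_um: float = DEFAULT_CUTOFF_UM
    nb_mean_baseline: float = 1.0
    gene_baseline_sigma: float = 1.0  # log-scale spread of background-gene baseline means
    nb_dispersion: float = 2.0
    effect_log2fc: tuple[float, float, float] = (2.0, 2.0, 2.0)  # per program, order PROGRAMS
    volume_lognormal: tuple[float, float] = (float(np.log(300.0)), 0.35)  # (mu, sigma) of ln volume
    intensity_mixture: tuple = DEFAULT_INTENSITY_MIXTURE  # three (mu, sigma, weight)
    n_samples: int = 2
    sample_depth: tuple[float, ...] = (1.0, 1.3)  # per-sample capture-efficiency multipliers
    dropout_cells: dict = field(
        default_factory=lambda: {"low_transcripts": 5, "low_volume": 5, "low_genes": 5}
    )

    def __post_init__(self) -> None:
        if self.n_cells < 0 or self.n_genes < 1 or self.n_plaques < 0:
            raise ConfigurationError("n_cells/n_plaques must be >= 0 and n_genes >= 1")
        xmin, ymin, xmax, ymax = self.region
        if not (xmax > xmin and ymax > ymin):
            raise ConfigurationError(f"degenerate region extents {self.region}")
        fr = np.asarray(self.frac_states, dtype=float)
        if fr.shape != (3,) or (fr < 0).any() or (fr > 1).any() or not np.isclose(fr.sum(), 1.0):
            raise ConfigurationError(f"frac_states must be 3 proportions summing to 1, got {self.frac_states}")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be positive")
        if self.proximity_enrichment < 1:
            raise ConfigurationError("proximity_enrichment must be >= 1")
        n_named = sum(len(v) for v in _PROGRAM_GENE_NAMES.values()) + len(_BACKGROUND_GENE_NAMES)
        if self.n_genes < n_named:
            raise ConfigurationError(
                f"n_genes must cover the {n_named} named panel genes (programs + background)"
            )
        mix = np.asarray(self.intensity_mixture, dtype=float)
        if mix.shape != (3, 3) or (mix[:, 1] <= 0).any():
            raise ConfigurationError("intensity_mixture needs three (mu, sigma>0, weight) components")
        if not np.isclose(mix[:, 2].sum(), 1.0):
            raise ConfigurationError("intensity mixture weights must sum to 1")
        if len(self.sample_depth) < self.n_samples:
            raise ConfigurationError("sample_depth must provide one factor per sample")
        lo, hi = self.plaque_radius_range
        if not (0 < lo <= hi):
            raise ConfigurationError(f"invalid plaque_radius_range {self.plaque_radius_range}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dropout_cells"] = dict(sorted(d["dropout_cells"].items()))
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()

    @property
    def gene_names(self) -> list[str]:
        names = [g for p in PROGRAMS for g in _PROGRAM_GENE_NAMES[p]]
        names += list(_BACKGROUND_GENE_NAMES)
        names += [f"Panel{i:04d}" for i in range(1, self.n_genes - len(names) + 1)]
        return names

    @property
    def program_genes(self) -> dict[str, tuple[str, ...]]:
        return {p: tuple(_PROGRAM_GENE_NAMES[p]) for p in PROGRAMS}


@dataclass
class GroundTruth:
    """Generative truth for recovery tests (synthetic data only)."""

    cell_state: pd.Series  # cell id -> state label
    program_genes: dict  # program -> tuple of gene ids (disjoint)
    true_log2fc: pd.DataFrame  # genes x programs effect sizes
    true_proximity_label: pd.Series  # cell id -> plaque_associated / distal
    intensity_component: pd.Series | None = None  # cell id -> 0/1/2
    qc_fail_reason: pd.Series | None = None  # cell id -> "" or injected failure mode
    gene_baseline: pd.Series | None = None  # gene -> NB baseline mean (counts/cell)

    def __post_init__(self) -> None:
        all_genes = [g for gs in self.program_genes.values() for g in gs]
        if len(all_genes) != len(set(all_genes)):
            raise ConfigurationError("program gene sets must be disjoint")
        if not self.cell_state.isin(STATES).all():
            raise ConfigurationError("unknown cell state label in ground truth")

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "cell_id": self.cell_state.index,
                "cell_state": self.cell_state.to_numpy(),
                "true_proximity_label": self.true_proximity_label.reindex(self.cell_state.index).to_numpy(),
            }
        )
        if self.intensity_component is not None:
            df["intensity_component"] = self.intensity_component.reindex(self.cell_state.index).to_numpy()
        if self.qc_fail_reason is not None:
            df["qc_fail_reason"] = self.qc_fail_reason.reindex(self.cell_state.index).fillna("").to_numpy()
        return df


@dataclass
class SyntheticDataset:
    """One simulated experiment plus its generative truth."""

    cells: pd.DataFrame
    counts: ExpressionMatrix
    plaques: list
    region_polygon: RegionPolygon
    intensities: pd.DataFrame
    truth: GroundTruth
    config: SimulationConfig

    def __post_init__(self) -> None:
        if self.counts.n_cells != len(self.cells):
            raise ConfigurationError("counts row count must equal cell count")
        xmin, ymin, xmax, ymax = self.config.region
        x = self.cells["x_um"].to_numpy()
        y = self.cells["y_um"].to_numpy()
        if ((x < xmin) | (x > xmax) | (y < ymin) | (y > ymax)).any():
            raise ConfigurationError("cell centroid outside region extents")


# ---------------------------------------------------------------------------
# stage RNGs
# ---------------------------------------------------------------------------

_STAGES = ("plaques", "cells", "states", "gene_baselines", "counts", "intensities")


def _stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {name: np.random.default_rng(child) for name, child in zip(_STAGES, children)}


# ---------------------------------------------------------------------------
# generation stages
# ---------------------------------------------------------------------------

def generate_plaques(config: SimulationConfig, rng: np.random.Generator) -> list[Plaque]:
    """Scatter ``n_plaques`` 4-point perimeter quadrilaterals inside the region.

    Each plaque takes 4 perimeter points at jittered angles around 0/90/180/
    270 degrees from a centre, at radii drawn from ``plaque_radius_range``;
    counter-clockwise ordering guarantees a simple outline, and centres are
    inset by the maximal radius so every vertex stays inside the region.
    """
    xmin, ymin, xmax, ymax = config.region
    r_lo, r_hi = config.plaque_radius_range
    if xmax - xmin <= 2 * r_hi or ymax - ymin <= 2 * r_hi:
        raise ConfigurationError("region too small for the requested plaque radii")
    plaques = []
    base_angles = np.deg2rad([0.0, 90.0, 180.0, 270.0])
    for pid in range(1, config.n_plaques + 1):
        cx = rng.uniform(xmin + r_hi, xmax - r_hi)
        cy = rng.uniform(ymin + r_hi, ymax - r_hi)
        angles = base_angles + rng.uniform(-np.deg2rad(30.0), np.deg2rad(30.0), size=4)
        radii = rng.uniform(r_lo, r_hi, size=4)
        pts = np.column_stack([cx + radii * np.cos(angles), cy + radii * np.sin(angles)])
        plaques.append(Plaque.from_points(pid, pts))
    return plaques


def generate_cells(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Cell table: uniform centroids, lognormal volumes, round-robin samples.

    Regular cells get volumes clipped to stay above the QC threshold (the
    lognormal tail below 100 um^3 is < 0.1% at the defaults), so that only
    the explicitly injected ``low_volume`` cells fail the volume filter.
    """
    xmin, ymin, xmax, ymax = config.region
    n = config.n_cells
    mu, sigma = config.volume_lognormal
    ids = [f"cell_{i:05d}" for i in range(n)]
    volumes = np.maximum(rng.lognormal(mu, sigma, size=n), 105.0)
    cells = pd.DataFrame(
        {
            "cell_id": ids,
            "x_um": rng.uniform(xmin, xmax, size=n),
            "y_um": rng.uniform(ymin, ymax, size=n),
            "volume_um3": volumes,
            "sample_id": [f"sample_{1 + i % config.n_samples}" for i in range(n)],
        }
    )

    # explicitly injected QC failures with known ids
    fail_rows = []
    spec = config.dropout_cells or {}
    for mode in ("low_transcripts", "low_volume", "low_genes"):
        for j in range(int(spec.get(mode, 0))):
            vol = rng.uniform(20.0, 99.5) if mode == "low_volume" else max(rng.lognormal(mu, sigma), 105.0)
            fail_rows.append(
                {
                    "cell_id": f"fail_{mode}_{j:02d}",
                    "x_um": rng.uniform(xmin, xmax),
                    "y_um": rng.uniform(ymin, ymax),
                    "volume_um3": vol,
                    "sample_id": f"sample_{1 + j % config.n_samples}",
                }
            )
    if fail_rows:
        cells = pd.concat([cells, pd.DataFrame(fail_rows)], ignore_index=True)
    return cells


def assign_states(
    cells: pd.DataFrame,
    plaques: list,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> GroundTruth:
    """Draw per-cell states with plaque-proximity-enriched DAM odds.

    Cells within ``proximity_cutoff_um`` of a plaque edge draw their state
    with the DAM and lymphoid-DAM odds multiplied by
    ``proximity_enrichment``; the same cutoff defines the generative
    proximity label recorded in the truth.
    """
    ids = pd.Index(cells["cell_id"])
    if plaques:
        prox = compute_proximity(cells, plaques, region=None, cutoff=config.proximity_cutoff_um)
        near = prox["label"].to_numpy() == "plaque_associated"
        labels = pd.Series(prox["label"].to_numpy(dtype=object), index=ids)
    else:
        near = np.zeros(len(cells), dtype=bool)
        labels = pd.Series("distal", index=ids)

    base = np.asarray(config.frac_states, dtype=float)
    enriched = base * np.array([1.0, config.proximity_enrichment, config.proximity_enrichment])
    if enriched.sum() <= 0:
        raise ConfigurationError("state odds degenerate to zero")
    enriched = enriched / enriched.sum()
    probs = np.where(near[:, None], enriched[None, :], base[None, :])
    u = rng.random(len(cells))
    state_idx = (u[:, None] >= probs.cumsum(axis=1)).sum(axis=1)
    states = pd.Series(np.asarray(STATES, dtype=object)[state_idx], index=ids)

    genes = config.gene_names
    effects = pd.DataFrame(0.0, index=pd.Index(genes, name="gene"), columns=list(PROGRAMS))
    for p, eff in zip(PROGRAMS, config.effect_log2fc):
        effects.loc[list(config.program_genes[p]), p] = float(eff)

    return GroundTruth(
        cell_state=states,
        program_genes=config.program_genes,
        true_log2fc=effects,
        true_proximity_label=labels,
        qc_fail_reason=pd.Series("", index=ids, dtype=object),
    )


def generate_gene_baselines(config: SimulationConfig, rng: np.random.Generator) -> pd.Series:
    """Per-gene NB baseline means.

    Program genes sit at ``nb_mean_baseline`` (comparable moderate marker
    expression, keeping program totals balanced between states); background
    panel genes draw heterogeneous baselines from a mean-one lognormal with
    log-scale spread ``gene_baseline_sigma``, emulating the orders-of-
    magnitude expression range of a real panel.
    """
    genes = config.gene_names
    program = {g for gs in config.program_genes.values() for g in gs}
    sigma = config.gene_baseline_sigma
    base = np.full(len(genes), config.nb_mean_baseline)
    bg = np.array([g not in program for g in genes])
    if sigma > 0 and bg.any():
        # exp(N(-sigma^2/2, sigma)) has mean 1, preserving the baseline scale
        base[bg] *= rng.lognormal(-sigma**2 / 2.0, sigma, size=int(bg.sum()))
    return pd.Series(base, index=pd.Index(genes, name="gene"))


def generate_counts(
    truth: GroundTruth,
    cells: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> ExpressionMatrix:
    """Gamma-Poisson counts with program-elevated means.

    counts[c, g] ~ NB(mean = baseline * depth(sample(c)) *
    2**(effect_p if g in an active program p of state(c)), dispersion).
    Cells flagged as injected ``low_transcripts`` / ``low_genes`` failures get
    their rows replaced by constructions that violate exactly one QC rule.
    """
    if config.nb_dispersion <= 0:
        raise ConfigurationError("nb_dispersion must be positive")
    genes = config.gene_names
    n_cells, n_genes = len(cells), len(genes)
    ids = pd.Index(cells["cell_id"])

    mult = {}
    for state in STATES:
        m = np.ones(n_genes)
        for p in ACTIVE_PROGRAMS[state]:
            eff = truth.true_log2fc[p].reindex(genes).to_numpy()
            m = m * np.power(2.0, eff)
        mult[state] = m
    state_mult = np.stack([mult[s] for s in truth.cell_state.reindex(ids)])

    depth_map = {f"sample_{i+1}": config.sample_depth[i] for i in range(config.n_samples)}
    depth = cells["sample_id"].map(depth_map).to_numpy(dtype=float)
    if truth.gene_baseline is not None:
        base = truth.gene_baseline.reindex(genes).to_numpy(dtype=float)
    else:
        base = np.full(n_genes, config.nb_mean_baseline)
    mean = base[None, :] * depth[:, None] * state_mult
    if (mean <= 0).any():
        raise ConfigurationError("non-positive NB means")

    r = config.nb_dispersion
    lam = rng.gamma(shape=r, scale=mean / r)
    counts = rng.poisson(lam).astype(np.int64)

    # injected failures: overwrite with rows violating exactly one rule
    fail = truth.qc_fail_reason.reindex(ids).fillna("").to_numpy() if truth.qc_fail_reason is not None else None
    for i, cid in enumerate(ids):
        if not cid.startswith("fail_"):
            continue
        mode = "_".join(cid.split("_")[1:3])
        if mode == "low_transcripts":
            total = int(rng.integers(5, 40))  # < 40 transcripts
            counts[i] = rng.multinomial(total, np.full(n_genes, 1.0 / n_genes))
        elif mode == "low_genes":
            chosen = rng.choice(n_genes, size=5, replace=False)  # <= 5 unique genes
            row = np.zeros(n_genes, dtype=np.int64)
            row[chosen] = rng.multinomial(int(rng.integers(60, 120)), np.full(5, 0.2))
            counts[i] = row
        if truth.qc_fail_reason is not None:
            truth.qc_fail_reason.loc[cid] = mode

    return ExpressionMatrix(pd.DataFrame(counts, index=ids, columns=genes), RAW)


def generate_intensities(
    truth: GroundTruth,
    cells: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Trimodal lognormal nuclear PU.1 intensities, component set by state.

    Each nucleus draws from the mixture component its truth state maps to
    (lymphoid-DAM -> low, homeostatic -> medium, DAM -> high); the component
    index is recorded in the truth for recovery tests.
    """
    mix = np.asarray(config.intensity_mixture, dtype=float)
    ids = pd.Index(cells["cell_id"])
    comp = truth.cell_state.reindex(ids).map(STATE_COMPONENT).to_numpy(dtype=int)
    mu = mix[comp, 0]
    sigma = mix[comp, 1]
    vals = rng.lognormal(mu, sigma)
    truth.intensity_component = pd.Series(comp, index=ids)
    return pd.DataFrame(
        {
            "nucleus_id": ids,
            "mean_intensity": vals,
            "sample_id": cells["sample_id"].to_numpy(),
        }
    )


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Run every generation stage under one hierarchically split seed."""
    rngs = _stage_rngs(config.seed)
    plaques = generate_plaques(config, rngs["plaques"])
    cells = generate_cells(config, rngs["cells"])
    truth = assign_states(cells, plaques, config, rngs["states"])
    truth.gene_baseline = generate_gene_baselines(config, rngs["gene_baselines"])
    counts = generate_counts(truth, cells, config, rngs["counts"])
    intensities = generate_intensities(truth, cells, config, rngs["intensities"])
    xmin, ymin, xmax, ymax = config.region
    region = RegionPolygon("cortex", np.array([[xmin, ymin], [xmax, ymin], [xmax, ymax], [xmin, ymax]]))
    return SyntheticDataset(cells, counts, plaques, region, intensities, truth, config)


# ---------------------------------------------------------------------------
# on-disk format (MTX + CSV + GeoJSON + JSON manifest)
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_dataset(ds: SyntheticDataset, directory) -> dict:
    """Write a dataset to ``directory``; returns the manifest dict.

    Counts go out both as MatrixMarket (counts.mtx + features.tsv +
    barcodes.tsv) and as a dense CSV; metadata, plaques, intensities and
    truth as CSV; the region as GeoJSON.  A round-trip through
    :func:`read_dataset` reproduces the dataset exactly.
    """
    from .spatial import plaques_to_frame

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    mat = sparse.csr_matrix(ds.counts.values.to_numpy(dtype=np.int64))
    scipy_io.mmwrite(directory / "counts.mtx", mat, field="integer")
    (directory / "features.tsv").write_text("".join(f"{g}\n" for g in ds.counts.genes))
    (directory / "barcodes.tsv").write_text("".join(f"{c}\n" for c in ds.counts.cell_ids))
    ds.counts.values.to_csv(directory / "counts.csv", index_label="cell_id")
    ds.cells.to_csv(directory / "cells.csv", index=False)
    plaques_to_frame(ds.plaques).to_csv(directory / "plaques.csv", index=False)
    with open(directory / "region.geojson", "w") as fh:
        json.dump(ds.region_polygon.to_geojson(), fh, sort_keys=True)
    ds.intensities.to_csv(directory / "intensities.csv", index=False)
    ds.truth.frame().to_csv(directory / "truth_cells.csv", index=False)
    effects = ds.truth.true_log2fc.copy()
    if ds.truth.gene_baseline is not None:
        effects["baseline_mean"] = ds.truth.gene_baseline.reindex(effects.index)
    effects.to_csv(directory / "truth_effects.csv")
    with open(directory / "programs.json", "w") as fh:
        json.dump({p: list(g) for p, g in ds.truth.program_genes.items()}, fh, sort_keys=True)

    files = sorted(
        p.name
        for p in directory.iterdir()
        if p.name != "manifest.json" and p.is_file()
    )
    manifest = {
        "config": ds.config.to_dict(),
        "config_sha256": ds.config.config_hash(),
        "files": {name: _sha256(directory / name) for name in files},
        "n_cells": int(len(ds.cells)),
        "n_genes": int(ds.counts.n_genes),
        "n_plaques": int(len(ds.plaques)),
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)
    return manifest


def read_dataset(directory) -> SyntheticDataset:
    """Read a dataset written by :func:`write_dataset`."""
    from .spatial import plaques_from_frame

    directory = Path(directory)
    if not (directory / "manifest.json").exists():
        raise InputError(f"no manifest.json under {directory}")
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    cfg_dict = dict(manifest["config"])
    for key in ("region", "plaque_radius_range", "frac_states", "effect_log2fc",
                "volume_lognormal", "sample_depth"):
        cfg_dict[key] = tuple(cfg_dict[key])
    cfg_dict["intensity_mixture"] = tuple(tuple(c) for c in cfg_dict["intensity_mixture"])
    config = SimulationConfig(**cfg_dict)

    genes = [ln for ln in (directory / "features.tsv").read_text().splitlines() if ln]
    barcodes = [ln for ln in (directory / "barcodes.tsv").read_text().splitlines() if ln]
    mat = scipy_io.mmread(directory / "counts.mtx").toarray().astype(np.int64)
    counts = ExpressionMatrix(
        pd.DataFrame(mat, index=pd.Index(barcodes, name="cell_id"), columns=genes), RAW
    )

    # round_trip parsing: the default C parser can be one ulp off, breaking
    # byte-identical re-serialization of a read dataset
    cells = pd.read_csv(directory / "cells.csv", float_precision="round_trip")
    plaques = plaques_from_frame(pd.read_csv(directory / "plaques.csv", float_precision="round_trip"))
    region = RegionPolygon.read_geojson(directory / "region.geojson")
    intensities = pd.read_csv(directory / "intensities.csv", float_precision="round_trip")
    truth_cells = pd.read_csv(directory / "truth_cells.csv", keep_default_na=False)
    effects = pd.read_csv(directory / "truth_effects.csv", index_col="gene", float_precision="round_trip")
    baseline = None
    if "baseline_mean" in effects.columns:
        baseline = effects.pop("baseline_mean")
    with open(directory / "programs.json") as fh:
        programs = {p: tuple(g) for p, g in json.load(fh).items()}

    idx = pd.Index(truth_cells["cell_id"])
    truth = GroundTruth(
        cell_state=pd.Series(truth_cells["cell_state"].to_numpy(dtype=object), index=idx),
        program_genes=programs,
        true_log2fc=effects,
        true_proximity_label=pd.Series(truth_cells["true_proximity_label"].to_numpy(dtype=object), index=idx),
        intensity_component=pd.Series(truth_cells["intensity_component"].to_numpy(dtype=int), index=idx)
        if "intensity_component" in truth_cells
        else None,
        qc_fail_reason=pd.Series(truth_cells["qc_fail_reason"].to_numpy(dtype=object), index=idx)
        if "qc_fail_reason" in truth_cells
        else None,
        gene_baseline=baseline,
    )
    return SyntheticDataset(cells, counts, plaques, region, intensities, truth, config)
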
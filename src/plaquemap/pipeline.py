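"""End-to-end orchestration: simulate/load -> QC -> proximity -> DE -> scoring -> PU.1.

``run_pipeline`` executes the stages in a fixed order from one resolved
config, persists every intermediate artifact, and emits a machine-readable
``report.json`` whose stage counts are mutually consistent and whose content
is byte-identical across reruns with the same config and seed (wall-clock
timing goes to the log only, never into the report).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import de, intensity, qc, scoring, spatial
from .containers import InputError
from .synthdata import SimulationConfig, SyntheticDataset, read_dataset, simulate_dataset, write_dataset

log = logging.getLogger("plaquemap")

STAGE_ORDER = ("simulate", "qc", "proximity", "de", "score", "classify_pu1")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending records."""


@dataclass
class PipelineConfig:
    """Resolved configuration for one pipeline run.

    Thresholds default to the study values: 40 transcripts, 100 um^3,
    11 unique genes, 15 um proximity cutoff, min.pct 0.01, log2fc threshold
    0.25, PU.1 fold change 1.25, Cd28 >= 5 dots, Mx1 >= 3 dots.
    """

    seed: int = 0
    output_dir: str = "plaquemap_run"
    input_dir: str | None = None  # read an existing dataset instead of simulating
    simulate: dict = field(default_factory=dict)  # SimulationConfig overrides
    min_transcripts: int = qc.DEFAULT_MIN_TRANSCRIPTS
    min_volume_um3: float = qc.DEFAULT_MIN_VOLUME_UM3
    min_genes: int = qc.DEFAULT_MIN_GENES
    cutoff_um: float = spatial.DEFAULT_CUTOFF_UM
    min_pct: float = de.DEFAULT_MIN_PCT
    logfc_threshold: float = de.DEFAULT_LOGFC_THRESHOLD
    de_adjust: str = "bh"
    score_sets: tuple[str, ...] = ("lymphoid", "interferon", "DAM", "homeostatic")
    n_bins: int = scoring.DEFAULT_N_BINS
    n_ctrl: int = scoring.DEFAULT_N_CTRL
    fold_change: float = intensity.DEFAULT_FOLD_CHANGE
    cd28_dots: int = scoring.SPOT_THRESHOLDS["Cd28"]
    mx1_dots: int = scoring.SPOT_THRESHOLDS["Mx1"]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        if "score_sets" in raw:
            raw["score_sets"] = tuple(raw["score_sets"])
        return cls(**raw)

    def resolved(self) -> dict:
        d = asdict(self)
        d["score_sets"] = list(self.score_sets)
        d["simulate"] = self.simulation_config().to_dict() if self.input_dir is None else None
        return d

    def simulation_config(self) -> SimulationConfig:
        overrides = dict(self.simulate)
        overrides.setdefault("seed", self.seed)
        for key in ("region", "plaque_radius_range", "frac_states", "effect_log2fc",
                    "volume_lognormal", "sample_depth"):
            if key in overrides:
                overrides[key] = tuple(overrides[key])
        if "intensity_mixture" in overrides:
            overrides["intensity_mixture"] = tuple(tuple(c) for c in overrides["intensity_mixture"])
        return SimulationConfig(**overrides)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_table(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def validate_inputs(directory) -> list[dict]:
    """Schema diagnostics for an on-disk dataset.

    Returns a list of ``{"level": "warning"|"fatal", "message": ...}``
    diagnostics; raises nothing itself so callers can collect everything.
    """
    directory = Path(directory)
    diags: list[dict] = []

    def fatal(msg):
        diags.append({"level": "fatal", "message": msg})

    def warn(msg):
        diags.append({"level": "warning", "message": msg})

    required = ["cells.csv", "plaques.csv", "region.geojson", "manifest.json"]
    for name in required:
        if not (directory / name).exists():
            fatal(f"missing required file {name}")
    if any(d["level"] == "fatal" for d in diags):
        return diags

    cells = pd.read_csv(directory / "cells.csv")
    for col in ("cell_id", "x_um", "y_um", "volume_um3", "sample_id"):
        if col not in cells.columns:
            fatal(f"cells.csv missing required column {col!r}")
    extra = set(cells.columns) - {"cell_id", "x_um", "y_um", "volume_um3", "sample_id", "cluster"}
    if extra:
        warn(f"cells.csv has unknown columns {sorted(extra)}")

    plq = pd.read_csv(directory / "plaques.csv")
    coord_cols = [c for c in plq.columns if c != "plaque_id"]
    if len(coord_cols) != 8:
        fatal(f"plaques.csv must carry exactly 8 coordinate columns (x1..y4), found {len(coord_cols)}")

    try:
        region = spatial.RegionPolygon.read_geojson(directory / "region.geojson")
    except Exception as exc:  # noqa: BLE001 - diagnostics, not control flow
        fatal(f"region.geojson unreadable: {exc}")
        return diags

    if not any(d["level"] == "fatal" for d in diags) and {"x_um", "y_um", "cell_id"} <= set(cells.columns):
        xmin, ymin, xmax, ymax = region.polygon.bounds
        out = cells[
            (cells["x_um"] < xmin) | (cells["x_um"] > xmax)
            | (cells["y_um"] < ymin) | (cells["y_um"] > ymax)
        ]
        if len(out):
            warn(f"{len(out)} cell(s) outside the region bounding box: {out['cell_id'].tolist()[:5]}")
    return diags


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in the fixed order; returns the report dict."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.resolved(), "stages": {}, "checksums": {}}
    t0 = time.perf_counter()

    def stage(name):
        log.info("stage %s", name)
        return report["stages"].setdefault(name, {})

    # -- simulate / load ---------------------------------------------------
    rec = stage("simulate")
    try:
        if config.input_dir is not None:
            ds: SyntheticDataset = read_dataset(config.input_dir)
            rec["source"] = str(config.input_dir)
        else:
            ds = simulate_dataset(config.simulation_config())
            rec["source"] = "simulated"
        manifest = write_dataset(ds, outdir / "dataset")
        rec.update(
            n_cells=int(len(ds.cells)),
            n_genes=int(ds.counts.n_genes),
            n_plaques=int(len(ds.plaques)),
            config_sha256=manifest["config_sha256"],
        )
    except Exception as exc:
        raise PipelineError(f"stage simulate failed: {exc}") from exc

    # -- QC ----------------------------------------------------------------
    rec = stage("qc")
    try:
        lognorm, cells, qc_report = qc.run_qc(
            ds.counts, ds.cells, config.min_transcripts, config.min_volume_um3, config.min_genes
        )
    except InputError as exc:
        raise PipelineError(f"stage qc failed: {exc}") from exc
    rec.update(qc_report.to_dict())
    with open(outdir / "qc_report.json", "w") as fh:
        json.dump(qc_report.to_dict(), fh, sort_keys=True, indent=1)
    lognorm.values.to_csv(outdir / "lognorm.csv", index_label="cell_id")

    # -- proximity ---------------------------------------------------------
    rec = stage("proximity")
    try:
        prox = spatial.compute_proximity(cells, ds.plaques, ds.region_polygon, config.cutoff_um)
        summary = spatial.summarize_proximity(prox, ds.plaques, ds.region_polygon)
    except InputError as exc:
        raise PipelineError(f"stage proximity failed: {exc}") from exc
    _write_table(prox, outdir / "proximity.tsv")
    rec.update(n_input=int(len(cells)), **{k: v for k, v in summary.items() if k != "per_plaque_counts"})
    rec["per_plaque_counts"] = summary["per_plaque_counts"]

    # -- differential expression ------------------------------------------
    rec = stage("de")
    labels = pd.Series(
        prox.loc[prox["in_region"], "label"].to_numpy(dtype=object),
        index=pd.Index(prox.loc[prox["in_region"], "cell_id"]),
    ).dropna()
    try:
        if labels.nunique() < 2:
            raise InputError("need both plaque-associated and distal cells within the region")
        markers = de.find_markers(
            lognorm,
            labels,
            groups=(spatial.PLAQUE_ASSOCIATED, spatial.DISTAL),
            min_pct=config.min_pct,
            logfc_threshold=config.logfc_threshold,
            adjust=config.de_adjust,
        )
    except InputError as exc:
        raise PipelineError(f"stage de failed: {exc}") from exc
    _write_table(markers, outdir / "de.tsv")
    rec.update(
        n_group1=int((labels == spatial.PLAQUE_ASSOCIATED).sum()),
        n_group2=int((labels == spatial.DISTAL).sum()),
        n_genes_tested=int(len(markers)),
        n_significant=int((markers["p_adjusted"] < 0.05).sum()) if len(markers) else 0,
        params=markers.attrs.get("params", {}),
    )

    # -- module scores -----------------------------------------------------
    rec = stage("score")
    score_cols = {}
    try:
        for name in config.score_sets:
            gs = scoring.BUILTIN_SETS[name]
            res = scoring.module_score(lognorm, gs, config.n_bins, config.n_ctrl, seed=config.seed)
            score_cols[name] = res.scores
    except (KeyError, InputError) as exc:
        raise PipelineError(f"stage score failed: {exc}") from exc
    scores = pd.DataFrame(score_cols)
    scores.insert(0, "cell_id", scores.index)
    _write_table(scores.reset_index(drop=True), outdir / "scores.tsv")
    rec["n_cells_scored"] = int(len(scores))
    if "lymphoid" in score_cols:
        grp = labels.reindex(scores.index.intersection(labels.index))
        assoc = score_cols["lymphoid"].loc[grp.index[grp == spatial.PLAQUE_ASSOCIATED]]
        distal = score_cols["lymphoid"].loc[grp.index[grp == spatial.DISTAL]]
        if len(assoc) and len(distal):
            _, p = de.wilcoxon_rank_sum(assoc, distal)
            rec["lymphoid_score_plaque_associated_mean"] = float(assoc.mean())
            rec["lymphoid_score_distal_mean"] = float(distal.mean())
            rec["lymphoid_score_rank_sum_p"] = float(p)
    if {"DAM", "homeostatic", "lymphoid"} <= set(score_cols):
        cluster_labels = ds.truth.cell_state.reindex(scores.index)
        cats = scoring.categorize_clusters(
            scores[["DAM", "homeostatic", "lymphoid"]], cluster_labels
        )
        _write_table(cats, outdir / "clusters.tsv")
        rec["cluster_categories"] = dict(zip(cats["cluster"], cats["category"]))

    # -- PU.1 intensity states --------------------------------------------
    rec = stage("classify_pu1")
    try:
        keep = ds.intensities["nucleus_id"].isin(cells["cell_id"])
        labeled = intensity.classify_nuclei(
            ds.intensities.loc[keep].reset_index(drop=True), fold_change=config.fold_change
        )
        props = intensity.state_proportions(labeled)
    except InputError as exc:
        raise PipelineError(f"stage classify_pu1 failed: {exc}") from exc
    _write_table(labeled, outdir / "pu1_states.tsv")
    _write_table(props, outdir / "pu1_proportions.tsv")
    rec.update(
        n_nuclei=int(len(labeled)),
        proportions={
            s: float(props.loc[0, f"frac_{s}"]) for s in intensity.STATES
        },
        fold_change=config.fold_change,
    )

    # -- report ------------------------------------------------------------
    artifacts = [
        "qc_report.json", "lognorm.csv", "proximity.tsv", "de.tsv", "scores.tsv",
        "clusters.tsv", "pu1_states.tsv", "pu1_proportions.tsv",
    ]
    for name in artifacts:
        path = outdir / name
        if path.exists():
            report["checksums"][name] = _sha256(path)
    report["checksums"]["dataset/manifest.json"] = _sha256(outdir / "dataset" / "manifest.json")
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, sort_keys=True, indent=1)
    log.info("pipeline finished in %.1f s", time.perf_counter() - t0)
    return report
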
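"""Cell quality filters and the three-step normalization cascade.

The cascade, in fixed order:

1. ``filter_cells`` — drop cells with fewer than 40 total transcripts or a
   segmented volume below 100 um^3 (both thresholds strict and configurable).
2. ``sample_scale`` — remove global between-sample differences in mRNA
   capture by rescaling each sample's mean per-cell total to the grand mean
   of the per-sample means.
3. ``volume_normalize`` — divide each cell's counts by its volume, yielding
   counts per cubic micrometre.
4. ``filter_min_genes`` — drop cells detecting fewer than 11 unique genes.
5. ``log_normalize`` — per cell, divide by the total per-um^3 count, multiply
   by 10,000 and apply log1p, so that sum(exp(x) - 1) == 10,000 per cell.

``run_qc`` chains the five steps and returns the log-normalized matrix, the
surviving cell table and a :class:`QcReport` whose counts reconcile exactly
with the matrix shapes at every stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import (
    LOGNORM,
    PER_UM3,
    RAW,
    SAMPLE_SCALED,
    ExpressionMatrix,
    InputError,
    align_matrix_and_cells,
)

DEFAULT_MIN_TRANSCRIPTS = 40
DEFAULT_MIN_VOLUME_UM3 = 100.0
DEFAULT_MIN_GENES = 11
LOG_NORM_SCALE = 10_000.0


@dataclass
class QcReport:
    """Bookkeeping for the QC cascade.

    ``n_fail_transcripts`` and ``n_fail_volume`` count cells failing each
    criterion (a cell failing both is counted in both); ``n_fail_first_stage``
    counts each dropped cell once, so
    ``n_retained == n_input - n_fail_first_stage - n_fail_genes``.
    """

    n_input: int = 0
    n_fail_transcripts: int = 0
    n_fail_volume: int = 0
    n_fail_first_stage: int = 0
    n_fail_genes: int = 0
    n_retained: int = 0
    sample_scale_factors: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    notes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def filter_cells(
    matrix: ExpressionMatrix,
    cells: pd.DataFrame,
    min_transcripts: int = DEFAULT_MIN_TRANSCRIPTS,
    min_volume: float = DEFAULT_MIN_VOLUME_UM3,
) -> tuple[ExpressionMatrix, pd.DataFrame, QcReport]:
    """Drop cells with total transcripts < ``min_transcripts`` OR volume < ``min_volume``.

    Both comparisons are strict: a cell with exactly 40 transcripts or exactly
    100 um^3 is retained.
    """
    if matrix.layer != RAW:
        raise InputError(f"filter_cells expects the raw layer, got {matrix.layer!r}")
    cells = align_matrix_and_cells(matrix, cells)
    totals = matrix.total_counts().to_numpy()
    volumes = cells["volume_um3"].to_numpy(dtype=float)
    fail_t = totals < min_transcripts
    fail_v = volumes < min_volume
    keep = ~(fail_t | fail_v)
    report = QcReport(
        n_input=matrix.n_cells,
        n_fail_transcripts=int(fail_t.sum()),
        n_fail_volume=int(fail_v.sum()),
        n_fail_first_stage=int((~keep).sum()),
        n_retained=int(keep.sum()),
        params={"min_transcripts": min_transcripts, "min_volume_um3": min_volume},
    )
    kept_ids = matrix.cell_ids[keep]
    return matrix.subset_cells(kept_ids), cells.loc[keep].reset_index(drop=True), report


def sample_scale(matrix: ExpressionMatrix, cells: pd.DataFrame) -> ExpressionMatrix:
    """Equalize per-sample mean per-cell totals against their grand mean.

    Every cell in sample *s* is multiplied by
    ``mean(per-sample means) / mean(per-cell totals of s)``, which removes
    global differences in transcript capture between samples while leaving a
    single-sample dataset unchanged.
    """
    cells = align_matrix_and_cells(matrix, cells)
    totals = matrix.total_counts()
    sample_ids = cells["sample_id"].to_numpy()
    sample_means = totals.groupby(sample_ids).mean()
    zero = sample_means[sample_means <= 0]
    if len(zero):
        raise InputError(f"sample(s) with zero total transcripts: {list(zero.index)}")
    grand_mean = float(sample_means.mean())
    factors = grand_mean / sample_means
    scaled = matrix.values.mul(factors.loc[sample_ids].to_numpy(), axis=0)
    meta = dict(matrix.meta)
    meta["sample_scale_factors"] = {str(k): float(v) for k, v in factors.items()}
    meta["sample_scale_definition"] = (
        "per-sample mean per-cell totals rescaled to the unweighted grand mean of "
        "per-sample means (reference-sample and per-cell variants not used)"
    )
    return ExpressionMatrix(scaled, SAMPLE_SCALED, meta)


def volume_normalize(matrix: ExpressionMatrix, cells: pd.DataFrame) -> ExpressionMatrix:
    """Divide each cell's values by its volume -> counts per cubic micrometre."""
    if matrix.layer not in (RAW, SAMPLE_SCALED):
        raise InputError(f"volume_normalize expects raw or sample-scaled values, got {matrix.layer!r}")
    cells = align_matrix_and_cells(matrix, cells)
    volumes = cells["volume_um3"].to_numpy(dtype=float)
    if (volumes <= 0).any():
        bad = cells.loc[volumes <= 0, "cell_id"].tolist()
        raise InputError(f"non-positive volumes among retained cells: {bad[:5]}")
    return ExpressionMatrix(matrix.values.div(volumes, axis=0), PER_UM3, dict(matrix.meta))


def filter_min_genes(
    matrix: ExpressionMatrix,
    cells: pd.DataFrame,
    min_genes: int = DEFAULT_MIN_GENES,
) -> tuple[ExpressionMatrix, pd.DataFrame, QcReport]:
    """Drop cells detecting fewer than ``min_genes`` genes (value > 0).

    Positivity is preserved by the scaling steps, so counting unique genes on
    any layer equals counting on raw counts.
    """
    cells = align_matrix_and_cells(matrix, cells)
    n_unique = (matrix.values.to_numpy() > 0).sum(axis=1)
    keep = n_unique >= min_genes
    report = QcReport(
        n_input=matrix.n_cells,
        n_fail_genes=int((~keep).sum()),
        n_retained=int(keep.sum()),
        params={"min_genes": min_genes},
    )
    kept_ids = matrix.cell_ids[keep]
    return matrix.subset_cells(kept_ids), cells.loc[keep].reset_index(drop=True), report


def log_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Library-size normalize to 10,000 per cell and log1p-transform.

    x[c, g] = ln(1 + 10,000 * v[c, g] / sum_g v[c, g]).  Natural log; the base
    is recorded in the output metadata.  After this step
    sum_g (exp(x) - 1) == 10,000 for every cell.
    """
    if matrix.layer != PER_UM3:
        raise InputError(f"log_normalize expects the per-um^3 layer, got {matrix.layer!r}")
    totals = matrix.total_counts().to_numpy()
    if (totals <= 0).any():
        bad = matrix.cell_ids[totals <= 0].tolist()
        raise InputError(f"cells with zero total signal reached log_normalize: {bad[:5]}")
    values = np.log1p(LOG_NORM_SCALE * matrix.values.to_numpy() / totals[:, None])
    meta = dict(matrix.meta)
    meta["log_base"] = "e"
    meta["scale_factor"] = LOG_NORM_SCALE
    return ExpressionMatrix(pd.DataFrame(values, index=matrix.cell_ids, columns=matrix.genes), LOGNORM, meta)


def run_qc(
    matrix: ExpressionMatrix,
    cells: pd.DataFrame,
    min_transcripts: int = DEFAULT_MIN_TRANSCRIPTS,
    min_volume: float = DEFAULT_MIN_VOLUME_UM3,
    min_genes: int = DEFAULT_MIN_GENES,
) -> tuple[ExpressionMatrix, pd.DataFrame, QcReport]:
    """Run the full cascade in its fixed order and reconcile the report."""
    m1, c1, rep1 = filter_cells(matrix, cells, min_transcripts, min_volume)
    if m1.n_cells == 0:
        raise InputError(
            "no cells survive the transcript/volume filters "
            f"(min_transcripts={min_transcripts}, min_volume={min_volume})"
        )
    m2 = sample_scale(m1, c1)
    m3 = volume_normalize(m2, c1)
    m4, c4, rep2 = filter_min_genes(m3, c1, min_genes)
    if m4.n_cells == 0:
        raise InputError(f"no cells survive the unique-gene filter (min_genes={min_genes})")
    m5 = log_normalize(m4)
    report = QcReport(
        n_input=rep1.n_input,
        n_fail_transcripts=rep1.n_fail_transcripts,
        n_fail_volume=rep1.n_fail_volume,
        n_fail_first_stage=rep1.n_fail_first_stage,
        n_fail_genes=rep2.n_fail_genes,
        n_retained=m4.n_cells,
        sample_scale_factors=m2.meta["sample_scale_factors"],
        params={
            "min_transcripts": min_transcripts,
            "min_volume_um3": min_volume,
            "min_genes": min_genes,
            "log_base": "e",
            "scale_factor": LOG_NORM_SCALE,
        },
        notes=[m2.meta["sample_scale_definition"]],
    )
    assert report.n_retained == report.n_input - report.n_fail_first_stage - report.n_fail_genes
    return m5, c4, report
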
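"""Shared in-memory containers for the analysis pipeline.

The central object is :class:`ExpressionMatrix`, a cells x genes table with a
declared *layer* tag that records where in the normalization cascade the
values sit.  Cell metadata travels separately as a plain pandas DataFrame
(the "cell table") with the columns declared in :data:`CELL_COLUMNS`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Layer tags, in the order the normalization cascade produces them.
RAW = "raw"
SAMPLE_SCALED = "sample_scaled"
PER_UM3 = "per_um3"
LOGNORM = "lognorm"
LAYERS = (RAW, SAMPLE_SCALED, PER_UM3, LOGNORM)

#: Required cell-table columns.  ``cluster`` is optional.
CELL_COLUMNS = ("cell_id", "x_um", "y_um", "volume_um3", "sample_id")


class InputError(ValueError):
    """Malformed or mutually inconsistent inputs."""


@dataclass
class ExpressionMatrix:
    """Cells x genes expression values with a declared layer tag.

    Parameters
    ----------
    values
        DataFrame indexed by cell id with gene ids as columns.
    layer
        One of :data:`LAYERS`.  The ``raw`` layer must hold non-negative
        integers; every layer must be free of non-finite values.
    """

    values: pd.DataFrame
    layer: str = RAW
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise InputError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            raise InputError(f"non-finite values in {self.layer!r} expression matrix")
        if self.layer == RAW and arr.size:
            if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
                raise InputError("raw layer must contain non-negative integer counts")
        if not self.values.index.is_unique:
            raise InputError("duplicate cell ids in expression matrix")
        if not self.values.columns.is_unique:
            raise InputError("duplicate gene ids in expression matrix")

    # -- convenience -------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def cell_ids(self) -> pd.Index:
        return self.values.index

    @property
    def genes(self) -> pd.Index:
        return self.values.columns

    def subset_cells(self, cell_ids) -> "ExpressionMatrix":
        """Return a matrix restricted to ``cell_ids`` (order preserved)."""
        return ExpressionMatrix(self.values.loc[cell_ids], self.layer, dict(self.meta))

    def total_counts(self) -> pd.Series:
        """Per-cell totals over genes."""
        return self.values.sum(axis=1)


def validate_cell_table(cells: pd.DataFrame, *, require_positive_volume: bool = True) -> None:
    """Schema checks for a cell metadata table.

    Raises :class:`InputError` on missing columns, duplicate ids, non-finite
    coordinates/volumes or (by default) non-positive volumes.
    """
    missing = [c for c in CELL_COLUMNS if c not in cells.columns]
    if missing:
        raise InputError(f"cell table is missing required columns: {missing}")
    if cells["cell_id"].duplicated().any():
        dupes = cells.loc[cells["cell_id"].duplicated(), "cell_id"].tolist()
        raise InputError(f"duplicate cell ids: {dupes[:5]}")
    for col in ("x_um", "y_um", "volume_um3"):
        vals = cells[col].to_numpy(dtype=float)
        if vals.size and not np.isfinite(vals).all():
            raise InputError(f"non-finite values in cell table column {col!r}")
    if require_positive_volume and (cells["volume_um3"].to_numpy(dtype=float) <= 0).any():
        bad = cells.loc[cells["volume_um3"] <= 0, "cell_id"].tolist()
        raise InputError(f"non-positive cell volumes for: {bad[:5]}")


def align_matrix_and_cells(matrix: ExpressionMatrix, cells: pd.DataFrame) -> pd.DataFrame:
    """Check that matrix rows and cell-table rows describe the same cells.

    Returns the cell table re-indexed to the matrix row order.
    """
    validate_cell_table(cells, require_positive_volume=False)
    table_ids = pd.Index(cells["cell_id"])
    if set(table_ids) != set(matrix.cell_ids):
        only_m = set(matrix.cell_ids) - set(table_ids)
        only_t = set(table_ids) - set(matrix.cell_ids)
        raise InputError(
            "cell ids differ between expression matrix and cell table "
            f"(matrix-only: {sorted(only_m)[:3]}, table-only: {sorted(only_t)[:3]})"
        )
    return cells.set_index("cell_id", drop=False).loc[matrix.cell_ids].reset_index(drop=True)
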
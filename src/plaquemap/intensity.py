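"""PU.1 nuclear-intensity state classification.

Microglial nuclei are classed low / medium / high by their mean nuclear PU.1
signal.  The cutoffs derive from a reference fold change *f* — the ratio of
mean PU.1 signal between nuclei of PU.1-high and PU.1-low reference animals,
measured once as 1.25 — applied around the mean intensity *m* of all
microglia in the experiment: ``low_cut = m / f`` and ``high_cut = m * f``.
Nuclei below the low cutoff are PU.1-low, above the high cutoff PU.1-high,
and between the cutoffs (inclusive) PU.1-medium.

``f`` is a stored calibration constant (default 1.25) so classification runs
without reference populations; recomputing it from reference intensity
tables is optional.  The population mean is computed per ``sample_id`` batch
by default, mirroring per-experiment calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import InputError

DEFAULT_FOLD_CHANGE = 1.25

LOW, MEDIUM, HIGH = "low", "medium", "high"
STATES = (LOW, MEDIUM, HIGH)


@dataclass(frozen=True)
class Pu1Cutoffs:
    """Reference-derived intensity cutoffs for one experiment/batch."""

    fold_change: float
    population_mean: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.fold_change) or self.fold_change < 1:
            raise InputError(f"fold change must be >= 1, got {self.fold_change}")
        if not np.isfinite(self.population_mean) or self.population_mean <= 0:
            raise InputError(f"population mean must be positive, got {self.population_mean}")

    @property
    def low_cut(self) -> float:
        return self.population_mean / self.fold_change

    @property
    def high_cut(self) -> float:
        return self.population_mean * self.fold_change


def _validate_intensities(values: np.ndarray, what: str) -> None:
    if values.size == 0:
        raise InputError(f"{what} is empty")
    if not np.isfinite(values).all() or (values <= 0).any():
        raise InputError(f"{what} must be finite and positive")


def reference_fold_change(high_ref, low_ref) -> float:
    """f = mean(high-reference intensities) / mean(low-reference intensities)."""
    hi = np.asarray(high_ref, dtype=float)
    lo = np.asarray(low_ref, dtype=float)
    _validate_intensities(hi, "high reference")
    _validate_intensities(lo, "low reference")
    return float(hi.mean() / lo.mean())


def compute_cutoffs(all_intensities, fold_change: float = DEFAULT_FOLD_CHANGE) -> Pu1Cutoffs:
    """Cutoffs from the mean intensity of all microglia in the experiment."""
    vals = np.asarray(all_intensities, dtype=float)
    _validate_intensities(vals, "intensity population")
    if fold_change < 1:
        raise InputError(f"fold change must be >= 1, got {fold_change}")
    return Pu1Cutoffs(float(fold_change), float(vals.mean()))


def classify_intensity(values, cutoffs: Pu1Cutoffs) -> np.ndarray:
    """Vector low/medium/high classification; cutoff values count as medium."""
    vals = np.asarray(values, dtype=float)
    _validate_intensities(vals, "intensities")
    out = np.full(vals.shape, MEDIUM, dtype=object)
    out[vals < cutoffs.low_cut] = LOW
    out[vals > cutoffs.high_cut] = HIGH
    return out.astype(str)


def classify_nuclei(
    table: pd.DataFrame,
    cutoffs: Pu1Cutoffs | None = None,
    fold_change: float = DEFAULT_FOLD_CHANGE,
    *,
    per_sample: bool = True,
) -> pd.DataFrame:
    """Add a ``pu1_state`` column to a nuclear-intensity table.

    With ``cutoffs=None`` the population mean is computed from the table
    itself — per ``sample_id`` batch when ``per_sample`` is set (default),
    pooled otherwise — and combined with ``fold_change``.
    """
    for col in ("nucleus_id", "mean_intensity"):
        if col not in table.columns:
            raise InputError(f"intensity table is missing the {col!r} column")
    out = table.copy()
    if cutoffs is not None:
        out["pu1_state"] = classify_intensity(out["mean_intensity"].to_numpy(), cutoffs)
    elif per_sample and "sample_id" in out.columns:
        states = pd.Series(index=out.index, dtype=object)
        for _, idx in out.groupby("sample_id").groups.items():
            cuts = compute_cutoffs(out.loc[idx, "mean_intensity"].to_numpy(), fold_change)
            states.loc[idx] = classify_intensity(out.loc[idx, "mean_intensity"].to_numpy(), cuts)
        out["pu1_state"] = states.astype(str)
    else:
        cuts = compute_cutoffs(out["mean_intensity"].to_numpy(), fold_change)
        out["pu1_state"] = classify_intensity(out["mean_intensity"].to_numpy(), cuts)
    return out


def state_proportions(labeled: pd.DataFrame, group_by: str | None = None) -> pd.DataFrame:
    """Low/medium/high fractions, normalized to the nuclei analysed per group."""
    if "pu1_state" not in labeled.columns:
        raise InputError("table has no 'pu1_state' column; run classify_nuclei first")
    if group_by is None:
        groups = {"all": labeled.index}
    else:
        if group_by not in labeled.columns:
            raise InputError(f"unknown grouping column {group_by!r}")
        groups = labeled.groupby(group_by).groups
    rows = []
    for name, idx in groups.items():
        sub = labeled.loc[idx, "pu1_state"]
        if len(sub) == 0:
            raise InputError(f"group {name!r} has no labeled nuclei")
        counts = sub.value_counts()
        total = int(len(sub))
        row = {"group": name, "n": total}
        for state in STATES:
            row[f"frac_{state}"] = counts.get(state, 0) / total
        rows.append(row)
    out = pd.DataFrame(rows)
    assert np.allclose(out[[f"frac_{s}" for s in STATES]].sum(axis=1), 1.0, atol=1e-12)
    return out
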
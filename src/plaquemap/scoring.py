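"""Gene-set module scores, cluster categorization and dot-count positivity.

The module score follows the control-gene-bin construction used throughout
the single-cell literature: genes are binned by mean expression, each
signature gene draws control genes from its own bin, and a cell's score is
its mean signature expression minus its mean control expression.  Scores are
therefore centred near zero and may be negative.

Cluster categorization splits microglial clusters into homeostatic vs DAM by
comparing mean DAM and homeostatic module scores, and subdivides DAM
clusters into lymphoid-positive/negative by the sign of the mean lymphoid
score.  Dot-count positivity implements the in situ hybridization calls
(Cd28 >= 5 dots, Mx1 >= 3 dots).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, InputError

# Bundled signature gene sets.  The lymphoid and interferon sets are the
# mouse immunoregulatory-receptor and type-I interferon-stimulated panels
# used for microglial scoring (interferon list de-duplicated); the DAM and
# homeostatic sets are the canonical cluster-driving markers of each state.
LYMPHOID_GENES = ("Cd28", "Cd274", "Pdcd1", "Ctla2a", "Cd5", "Sox5", "Cd48", "Cd52", "Cd72")
INTERFERON_GENES = (
    "Ifitm3", "Ifit3", "Isg15", "Ifit2", "Ifi27l2a", "Ifi204", "Irf7", "Usp18",
    "Stat2", "Ifitm2", "Rsad2", "Ifit1", "Bst2", "Isg20", "Xaf1",
)
DAM_GENES = ("Cst7", "Apoe", "Lpl", "Itgax")
HOMEOSTATIC_GENES = ("Cx3cr1", "Tmem119", "P2ry12", "Csf1r", "Hexb", "Sall1", "Selplg")

#: In situ hybridization dot-count thresholds for calling a cell positive.
SPOT_THRESHOLDS = {"Cd28": 5, "Mx1": 3}

HOMEOSTATIC = "homeostatic"
DAM_LYMPHOID_POS = "DAM_lymphoid_pos"
DAM_LYMPHOID_NEG = "DAM_lymphoid_neg"

DEFAULT_N_BINS = 24
DEFAULT_N_CTRL = 100


@dataclass(frozen=True)
class GeneSet:
    """A named signature gene set."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise InputError(f"gene set {self.name!r} is empty")
        object.__setattr__(self, "genes", tuple(dict.fromkeys(self.genes)))

    def match(self, available, *, allow_missing: bool = False) -> tuple[str, ...]:
        """Intersect with the matrix genes; missing ids are reported, never dropped silently."""
        avail = set(available)
        present = tuple(g for g in self.genes if g in avail)
        missing = [g for g in self.genes if g not in avail]
        if not present:
            raise InputError(f"gene set {self.name!r}: no genes found in matrix (missing: {missing})")
        if missing and not allow_missing:
            raise InputError(
                f"gene set {self.name!r}: {len(missing)} gene(s) absent from matrix: {missing}; "
                "pass allow_missing=True to score the matched subset"
            )
        return present


BUILTIN_SETS = {
    "lymphoid": GeneSet("lymphoid", LYMPHOID_GENES),
    "interferon": GeneSet("interferon", INTERFERON_GENES),
    "DAM": GeneSet("DAM", DAM_GENES),
    "homeostatic": GeneSet("homeostatic", HOMEOSTATIC_GENES),
}


@dataclass
class ModuleScoreResult:
    """Per-cell module scores plus the parameters that produced them."""

    set_name: str
    scores: pd.Series  # indexed by cell id
    params: dict = field(default_factory=dict)


def module_score(
    matrix: ExpressionMatrix,
    gene_set: GeneSet,
    n_bins: int = DEFAULT_N_BINS,
    n_ctrl: int = DEFAULT_N_CTRL,
    seed: int = 0,
    *,
    allow_missing: bool = False,
) -> ModuleScoreResult:
    """Control-gene-bin module score.

    Genes are ranked by mean expression across cells and cut into ``n_bins``
    equal-frequency bins.  For every signature gene, ``n_ctrl`` control genes
    are drawn (seed-controlled) from the same bin, excluding signature genes
    — without replacement when the bin is large enough, otherwise with
    replacement (recorded in ``params``).  The score of cell *c* is the mean
    expression of the signature genes minus the mean expression of the pooled
    control draw.
    """
    if matrix.n_genes < n_bins:
        raise InputError(f"matrix has {matrix.n_genes} genes; needs >= n_bins ({n_bins})")
    set_genes = gene_set.match(matrix.genes, allow_missing=allow_missing)

    X = matrix.values
    gene_means = X.mean(axis=0)
    # equal-frequency bins on mean expression (stable rank -> deterministic)
    order = np.argsort(gene_means.to_numpy(), kind="stable")
    ranks = np.empty(matrix.n_genes, dtype=int)
    ranks[order] = np.arange(matrix.n_genes)
    bins = (ranks * n_bins) // matrix.n_genes
    bin_of = dict(zip(matrix.genes, bins))

    set_lookup = set(set_genes)
    rng = np.random.default_rng(seed)
    controls: list[str] = []
    with_replacement = False
    widened = False
    genes_arr = np.asarray(matrix.genes)
    non_set = ~np.isin(genes_arr, list(set_lookup))
    if not non_set.any():
        raise InputError("no control genes: the gene set covers the whole panel")
    for g in set_genes:
        # widen to neighbouring bins if the gene's own bin holds only set genes
        width = 0
        while True:
            in_window = np.abs(bins - bin_of[g]) <= width
            pool = genes_arr[in_window & non_set]
            if pool.size:
                break
            width += 1
            widened = True
        replace = pool.size < n_ctrl
        with_replacement = with_replacement or replace
        controls.extend(rng.choice(pool, size=n_ctrl, replace=replace))

    scores = X[list(set_genes)].mean(axis=1) - X[controls].mean(axis=1)
    scores.name = gene_set.name
    return ModuleScoreResult(
        set_name=gene_set.name,
        scores=scores,
        params={
            "n_bins": n_bins,
            "n_ctrl": n_ctrl,
            "seed": seed,
            "n_set_genes": len(set_genes),
            "control_with_replacement": with_replacement,
            "control_bins_widened": widened,
        },
    )


def categorize_clusters(scores: pd.DataFrame, clusters: pd.Series) -> pd.DataFrame:
    """Categorize clusters into homeostatic / lymphoid+ DAM / lymphoid- DAM.

    Parameters
    ----------
    scores
        Per-cell DataFrame with columns ``DAM``, ``homeostatic`` and
        ``lymphoid`` (module scores), indexed by cell id.
    clusters
        Series mapping cell id -> cluster label (same index).

    A cluster is DAM when its mean DAM score exceeds its mean homeostatic
    score (ties fall to homeostatic, the null category); DAM clusters are
    lymphoid-positive when their mean lymphoid score is > 0.  Because module
    scores can be negative a literal DAM/homeostatic score ratio is
    ill-defined; the mean difference decides and the ratio is reported
    alongside for reference.
    """
    for col in ("DAM", "homeostatic", "lymphoid"):
        if col not in scores.columns:
            raise InputError(f"scores table is missing the {col!r} column")
    clusters = clusters.reindex(scores.index)
    if clusters.isna().any():
        raise InputError("every scored cell needs a cluster label")
    rows = []
    for cluster, idx in scores.groupby(clusters).groups.items():
        sub = scores.loc[idx]
        if len(sub) == 0:
            raise InputError(f"cluster {cluster!r} is empty")
        mean_dam = float(sub["DAM"].mean())
        mean_homeo = float(sub["homeostatic"].mean())
        mean_lymph = float(sub["lymphoid"].mean())
        if mean_dam > mean_homeo:
            category = DAM_LYMPHOID_POS if mean_lymph > 0 else DAM_LYMPHOID_NEG
        else:
            category = HOMEOSTATIC
        rows.append(
            {
                "cluster": cluster,
                "category": category,
                "mean_dam_score": mean_dam,
                "mean_homeostatic_score": mean_homeo,
                "mean_lymphoid_score": mean_lymph,
                "dam_homeostatic_ratio": mean_dam / mean_homeo if mean_homeo != 0 else np.nan,
                "n_cells": int(len(sub)),
            }
        )
    return pd.DataFrame(rows)


def classify_spot_positive(spot_counts, threshold: int) -> np.ndarray:
    """Dot-count positivity: a cell is positive iff count >= threshold.

    Presets: Cd28 needs at least 5 in situ dots, Mx1 at least 3
    (:data:`SPOT_THRESHOLDS`).
    """
    counts = np.asarray(spot_counts)
    if counts.size and (not np.issubdtype(counts.dtype, np.number) or (counts < 0).any()):
        raise InputError("spot counts must be non-negative integers")
    if counts.size and not np.allclose(counts, np.round(counts)):
        raise InputError("spot counts must be integers")
    if threshold < 0:
        raise InputError("threshold must be non-negative")
    return counts >= threshold
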
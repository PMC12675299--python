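"""Rank-sum differential expression with FindMarkers-style pre-filters.

Genes are screened by detection fraction (``min_pct``) and absolute log2
fold change (``logfc_threshold``) before testing; the surviving genes are
compared between the two groups with a Wilcoxon rank-sum test and the p
values are adjusted over the tested set (Benjamini-Hochberg by default,
Bonferroni optionally).

The rank-sum test enumerates the exact null distribution for small tie-free
samples (n1 + n2 <= 12) and otherwise uses the normal approximation with
midranks, tie correction and a continuity correction.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import LOGNORM, ExpressionMatrix, InputError

DEFAULT_MIN_PCT = 0.01
DEFAULT_LOGFC_THRESHOLD = 0.25
DEFAULT_PSEUDOCOUNT = 1.0
EXACT_MAX_N = 12


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns ``(W, p)`` where ``W`` is the rank sum of ``x`` (midranks for
    ties).  For tie-free samples with ``n1 + n2 <= 12`` the p value comes
    from exhaustive enumeration of all C(n, n1) group assignments
    (``p = P(|W - E[W]| >= |w - E[W]|)`` under the permutation null);
    otherwise from the normal approximation with tie and continuity
    corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InputError("both groups must be non-empty")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise InputError("non-finite values passed to wilcoxon_rank_sum")
    n1, n2 = x.size, y.size
    n = n1 + n2
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # midranks
    w = float(ranks[:n1].sum())
    mu = n1 * (n + 1) / 2.0

    no_ties = np.unique(pooled).size == n
    if no_ties and n <= EXACT_MAX_N:
        # exhaustive enumeration of the permutation null
        all_ranks = np.arange(1, n + 1)
        sums = np.fromiter(
            (sum(c) for c in combinations(all_ranks, n1)),
            dtype=float,
        )
        p = float(np.mean(np.abs(sums - mu) >= abs(w - mu) - 1e-9))
        return w, min(1.0, p)

    # normal approximation with tie correction
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return w, 1.0  # all pooled values identical
    diff = w - mu
    # continuity correction shrinks |diff| by 0.5
    diff_cc = np.sign(diff) * max(abs(diff) - 0.5, 0.0)
    z = diff_cc / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return w, float(min(1.0, p))


def log2_fold_change(group1, group2, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> float:
    """log2 fold change between de-logged group means of log-normalized values.

    ``log2((mean(exp(x) - 1 over group1) + pc) / (mean(exp(x) - 1 over group2) + pc))``.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size == 0 or g2.size == 0:
        raise InputError("both groups must be non-empty")
    m1 = float(np.mean(np.expm1(g1)))
    m2 = float(np.mean(np.expm1(g2)))
    return float(np.log2((m1 + pseudocount) / (m2 + pseudocount)))


def pct_expressing(values) -> float:
    """Fraction of cells with value > 0."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise InputError("empty group in pct_expressing")
    return float(np.mean(v > 0))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, monotone and capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p <= 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise InputError("p values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def bonferroni_adjust(p_values) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p <= 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise InputError("p values must lie in (0, 1]")
    return multipletests(p, method="bonferroni")[1]


def find_markers(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    groups: tuple[str, str] | None = None,
    min_pct: float = DEFAULT_MIN_PCT,
    logfc_threshold: float = DEFAULT_LOGFC_THRESHOLD,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    adjust: str = "bh",
) -> pd.DataFrame:
    """Two-group marker detection on the log-normalized layer.

    Parameters
    ----------
    matrix
        Log-normalized expression (:data:`~plaquemap.containers.LOGNORM` layer).
    labels
        Series mapping cell id -> group label; may cover a subset of the
        matrix cells.  Exactly two distinct labels are required.
    groups
        Orders the comparison as (group1, group2); positive log2fc means
        higher in group1.  Defaults to the sorted label pair.
    adjust
        ``"bh"`` (Benjamini-Hochberg, default) or ``"bonferroni"``; applied
        over the genes that pass both pre-filters.

    Returns a DataFrame sorted by p value with columns ``gene, log2fc,
    p_value, p_adjusted, pct_group1, pct_group2, n1, n2``.
    """
    if matrix.layer != LOGNORM:
        raise InputError(f"find_markers expects the lognorm layer, got {matrix.layer!r}")
    if adjust not in ("bh", "bonferroni"):
        raise InputError(f"unknown adjustment {adjust!r}")
    labels = labels.dropna()
    unknown = labels.index.difference(matrix.cell_ids)
    if len(unknown):
        raise InputError(f"labels refer to cells absent from the matrix: {list(unknown[:3])}")
    found = sorted(pd.unique(labels))
    if len(found) != 2:
        raise InputError(f"need exactly two groups, found {found}")
    if groups is None:
        groups = (found[0], found[1])
    if sorted(groups) != found:
        raise InputError(f"groups {groups} do not match labels {found}")

    ids1 = labels.index[labels == groups[0]]
    ids2 = labels.index[labels == groups[1]]
    x1 = matrix.values.loc[ids1].to_numpy()
    x2 = matrix.values.loc[ids2].to_numpy()
    n1, n2 = len(ids1), len(ids2)

    pct1 = (x1 > 0).mean(axis=0)
    pct2 = (x2 > 0).mean(axis=0)
    m1 = np.expm1(x1).mean(axis=0)
    m2 = np.expm1(x2).mean(axis=0)
    lfc = np.log2((m1 + pseudocount) / (m2 + pseudocount))

    keep = (np.maximum(pct1, pct2) >= min_pct) & (np.abs(lfc) >= logfc_threshold)
    genes = matrix.genes[keep]
    if len(genes) == 0:
        return pd.DataFrame(
            columns=["gene", "log2fc", "p_value", "p_adjusted", "pct_group1", "pct_group2", "n1", "n2"]
        )

    pvals = np.empty(len(genes))
    for j, g in enumerate(np.flatnonzero(keep)):
        _, pvals[j] = wilcoxon_rank_sum(x1[:, g], x2[:, g])
    adjusted = bh_adjust(pvals) if adjust == "bh" else bonferroni_adjust(pvals)

    out = pd.DataFrame(
        {
            "gene": genes,
            "log2fc": lfc[keep],
            "p_value": pvals,
            "p_adjusted": adjusted,
            "pct_group1": pct1[keep],
            "pct_group2": pct2[keep],
            "n1": n1,
            "n2": n2,
        }
    )
    out = out.sort_values(["p_value", "gene"], kind="stable").reset_index(drop=True)
    out.attrs["params"] = {
        "groups": list(groups),
        "min_pct": min_pct,
        "logfc_threshold": logfc_threshold,
        "pseudocount": pseudocount,
        "adjust": adjust,
        "n_genes_tested": int(len(genes)),
        "continuity_correction": True,
    }
    return out
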
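"""Nearest-centroid subtype assignment and score-by-subtype enrichment.

Tumours are assigned the subtype whose centroid expression vector they
correlate with most strongly (Pearson by default, Spearman optional),
the convention used for intrinsic breast-cancer subtype calls from
published centroid tables. Centroids are inputs; no training happens
here.

Given per-tumour activation scores and subtype labels,
:func:`score_by_subtype` summarises the score distribution per subtype
and tests each subtype for enrichment of "high"-scoring (top-tertile)
tumours with a hypergeometric test, Benjamini-Hochberg corrected across
subtypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from mascsig.core import check_matrix
from mascsig.scoring import dichotomise

logger = logging.getLogger(__name__)


@dataclass
class CentroidSet:
    """Per-subtype centroid expression vectors over a shared gene index."""

    centroids: pd.DataFrame  # genes x subtypes
    correlation: str = "pearson"

    def __post_init__(self) -> None:
        if self.centroids.shape[1] < 2:
            raise ValueError("need >= 2 subtype centroids")
        if self.centroids.index.has_duplicates:
            raise ValueError("duplicate genes in centroid table")
        sds = self.centroids.std(axis=0)
        if (sds == 0).any():
            bad = self.centroids.columns[sds == 0].tolist()
            raise ValueError(f"constant centroid(s): {bad}")
        if self.correlation not in ("pearson", "spearman"):
            raise ValueError(f"unknown correlation method: {self.correlation!r}")

    @property
    def subtypes(self) -> list[str]:
        return list(self.centroids.columns)


def classify_by_centroid(matrix: pd.DataFrame, centroids: CentroidSet,
                         r_min: float = 0.1) -> pd.DataFrame:
    """Assign each sample the argmax-correlation subtype.

    Returns a DataFrame indexed by sample with the assigned ``subtype``,
    one correlation column per subtype (``r_<name>``), the winning
    correlation ``r_max`` and a ``low_confidence`` flag when ``r_max``
    falls below ``r_min``. Ties break by subtype name order with a logged
    note.
    """
    check_matrix(matrix)
    shared = matrix.index.intersection(centroids.centroids.index)
    if len(shared) == 0:
        raise ValueError("no genes shared between matrix and centroids")
    if len(shared) < 10:
        raise ValueError(
            f"only {len(shared)} genes shared with centroids; >= 10 required"
        )
    x = matrix.loc[shared].to_numpy(dtype=float)
    c = centroids.centroids.loc[shared].to_numpy(dtype=float)
    if centroids.correlation == "spearman":
        x = stats.rankdata(x, axis=0)
        c = stats.rankdata(c, axis=0)
    xz = (x - x.mean(axis=0)) / x.std(axis=0)
    cz = (c - c.mean(axis=0)) / c.std(axis=0)
    corr = xz.T @ cz / len(shared)  # samples x subtypes

    names = centroids.subtypes
    best = corr.argmax(axis=1)
    ties = (corr == corr.max(axis=1, keepdims=True)).sum(axis=1) > 1
    if ties.any():
        logger.info("%d sample(s) with tied centroid correlations; "
                    "tie broken by subtype name order", int(ties.sum()))
    out = pd.DataFrame(
        corr, index=matrix.columns, columns=[f"r_{s}" for s in names]
    )
    out.insert(0, "subtype", [names[i] for i in best])
    out["r_max"] = corr.max(axis=1)
    out["low_confidence"] = out["r_max"] < r_min
    return out


def score_by_subtype(scores: pd.Series, subtypes: pd.Series,
                     alpha: float = 0.05, min_group: int = 3) -> pd.DataFrame:
    """Summarise activation scores per subtype and test "high" enrichment.

    "High" membership is the top tertile of the score. Per subtype the
    hypergeometric upper-tail probability of observing at least the seen
    number of high tumours is computed; Benjamini-Hochberg correction runs
    across the tested subtypes. Subtypes with fewer than ``min_group``
    tumours are summarised but excluded from testing.
    """
    subtypes = subtypes.reindex(scores.index)
    if subtypes.isna().any():
        missing = scores.index[subtypes.isna()].tolist()
        raise ValueError(f"samples without subtype label: {missing[:5]}")
    high = dichotomise(scores, "top_tertile") == "high"
    n_total = len(scores)
    n_high = int(high.sum())

    rows = []
    for name, idx in scores.groupby(subtypes).groups.items():
        sub_scores = scores.loc[idx]
        k_high = int(high.loc[idx].sum())
        rows.append({
            "subtype": name,
            "n": len(idx),
            "n_high": k_high,
            "median": float(sub_scores.median()),
            "q1": float(sub_scores.quantile(0.25)),
            "q3": float(sub_scores.quantile(0.75)),
            "testable": len(idx) >= min_group,
        })
    summary = pd.DataFrame(rows).set_index("subtype").sort_index()

    testable = summary.index[summary["testable"]]
    if len(testable) == 0 or len(summary) < 2:
        logger.warning("no subtype testable for enrichment; summary only")
        summary["p_hypergeom"] = np.nan
        summary["p_bh"] = np.nan
        summary["enriched"] = False
        return summary

    pvals = []
    for name in testable:
        n_sub = int(summary.loc[name, "n"])
        k = int(summary.loc[name, "n_high"])
        # P(X >= k) drawing n_sub from a universe with n_high highs
        pvals.append(float(stats.hypergeom.sf(k - 1, n_total, n_high, n_sub)))
    _, p_bh, _, _ = multipletests(pvals, method="fdr_bh")
    summary["p_hypergeom"] = np.nan
    summary["p_bh"] = np.nan
    summary.loc[testable, "p_hypergeom"] = pvals
    summary.loc[testable, "p_bh"] = p_bh
    summary["enriched"] = summary["p_bh"] < alpha
    return summary
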
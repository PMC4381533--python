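"""Signature activation scoring of tumour cohorts.

Two scoring routes are provided, mirroring the two ways a signature's
activity is usually summarised per tumour:

* :func:`average_score` — median-centre each gene across the cohort, then
  average the centred expression of the signature genes per sample.
* :func:`relevance_network_score` — a relevance-network (DART-style)
  variant: build the signature-gene correlation graph over the cohort,
  keep significantly positively correlated edges, retain the largest
  connected component, drop genes anti-correlated with the component mean
  (denoising), and average the z-scored expression of the retained genes.
  This is a documented variant, not a reproduction of any specific
  published implementation.

Cohorts are then dichotomised at the top tertile or the median of the
score for survival stratification.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from mascsig.core import GeneSignature, check_matrix

logger = logging.getLogger(__name__)


@dataclass
class ActivationScores:
    """Per-sample signature activation scores.

    ``scores`` is indexed by sample identifier; ``retained_genes`` is the
    subset of the signature actually used; ``method`` is ``"average"`` or
    ``"relevance_network"``.
    """

    scores: pd.Series
    method: str
    retained_genes: list[str]
    params: dict = field(default_factory=dict)


@dataclass
class RelevanceNetwork:
    """Signature-gene correlation graph over a cohort.

    ``edges`` columns: gene_a, gene_b, r, p; ``retained`` is the node
    subset that survived component selection and denoising.
    """

    nodes: list[str]
    edges: pd.DataFrame
    retained: list[str]


def map_signature_ids(signature: GeneSignature,
                      mapping: pd.DataFrame) -> GeneSignature:
    """Translate signature identifiers through a two-column mapping table.

    One-to-many mappings expand; genes without any mapping are dropped and
    counted in the provenance note (e.g. mouse symbols to human Ensembl
    identifiers through a user-supplied orthology table).
    """
    src = mapping.iloc[:, 0].astype(str)
    dst = mapping.iloc[:, 1].astype(str)
    lookup: dict[str, list[str]] = {}
    for s, t in zip(src, dst):
        lookup.setdefault(s, []).append(t)
    out: list[str] = []
    dropped = 0
    for g in signature.genes:
        targets = lookup.get(g)
        if not targets:
            dropped += 1
            continue
        for t in targets:
            if t not in out:
                out.append(t)
    if not out:
        raise ValueError("no signature gene has a mapping; empty result")
    return GeneSignature(
        genes=out,
        provenance=f"{signature.provenance}; mapped {len(out)} ids, "
                   f"{dropped} gene(s) dropped (unmapped)",
    )


def median_centre(matrix: pd.DataFrame) -> pd.DataFrame:
    """Subtract each gene's median across samples (row medians become 0)."""
    check_matrix(matrix)
    return matrix.sub(matrix.median(axis=1), axis=0)


def _present_genes(matrix: pd.DataFrame, signature: GeneSignature) -> list[str]:
    present = [g for g in signature.genes if g in matrix.index]
    missing = len(signature) - len(present)
    if not present:
        raise ValueError("no signature gene present in the matrix")
    if missing:
        logger.warning("%d signature gene(s) absent from matrix, dropped", missing)
    return present


def average_score(matrix: pd.DataFrame, signature: GeneSignature) -> ActivationScores:
    """Median-centred average expression of the signature genes per sample."""
    present = _present_genes(matrix, signature)
    centred = median_centre(matrix)
    scores = centred.loc[present].mean(axis=0)
    return ActivationScores(
        scores=scores.rename("score"),
        method="average",
        retained_genes=present,
        params={"n_signature": len(signature), "n_retained": len(present)},
    )


def relevance_network_score(
    matrix: pd.DataFrame,
    signature: GeneSignature,
    r_threshold: float = 0.3,
    alpha: float = 0.05,
    bonferroni: bool = True,
) -> tuple[ActivationScores, RelevanceNetwork]:
    """Relevance-network activation score.

    Edges connect signature genes whose cohort-wide Pearson correlation is
    positive, above ``r_threshold`` and significant at ``alpha``
    (Bonferroni-corrected over edges by default; positive sign is required
    because every signature gene is an up-gene). The largest connected
    component is retained and genes anti-correlated with the component's
    mean profile are dropped. The score is the mean z-scored expression of
    the retained genes; if fewer than 3 genes survive, the method falls
    back to :func:`average_score` with a warning.
    """
    present = _present_genes(matrix, signature)
    if len(present) < 3:
        raise ValueError("need >= 3 signature genes present in the matrix")
    n_samples = matrix.shape[1]
    if n_samples < 10:
        raise ValueError("need >= 10 samples for correlation estimation")

    sub = matrix.loc[present].to_numpy(dtype=float)
    sds = sub.std(axis=1)
    ok = sds > 0
    genes = [g for g, keep in zip(present, ok) if keep]
    sub = sub[ok]
    m = len(genes)

    corr = np.corrcoef(sub) if m > 1 else np.ones((1, 1))
    n_pairs = m * (m - 1) // 2
    thr_alpha = alpha / n_pairs if (bonferroni and n_pairs) else alpha

    rows = []
    adj_i, adj_j = [], []
    for i in range(m):
        for j in range(i + 1, m):
            r = corr[i, j]
            # two-sided t-test for Pearson r
            if abs(r) >= 1.0:
                p = 0.0
            else:
                t = r * math.sqrt((n_samples - 2) / (1.0 - r * r))
                p = 2.0 * stats.t.sf(abs(t), df=n_samples - 2)
            rows.append((genes[i], genes[j], r, p))
            if r > r_threshold and p < thr_alpha:
                adj_i.append(i)
                adj_j.append(j)
    edges = pd.DataFrame(rows, columns=["gene_a", "gene_b", "r", "p"])

    if adj_i:
        data = np.ones(len(adj_i))
        graph = csr_matrix((data, (adj_i, adj_j)), shape=(m, m))
        n_comp, comp = connected_components(graph, directed=False)
        sizes = np.bincount(comp)
        # largest component; ties broken by smallest label (first-seen order)
        main = int(np.argmax(sizes))
        retained_idx = [i for i in range(m) if comp[i] == main and sizes[comp[i]] > 1]
    else:
        retained_idx = []

    # denoise: drop genes anti-correlated with the component mean profile
    if len(retained_idx) >= 3:
        comp_mean = sub[retained_idx].mean(axis=0)
        keep_idx = [
            i for i in retained_idx
            if np.corrcoef(sub[i], comp_mean)[0, 1] > 0
        ]
    else:
        keep_idx = retained_idx

    network = RelevanceNetwork(
        nodes=list(genes),
        edges=edges,
        retained=[genes[i] for i in keep_idx],
    )

    if len(keep_idx) < 3:
        logger.warning(
            "relevance network retained %d gene(s) (<3); falling back to "
            "median-centred average score", len(keep_idx),
        )
        fallback = average_score(matrix, signature)
        fallback.params.update({"fallback_from": "relevance_network"})
        return fallback, network

    kept = sub[keep_idx]
    z = (kept - kept.mean(axis=1, keepdims=True)) / kept.std(axis=1, keepdims=True)
    scores = pd.Series(z.mean(axis=0), index=matrix.columns, name="score")
    act = ActivationScores(
        scores=scores,
        method="relevance_network",
        retained_genes=network.retained,
        params={
            "r_threshold": r_threshold,
            "alpha": alpha,
            "bonferroni": bonferroni,
            "n_signature": len(signature),
            "n_retained": len(keep_idx),
        },
    )
    return act, network


def dichotomise(scores: pd.Series, method: str = "top_tertile") -> pd.Series:
    """Split samples into "high" / "low" activation groups.

    ``top_tertile``: "high" = score at or above the 66.67th percentile
    (nearest-rank convention, ties join "high"). ``median``: "high" =
    score strictly above the median, ties to "low".
    """
    if scores.nunique() == 1:
        raise ValueError("all scores identical; no split possible")
    n = len(scores)
    if method == "top_tertile":
        if n < 3:
            raise ValueError("top-tertile split needs >= 3 samples")
        # nearest-rank 66.67th percentile: smallest rank whose cumulative
        # fraction reaches 2/3, rounding up when 2n/3 is an integer so that
        # "high" holds about n/3 samples
        rank = (2 * n) // 3 + 1 if (2 * n) % 3 == 0 else math.ceil(2 * n / 3)
        cutoff = np.sort(scores.to_numpy())[rank - 1]
        high = scores >= cutoff
    elif method == "median":
        if n < 2:
            raise ValueError("median split needs >= 2 samples")
        high = scores > scores.median()
    else:
        raise ValueError(f"unknown dichotomisation method: {method!r}")
    return pd.Series(np.where(high, "high", "low"), index=scores.index, name="group")
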
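"""SAM-style permutation differential expression and signature derivation.

The relative-difference statistic is the moderated contrast

    d_g = (mean2_g - mean1_g) / (s_g + s0)

with ``s_g`` the two-sample pooled standard-error term and ``s0`` a small
"fudge factor" chosen, over a percentile grid of the ``s_g`` distribution,
to minimise the coefficient of variation of the d spread across windows of
the ``s_g`` range (Tusher-style tuning). Significance is assessed against
a column-relabelling permutation null: a global tail-area q-value and a
local false-discovery rate estimated from the permuted-to-observed
d-density ratio in a sliding window.

The signature of stem-cell-specific genes is the intersection of genes
up-regulated in the stem-cell population against each of the other
populations at a local FDR below 5% and a linear fold change of at least
1.5; a top subset is further refined at 2.5-fold against both the
myoepithelial and the combined luminal populations.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd

from mascsig.core import GeneSignature, check_matrix

logger = logging.getLogger(__name__)

#: enumerate the permutation null exhaustively when the number of distinct
#: column relabellings is at most this
EXHAUSTIVE_LIMIT = 10_000

#: half-width of the local-FDR density window, as a fraction of the
#: permuted-statistic range
LOCAL_FDR_BANDWIDTH = 0.05


@dataclass
class SamResult:
    """Per-gene SAM statistics for one comparison.

    ``table`` columns: ``d`` (relative difference), ``s`` (pooled SE term),
    ``fold_change`` (linear scale, group2 / group1), ``q_global``,
    ``fdr_local``, ``direction`` (sign of d).
    """

    table: pd.DataFrame
    s0: float
    n_perm: int
    seed: int | None
    groups: tuple[str, ...]

    def significant(self, fdr_max: float = 0.05, fc_min: float | None = None,
                    direction: int | None = None) -> pd.Index:
        """Genes passing the local-FDR gate and optional fold/direction gates."""
        keep = self.table["fdr_local"] < fdr_max
        if fc_min is not None:
            fc = self.table["fold_change"]
            keep &= np.maximum(fc, 1.0 / fc) >= fc_min
        if direction is not None:
            keep &= self.table["direction"] == direction
        return self.table.index[keep]


def load_top_signature_folds() -> pd.DataFrame:
    """Reference fold-change/FDR table for the 69-gene top stem-cell
    signature (versus myoepithelial and combined luminal populations),
    indexed by gene symbol. Columns: fc_myo, fdr_myo_pct, fc_lum,
    fdr_lum_pct."""
    from importlib import resources

    path = resources.files("mascsig") / "data" / "top_signature_folds.tsv"
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t", comment="#", index_col="gene")


def filter_probesets(matrix: pd.DataFrame, mapping: pd.DataFrame) -> pd.DataFrame:
    """Collapse a probeset-level matrix to gene level.

    ``mapping`` has two columns (probeset, gene). Probesets absent from the
    mapping or mapping to more than one gene are removed; when several
    surviving probesets map to one gene, the probeset with the highest mean
    expression represents the gene.
    """
    check_matrix(matrix)
    probes = mapping.iloc[:, 0].astype(str)
    genes = mapping.iloc[:, 1].astype(str)
    per_probe = pd.Series(genes.values, index=probes.values).groupby(level=0).nunique()
    multi = set(per_probe.index[per_probe > 1])
    gene_of = {p: g for p, g in zip(probes, genes) if p not in multi}

    rows, row_genes = [], []
    for p in matrix.index:
        g = gene_of.get(str(p))
        if g is not None:
            rows.append(p)
            row_genes.append(g)
    if not rows:
        raise ValueError(
            "no probesets survive filtering: every row is unmapped or "
            "maps to multiple genes"
        )
    sub = matrix.loc[rows].copy()
    sub.index = pd.Index(row_genes, name="gene")
    means = sub.mean(axis=1)
    # highest-mean probeset represents each gene; stable tie-break by
    # original row order
    order = np.argsort(-means.to_numpy(), kind="stable")
    sub = sub.iloc[order]
    sub = sub[~sub.index.duplicated(keep="first")]
    return sub.sort_index()


def _two_class_stats(values: np.ndarray, mask2: np.ndarray):
    """Numerator r, pooled-SE term s and log2 fold change, vectorised.

    ``mask2`` marks group-2 columns; d is positive when group 2 is higher.
    """
    x1 = values[:, ~mask2]
    x2 = values[:, mask2]
    n1, n2 = x1.shape[1], x2.shape[1]
    m1 = x1.mean(axis=1)
    m2 = x2.mean(axis=1)
    ss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x2 - m2[:, None]) ** 2).sum(axis=1)
    a = (1.0 / n1 + 1.0 / n2) / (n1 + n2 - 2)
    s = np.sqrt(a * ss)
    return m2 - m1, s, m2 - m1


def _multiclass_stats(values: np.ndarray, codes: np.ndarray, k: int):
    """Multiclass numerator r (>= 0) and pooled within-class SE term s."""
    n = values.shape[1]
    counts = np.array([(codes == j).sum() for j in range(k)], dtype=float)
    overall = values.mean(axis=1)
    between = np.zeros(values.shape[0])
    within = np.zeros(values.shape[0])
    means = np.empty((values.shape[0], k))
    for j in range(k):
        xj = values[:, codes == j]
        mj = xj.mean(axis=1)
        means[:, j] = mj
        between += counts[j] * (mj - overall) ** 2
        within += ((xj - mj[:, None]) ** 2).sum(axis=1)
    r = np.sqrt((1.0 / counts).sum() * between)
    s = np.sqrt((1.0 / counts).sum() / (n - k) * within)
    return r, s, means


def _choose_s0(r: np.ndarray, s: np.ndarray) -> float:
    """Fudge factor: the percentile of {s_g} minimising the coefficient of
    variation of the d spread across s-quantile windows.

    Candidates are percentiles 0, 5, ..., 100 of the s distribution. For
    each candidate the genes are split into (up to) 100 equal-occupancy
    windows of s; within each window the median absolute deviation of
    d = r/(s+s0) is taken, and the candidate with the smallest CV of these
    MADs wins. Ties go to the smaller s0.
    """
    order = np.argsort(s, kind="stable")
    r_o, s_o = r[order], s[order]
    n = len(s_o)
    n_win = min(100, max(2, n // 5))
    bounds = np.linspace(0, n, n_win + 1).astype(int)
    candidates = np.percentile(s, np.arange(0, 101, 5))
    best_s0, best_cv = float(candidates[0]), np.inf
    for s0 in candidates:
        d = r_o / (s_o + s0)
        mads = []
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            if hi - lo < 2:
                continue
            w = d[lo:hi]
            mads.append(np.median(np.abs(w - np.median(w))))
        mads = np.asarray(mads)
        mu = mads.mean()
        if mu == 0:
            continue
        cv = mads.std() / mu
        if cv < best_cv - 1e-12:
            best_cv, best_s0 = cv, float(s0)
    return best_s0


def _two_class_permutations(n: int, n2: int, n_perm: int, seed: int | None):
    """Group-2 column index sets for the permutation null.

    Exhaustive over all C(n, n2) distinct relabellings when that count is
    at most ``EXHAUSTIVE_LIMIT``; otherwise ``n_perm`` sampled relabellings
    under the given seed.
    """
    total = math.comb(n, n2)
    if total <= EXHAUSTIVE_LIMIT:
        return [np.array(c) for c in itertools.combinations(range(n), n2)], total
    rng = np.random.default_rng(seed)
    perms = [np.sort(rng.permutation(n)[:n2]) for _ in range(n_perm)]
    return perms, len(perms)


def _pi0(d_obs: np.ndarray, d_perm: np.ndarray) -> float:
    """Null-proportion estimate: observed mass inside the permuted
    interquartile range, divided by 0.5."""
    q25, q75 = np.percentile(d_perm, [25, 75])
    frac = np.mean((d_obs >= q25) & (d_obs <= q75))
    return float(min(1.0, frac / 0.5))


def _tail_q(score_obs: np.ndarray, score_perm: np.ndarray, pi0: float) -> np.ndarray:
    """Permutation tail-area q-values on a one-sided score (larger = more
    significant), monotone in the score.

    The expected false-call count at each threshold is the *median* over
    permutations of the per-permutation exceedance count — the median, not
    the mean, so that the handful of relabellings nearly identical to the
    true labelling (unavoidable at small sample sizes) cannot flood the
    null with genuine signal.
    """
    perm_sorted = np.sort(score_perm, axis=1)
    order = np.argsort(-score_obs, kind="stable")
    q = np.empty_like(score_obs)
    # counts[b, i] = #{d*_b >= thr_i} for thresholds in descending order
    thresholds = score_obs[order]
    counts = perm_sorted.shape[1] - np.stack(
        [np.searchsorted(row, thresholds, side="left") for row in perm_sorted]
    )
    med_false = np.median(counts, axis=0)
    ranks = np.arange(1, len(order) + 1)
    q_sorted = pi0 * med_false / ranks
    # enforce monotone non-decreasing q as the threshold relaxes
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q[order] = q_sorted
    return np.clip(q, 0.0, 1.0)


def _local_fdr(d_obs: np.ndarray, d_perm: np.ndarray, pi0: float,
               bandwidth: float = LOCAL_FDR_BANDWIDTH) -> np.ndarray:
    """Local FDR from the permuted-to-observed d-density ratio.

    Around each gene's d a symmetric interval of half-width
    ``bandwidth * range(d)`` is taken; the local FDR is the null count in
    that interval (median over permutations, scaled by pi0) over the
    observed count, clamped to [0, 1]. The window is symmetric in d — not
    in rank — so a dense cluster of strong genes next to the null bulk is
    not swamped by its neighbours' range.
    """
    lo_all = min(d_obs.min(), d_perm.min())
    hi_all = max(d_obs.max(), d_perm.max())
    h = bandwidth * (hi_all - lo_all)
    if h <= 0:
        return np.ones_like(d_obs)
    obs_sorted = np.sort(d_obs)
    perm_sorted = np.sort(d_perm, axis=1)
    lo_edge = d_obs - h
    hi_edge = d_obs + h
    obs = (np.searchsorted(obs_sorted, hi_edge, side="right")
           - np.searchsorted(obs_sorted, lo_edge, side="left")).astype(float)
    lo_counts = np.stack(
        [np.searchsorted(row, lo_edge, side="left") for row in perm_sorted]
    )
    hi_counts = np.stack(
        [np.searchsorted(row, hi_edge, side="right") for row in perm_sorted]
    )
    null = np.median(hi_counts - lo_counts, axis=0)
    return np.clip(pi0 * null / np.maximum(obs, 1.0), 0.0, 1.0)


def sam_two_class(matrix: pd.DataFrame, groups: pd.Series,
                  n_perm: int = 1000, seed: int | None = 0,
                  s0: float | None = None) -> SamResult:
    """Two-class unpaired SAM.

    ``groups`` maps sample identifier to one of exactly two labels; d is
    positive for genes higher in the second label (sorted label order).
    """
    check_matrix(matrix)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    groups = groups.reindex(matrix.columns)
    if groups.isna().any():
        missing = matrix.columns[groups.isna()].tolist()
        raise ValueError(f"samples without group label: {missing[:5]}")
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two group levels, got {levels}")
    mask2 = (groups == levels[1]).to_numpy()
    n1, n2 = int((~mask2).sum()), int(mask2.sum())
    if min(n1, n2) < 2:
        raise ValueError("each group needs >= 2 samples")

    values = matrix.to_numpy(dtype=float)
    r, s, log2fc = _two_class_stats(values, mask2)
    if s0 is None:
        s0 = _choose_s0(np.abs(r), s)
    d = r / (s + s0)

    perms, n_used = _two_class_permutations(values.shape[1], n2, n_perm, seed)
    d_perm = np.empty((n_used, values.shape[0]))
    for b, idx in enumerate(perms):
        m2 = np.zeros(values.shape[1], dtype=bool)
        m2[idx] = True
        rp, sp, _ = _two_class_stats(values, m2)
        d_perm[b] = rp / (sp + s0)

    pi0 = _pi0(d, d_perm)
    q = _tail_q(np.abs(d), np.abs(d_perm), pi0)
    fdr = _local_fdr(d, d_perm, pi0)

    table = pd.DataFrame(
        {
            "d": d,
            "s": s,
            "fold_change": np.exp2(log2fc),
            "q_global": q,
            "fdr_local": fdr,
            "direction": np.sign(d).astype(int),
        },
        index=matrix.index,
    )
    return SamResult(table=table, s0=float(s0), n_perm=n_used, seed=seed,
                     groups=tuple(levels))


def sam_multiclass(matrix: pd.DataFrame, groups: pd.Series,
                   n_perm: int = 1000, seed: int | None = 0,
                   s0: float | None = None) -> SamResult:
    """Multiclass SAM: does mean expression differ across k >= 3 groups?

    The statistic is the ANOVA-like between-group contrast over the pooled
    within-group SE plus the fudge factor; it is non-negative, so
    ``direction`` is +1 throughout and ``fold_change`` is the maximum
    pairwise ratio between group means.
    """
    check_matrix(matrix)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    groups = groups.reindex(matrix.columns)
    if groups.isna().any():
        missing = matrix.columns[groups.isna()].tolist()
        raise ValueError(f"samples without group label: {missing[:5]}")
    levels = sorted(groups.unique())
    k = len(levels)
    if k < 3:
        raise ValueError(f"multiclass needs >= 3 group levels, got {k}")
    codes = np.array([levels.index(g) for g in groups])
    counts = np.bincount(codes, minlength=k)
    if counts.min() < 2:
        raise ValueError("each group needs >= 2 samples")

    values = matrix.to_numpy(dtype=float)
    r, s, means = _multiclass_stats(values, codes, k)
    if s0 is None:
        s0 = _choose_s0(r, s)
    d = r / (s + s0)

    rng = np.random.default_rng(seed)
    d_perm = np.empty((n_perm, values.shape[0]))
    for b in range(n_perm):
        perm_codes = rng.permutation(codes)
        rp, sp, _ = _multiclass_stats(values, perm_codes, k)
        d_perm[b] = rp / (sp + s0)

    pi0 = _pi0(d, d_perm)
    q = _tail_q(d, d_perm, pi0)
    fdr = _local_fdr(d, d_perm, pi0)

    table = pd.DataFrame(
        {
            "d": d,
            "s": s,
            "fold_change": np.exp2(means.max(axis=1) - means.min(axis=1)),
            "q_global": q,
            "fdr_local": fdr,
            "direction": np.ones(len(d), dtype=int),
        },
        index=matrix.index,
    )
    return SamResult(table=table, s0=float(s0), n_perm=n_perm, seed=seed,
                     groups=tuple(levels))


def derive_signature(comparisons: dict[str, SamResult],
                     fdr_max: float = 0.05, fc_min: float = 1.5) -> GeneSignature | None:
    """Intersect per-comparison up-gene calls into the stem-cell signature.

    ``comparisons`` maps a comparison name (e.g. ``"vs_MYO"``) to a
    two-class :class:`SamResult` in which positive d means up in the
    stem-cell population. A gene enters the signature only if it is up at
    ``fdr_local < fdr_max`` with linear ``fold_change >= fc_min`` in
    *every* comparison. Returns ``None`` (with a warning) if the
    intersection is empty.
    """
    if not comparisons:
        raise ValueError("at least one comparison required")
    gene_sets = []
    for name, res in comparisons.items():
        tab = res.table
        keep = (
            (tab["direction"] > 0)
            & (tab["fdr_local"] < fdr_max)
            & (tab["fold_change"] >= fc_min)
        )
        gene_sets.append(set(tab.index[keep]))
    common = set.intersection(*gene_sets)
    if not common:
        logger.warning("signature intersection is empty")
        return None
    genes = sorted(common)
    return GeneSignature(
        genes=genes,
        provenance=(
            f"up in all of {sorted(comparisons)} at fdr_local<{fdr_max}, "
            f"fold_change>={fc_min}"
        ),
    )


def refine_top_signature(signature: GeneSignature,
                         comparisons: dict[str, SamResult],
                         fc_min: float = 2.5,
                         fdr_max: float = 0.05) -> GeneSignature | None:
    """Refine a signature to its strongest genes.

    Keeps signature genes whose fold change reaches ``fc_min`` in every
    supplied comparison (canonically: versus the myoepithelial population
    and versus the combined luminal populations) at ``fdr_local < fdr_max``.
    The fold gate is inclusive so a gene printed at exactly the threshold
    is retained.
    """
    keep = list(signature.genes)
    for name, res in comparisons.items():
        tab = res.table
        ok = tab.index[
            (tab["direction"] > 0)
            & (tab["fold_change"] >= fc_min)
            & (tab["fdr_local"] < fdr_max)
        ]
        keep = [g for g in keep if g in set(ok)]
    if not keep:
        logger.warning("top-signature refinement removed every gene")
        return None
    return GeneSignature(
        genes=keep,
        provenance=f"{signature.provenance}; refined at fold_change>={fc_min} "
                   f"in {sorted(comparisons)}",
    )


def hierarchical_cluster(matrix: pd.DataFrame):
    """Average-linkage hierarchical clustering of samples on 1 - Pearson r.

    Returns
    -------
    linkage : ndarray
        SciPy linkage matrix over the samples.
    leaves : list of str
        Sample identifiers in dendrogram leaf order.
    cophenetic : DataFrame
        Sample x sample cophenetic distances.
    """
    check_matrix(matrix)
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 samples to cluster")
    values = matrix.to_numpy(dtype=float)
    sds = values.std(axis=0)
    if (sds == 0).any():
        bad = matrix.columns[sds == 0].tolist()
        raise ValueError(f"constant sample profile, correlation undefined: {bad}")
    corr = np.corrcoef(values.T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    condensed = ssd.squareform(dist, checks=False)
    linkage = sch.linkage(condensed, method="average")
    leaves = [matrix.columns[i] for i in sch.leaves_list(linkage)]
    coph = ssd.squareform(sch.cophenet(linkage))
    cophenetic = pd.DataFrame(coph, index=matrix.columns, columns=matrix.columns)
    return linkage, leaves, cophenetic
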
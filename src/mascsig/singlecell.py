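"""Single-cell RT-qPCR processing.

Works on :class:`mascsig.syndata.SingleCellPanel` objects: cells x genes
Ct tables (NaN = undetected) plus spike-control rows at known input copy
numbers.

* :func:`spike_linearity` checks amplification linearity from the spike
  dilution series (Ct versus log10 copies).
* :func:`ddct_quantify` gives relative expression by the delta-delta-Ct
  rule, 2^(-ddCt), against a reference gene or spike and a comparator.
* :func:`inverse_ct` converts to the 1/Ct scale, the monotone expression
  proxy used for heterogeneity and co-expression analysis; undetected
  wells map to 0 (non-amplification read as absence).
* :func:`cv_per_gene`, :func:`cell_correlation_matrix` and
  :func:`coexpression_contingency` quantify cell-to-cell heterogeneity
  and two-gene co-expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from mascsig.syndata import SingleCellPanel

logger = logging.getLogger(__name__)


@dataclass
class SpikeFit:
    """Least-squares fit of spike Ct versus log10 input copies."""

    slope: float  # cycles per tenfold dilution (negative)
    intercept: float  # Ct at 1 copy
    r: float  # Pearson correlation of the fit
    efficiency: float  # 10^(-1/slope) - 1; 1.0 at perfect doubling


@dataclass
class CoexpressionContingency:
    """Two-gene detection contingency over single cells."""

    gene_a: str
    gene_b: str
    double_negative: int
    a_only: int
    b_only: int
    double_positive: int
    n_cells: int

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return (self.double_negative, self.a_only, self.b_only,
                self.double_positive)

    @property
    def percentages(self) -> tuple[float, float, float, float]:
        """Category percentages, one decimal place."""
        return tuple(
            round(100.0 * c / self.n_cells, 1) for c in self.counts
        )


def spike_linearity(panel: SingleCellPanel) -> SpikeFit:
    """Fit Ct against log10(copies) over the spike dilution series.

    At 100% PCR efficiency the slope is -log2(10) = -3.3219 cycles per
    decade.
    """
    spikes = panel.spikes.dropna(subset=["ct"])
    if len(spikes) < 3:
        raise ValueError(
            f"need >= 3 detected spike levels, got {len(spikes)}"
        )
    x = np.log10(spikes["copies"].to_numpy(dtype=float))
    y = spikes["ct"].to_numpy(dtype=float)
    fit = stats.linregress(x, y)
    efficiency = 10.0 ** (-1.0 / fit.slope) - 1.0
    return SpikeFit(slope=float(fit.slope), intercept=float(fit.intercept),
                    r=float(fit.rvalue), efficiency=float(efficiency))


def ddct_quantify(panel: SingleCellPanel, reference: str,
                  comparator: str | None = None) -> pd.DataFrame:
    """Relative expression per gene per cell by the delta-delta-Ct rule.

    ``reference`` is a gene of the panel used for the per-cell delta-Ct.
    ``comparator`` names the baseline cell; if None, the per-gene mean
    delta-Ct over cells where the reference is detected is the baseline.
    Relative expression is 2^(-ddCt); cells with an undetected reference
    are dropped (counted in a log message) and undetected targets
    propagate as missing.
    """
    ct = panel.ct
    if reference not in ct.columns:
        raise ValueError(f"reference {reference!r} not in panel")
    ref = ct[reference]
    usable = ref.notna()
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.warning("reference undetected in %d cell(s); dropped", n_dropped)
    if not usable.any():
        raise ValueError(f"reference {reference!r} undetected in every cell")
    dct = ct.loc[usable].sub(ref.loc[usable], axis=0)
    if comparator is not None:
        if comparator not in dct.index:
            raise ValueError(f"comparator cell {comparator!r} not usable")
        baseline = dct.loc[comparator]
    else:
        baseline = dct.mean(axis=0, skipna=True)
    ddct = dct.sub(baseline, axis=1)
    return np.exp2(-ddct)


def inverse_ct(panel: SingleCellPanel) -> pd.DataFrame:
    """Cells x genes 1/Ct matrix; undetected wells become 0."""
    inv = 1.0 / panel.ct
    return inv.fillna(0.0)


def cv_per_gene(inv_ct: pd.DataFrame) -> pd.Series:
    """Per-gene coefficient of variation of 1/Ct across cells.

    Population SD (n denominator) over the mean; genes with mean 0 are
    undefined (NaN) and flagged in a log message.
    """
    if inv_ct.shape[0] < 2:
        raise ValueError("need >= 2 cells")
    mean = inv_ct.mean(axis=0)
    sd = inv_ct.std(axis=0, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = sd / mean
    undef = mean == 0
    if undef.any():
        logger.warning("CV undefined (mean 0) for: %s",
                       inv_ct.columns[undef].tolist())
        cv[undef] = np.nan
    return cv.rename("cv")


def cell_correlation_matrix(
    inv_ct: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlation between cell profiles.

    Returns (r, p, p_bh): cells x cells matrices of Pearson r, two-sided
    p-values and Benjamini-Hochberg adjusted p-values (adjusted over the
    distinct pairs). Constant cell profiles have undefined correlations
    (NaN) and are flagged.
    """
    if inv_ct.shape[1] < 3:
        raise ValueError("need >= 3 genes for cell-cell correlation")
    cells = inv_ct.index
    x = inv_ct.to_numpy(dtype=float)
    n_genes = x.shape[1]
    sds = x.std(axis=1)
    constant = sds == 0
    if constant.any():
        logger.warning("constant cell profile(s), correlations undefined: %s",
                       cells[constant].tolist())

    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    r[constant, :] = np.nan
    r[:, constant] = np.nan
    np.fill_diagonal(r, 1.0)

    m = len(cells)
    p = np.full((m, m), np.nan)
    np.fill_diagonal(p, 0.0)
    iu = np.triu_indices(m, k=1)
    pvals, keep = [], []
    for a, b in zip(*iu):
        rv = r[a, b]
        if np.isnan(rv):
            continue
        if abs(rv) >= 1.0:
            pv = 0.0
        else:
            t = rv * np.sqrt((n_genes - 2) / (1.0 - rv * rv))
            pv = 2.0 * stats.t.sf(abs(t), df=n_genes - 2)
        p[a, b] = p[b, a] = pv
        pvals.append(pv)
        keep.append((a, b))

    p_bh = np.full((m, m), np.nan)
    np.fill_diagonal(p_bh, 0.0)
    if pvals:
        _, adj, _, _ = multipletests(pvals, method="fdr_bh")
        for (a, b), v in zip(keep, adj):
            p_bh[a, b] = p_bh[b, a] = v

    idx = pd.Index(cells)
    return (pd.DataFrame(r, index=idx, columns=idx),
            pd.DataFrame(p, index=idx, columns=idx),
            pd.DataFrame(p_bh, index=idx, columns=idx))


def coexpression_contingency(inv_ct: pd.DataFrame, gene_a: str, gene_b: str,
                             ct_ceiling: float | None = None,
                             panel: SingleCellPanel | None = None
                             ) -> CoexpressionContingency:
    """Classify cells by joint detection of two genes.

    A gene is "detected" in a cell when its 1/Ct value exceeds 0 (any
    amplification). With ``ct_ceiling`` set (e.g. 40), detection instead
    requires Ct below the ceiling, i.e. 1/Ct > 1/ceiling.
    """
    for g in (gene_a, gene_b):
        if g not in inv_ct.columns:
            raise ValueError(f"gene {g!r} not in panel")
    thr = 0.0 if ct_ceiling is None else 1.0 / ct_ceiling
    a = inv_ct[gene_a] > thr
    b = inv_ct[gene_b] > thr
    return CoexpressionContingency(
        gene_a=gene_a,
        gene_b=gene_b,
        double_negative=int((~a & ~b).sum()),
        a_only=int((a & ~b).sum()),
        b_only=int((~a & b).sum()),
        double_positive=int((a & b).sum()),
        n_cells=len(inv_ct),
    )
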
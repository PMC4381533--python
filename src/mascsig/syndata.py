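"""Synthetic data generators with planted ground truth.

Three generators cover the pipeline's inputs:

* :func:`simulate_populations` — a purified-population microarray design
  (stem-cell, myoepithelial and two luminal populations) with planted
  stem-cell-specific, basal-shared, luminal-specific and null genes.
* :func:`simulate_cohort` — a tumour cohort whose hazard depends on a
  latent signature-activation variable through a proportional-hazards
  link, with independent censoring.
* :func:`simulate_single_cells` — single-cell RT-qPCR Ct panels with
  per-gene detection dropout and exogenous spike transcripts at known
  copy numbers.

All generators are deterministic given their design's ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mascsig.core import GeneSignature

POPULATIONS = ("MaSC", "MYO", "LumERneg", "LumERpos")

#: log2 Ct change per tenfold template dilution at 100% PCR efficiency.
IDEAL_SLOPE = float(np.log2(10.0))  # 3.3219... cycles/decade


@dataclass
class PopulationDesign:
    """Design of the four-population replicate microarray experiment.

    Default replicate counts (7, 3, 3, 3) follow the purified-population
    study design (seven stem-cell and three myoepithelial isolations;
    three replicates per luminal population by convention).

    ``noise_sd`` is the typical per-gene residual SD on the log2 scale;
    per-gene SDs are drawn around it from a scaled inverse-chi-square
    (``var_df`` degrees of freedom) to mimic microarray variance
    heterogeneity.
    """

    n_genes: int = 1000
    n_masc: int = 7
    n_myo: int = 3
    n_lum_erneg: int = 3
    n_lum_erpos: int = 3
    n_masc_up: int = 100
    n_basal_shared: int = 100
    n_luminal_up: int = 100
    effect_masc_up: float = 2.0
    effect_basal_shared: float = 2.0
    effect_luminal_up: float = 2.0
    noise_sd: float = 0.3
    var_df: int = 6
    baseline_mean: float = 7.0
    baseline_sd: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        reps = (self.n_masc, self.n_myo, self.n_lum_erneg, self.n_lum_erpos)
        if any(r < 2 for r in reps):
            raise ValueError(f"each population needs >= 2 replicates, got {reps}")
        planted = self.n_masc_up + self.n_basal_shared + self.n_luminal_up
        if planted > self.n_genes:
            raise ValueError(
                f"planted class counts ({planted}) exceed n_genes ({self.n_genes})"
            )
        for name in ("effect_masc_up", "effect_basal_shared", "effect_luminal_up"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class CohortDesign:
    """Design of a survival cohort with a latent activation variable.

    Each tumour carries a latent activation ``A ~ N(0, 1)``. Signature
    genes load on it linearly (``loading`` per gene); event times follow
    an exponential (or Weibull) baseline with hazard multiplied by
    ``exp(beta * A)``; censoring is independent exponential.
    """

    n_tumours: int = 500
    signature: GeneSignature | None = None
    n_genes: int = 300
    n_signature: int = 30
    beta: float = 0.7
    baseline_hazard: float = 0.02  # events per month
    weibull_shape: float = 1.0  # 1.0 -> exponential baseline
    censoring_rate: float = 0.005  # independent exponential, per month
    loading: float = 1.0
    noise_sd: float = 0.5
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_tumours < 20:
            raise ValueError("n_tumours must be >= 20")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline hazard must be positive")
        if self.weibull_shape <= 0:
            raise ValueError("Weibull shape must be positive")
        if self.censoring_rate < 0:
            raise ValueError("censoring rate must be >= 0")
        if not np.isfinite(self.loading):
            raise ValueError("loading must be finite")
        n_sig = len(self.signature) if self.signature is not None else self.n_signature
        if self.n_genes < n_sig:
            raise ValueError("n_genes must be >= signature size")


@dataclass
class SingleCellDesign:
    """Design of a single-cell RT-qPCR panel with spike-in controls.

    Default spike copy numbers (8400, 900, 90 molecules) correspond to
    serial tenfold dilutions of exogenous control transcripts. Ct values
    are clipped to [10, 40]; dropout is recorded as undetected (NaN in
    memory, "ND" on disk).
    """

    n_cells: int = 32
    genes: tuple[str, ...] = (
        "Cdh5", "Gfra2", "Krt15", "Lgals1", "Lgr5", "Nfatc1",
        "Pdgfb", "Prox1", "Ptprb", "Ptprz1", "Tnc", "Vim",
    )
    mean_ct: dict[str, float] = field(default_factory=dict)
    sd_ct: dict[str, float] = field(default_factory=dict)
    dropout: dict[str, float] = field(default_factory=dict)
    spike_copies: dict[str, float] = field(
        default_factory=lambda: {"LTP4": 8400.0, "LTP6": 900.0, "TIM": 90.0}
    )
    slope: float = IDEAL_SLOPE  # cycles per tenfold dilution
    spike_intercept: float = 35.0  # Ct at 1 copy
    spike_noise_sd: float = 0.0
    default_mean_ct: float = 25.0
    default_sd_ct: float = 2.0
    default_dropout: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene names in panel")
        for g, p in self.dropout.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"dropout probability for {g} outside [0, 1]")
        if any(c <= 0 for c in self.spike_copies.values()):
            raise ValueError("spike copy numbers must be positive")


@dataclass
class SingleCellPanel:
    """Cells x genes Ct table plus spike-control measurements.

    ``ct`` holds numeric Ct values with NaN marking undetected wells.
    ``spikes`` has one row per spike transcript: known input copies and
    measured Ct.
    """

    ct: pd.DataFrame
    spikes: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ct.index.has_duplicates:
            raise ValueError("duplicate cell identifiers")
        if self.ct.columns.has_duplicates:
            raise ValueError("duplicate gene identifiers")
        vals = self.ct.to_numpy(dtype=float)
        detected = vals[np.isfinite(vals)]
        if detected.size and ((detected <= 0) | (detected >= 45)).any():
            raise ValueError("numeric Ct values must lie in (0, 45)")


def _gene_sds(rng: np.random.Generator, n: int, sd: float, df: int) -> np.ndarray:
    """Per-gene SDs from a scaled inverse-chi-square around ``sd``."""
    if sd == 0:
        return np.zeros(n)
    var = sd**2 * df / rng.chisquare(df, size=n)
    return np.sqrt(var)


def simulate_populations(
    design: PopulationDesign,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Simulate the four-population log2 expression matrix.

    Returns
    -------
    matrix : DataFrame
        Genes x samples log2 expression.
    labels : Series
        Population label per sample, index = sample identifiers.
    truth : DataFrame
        Per-gene planted class (``masc_up``, ``basal_shared``,
        ``luminal_up`` or ``null``) and planted log2 effect.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)

    reps = {
        "MaSC": design.n_masc,
        "MYO": design.n_myo,
        "LumERneg": design.n_lum_erneg,
        "LumERpos": design.n_lum_erpos,
    }
    samples, labels = [], []
    for pop in POPULATIONS:
        for i in range(reps[pop]):
            samples.append(f"{pop}_{i + 1}")
            labels.append(pop)
    labels = pd.Series(labels, index=samples, name="population")

    genes = [f"g{i:05d}" for i in range(design.n_genes)]
    classes = np.array(
        ["masc_up"] * design.n_masc_up
        + ["basal_shared"] * design.n_basal_shared
        + ["luminal_up"] * design.n_luminal_up
        + ["null"] * (design.n_genes - design.n_masc_up
                      - design.n_basal_shared - design.n_luminal_up)
    )

    base = rng.normal(design.baseline_mean, design.baseline_sd, size=design.n_genes)
    mean = np.tile(base[:, None], (1, len(samples)))

    is_pop = {p: (labels.to_numpy() == p) for p in POPULATIONS}
    effects = np.zeros(design.n_genes)
    masc_up = classes == "masc_up"
    basal = classes == "basal_shared"
    lum = classes == "luminal_up"
    effects[masc_up] = design.effect_masc_up
    effects[basal] = design.effect_basal_shared
    effects[lum] = design.effect_luminal_up
    mean[np.ix_(masc_up, is_pop["MaSC"])] += design.effect_masc_up
    mean[np.ix_(basal, is_pop["MaSC"] | is_pop["MYO"])] += design.effect_basal_shared
    mean[np.ix_(lum, is_pop["LumERneg"] | is_pop["LumERpos"])] += design.effect_luminal_up

    sds = _gene_sds(rng, design.n_genes, design.noise_sd, design.var_df)
    values = mean + rng.standard_normal(mean.shape) * sds[:, None]

    matrix = pd.DataFrame(values, index=genes, columns=samples)
    truth = pd.DataFrame(
        {"gene_class": classes, "log2_effect": np.where(classes == "null", 0.0, effects)},
        index=genes,
    )
    truth.index.name = "gene"
    return matrix, labels, truth


def simulate_cohort(
    design: CohortDesign,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Simulate a tumour expression cohort with survival outcomes.

    Latent activation ``A_i ~ N(0, 1)`` drives both the expression of
    signature genes (``expr = baseline + loading * A + noise``) and the
    event hazard (``h0 * exp(beta * A)``). Non-signature genes carry no
    signal. Times are reported in months.

    Returns
    -------
    matrix : DataFrame
        Genes x tumours log2 expression.
    survival : DataFrame
        Columns ``time`` (months) and ``event`` (1 = event, 0 = censored),
        index = tumour identifiers.
    activation : Series
        The latent activation per tumour (ground truth).
    """
    design.validate()
    rng = np.random.default_rng(design.seed)

    if design.signature is not None:
        sig_genes = list(design.signature.genes)
    else:
        sig_genes = [f"sig{i:04d}" for i in range(design.n_signature)]
    n_bg = design.n_genes - len(sig_genes)
    genes = sig_genes + [f"bg{i:05d}" for i in range(n_bg)]
    tumours = [f"T{i:04d}" for i in range(design.n_tumours)]

    activation = rng.standard_normal(design.n_tumours)
    base = rng.normal(design.baseline_mean, design.baseline_sd, size=len(genes))
    values = np.tile(base[:, None], (1, design.n_tumours))
    values[: len(sig_genes)] += design.loading * activation[None, :]
    if design.noise_sd > 0:
        values += rng.standard_normal(values.shape) * design.noise_sd

    # Inverse-transform event times: exponential baseline scaled by
    # exp(beta*A); Weibull shape k generalises via U^(1/k) on the
    # integrated hazard.
    u = rng.uniform(size=design.n_tumours)
    scale = design.baseline_hazard * np.exp(design.beta * activation)
    cum = -np.log(u) / scale
    event_time = cum ** (1.0 / design.weibull_shape)
    if design.censoring_rate > 0:
        cens_time = rng.exponential(1.0 / design.censoring_rate, design.n_tumours)
    else:
        cens_time = np.full(design.n_tumours, np.inf)
    time = np.minimum(event_time, cens_time)
    event = (event_time <= cens_time).astype(int)

    matrix = pd.DataFrame(values, index=genes, columns=tumours)
    survival = pd.DataFrame({"time": time, "event": event}, index=tumours)
    survival.index.name = "sample_id"
    return matrix, survival, pd.Series(activation, index=tumours, name="activation")


def simulate_single_cells(design: SingleCellDesign) -> SingleCellPanel:
    """Simulate a single-cell RT-qPCR Ct panel with spike-in controls.

    Spike Cts follow ``intercept - slope * log10(copies)`` plus optional
    Gaussian noise; per-gene Cts are Gaussian around the design means and
    dropped out (undetected, NaN) with the per-gene dropout probability.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)

    cells = [f"cell{i + 1:02d}" for i in range(design.n_cells)]
    ct = np.empty((design.n_cells, len(design.genes)))
    for j, g in enumerate(design.genes):
        mu = design.mean_ct.get(g, design.default_mean_ct)
        sd = design.sd_ct.get(g, design.default_sd_ct)
        p_drop = design.dropout.get(g, design.default_dropout)
        vals = np.clip(rng.normal(mu, sd, design.n_cells), 10.0, 40.0)
        drop = rng.uniform(size=design.n_cells) < p_drop
        vals[drop] = np.nan
        ct[:, j] = vals

    spike_rows = []
    for name, copies in design.spike_copies.items():
        val = design.spike_intercept - design.slope * np.log10(copies)
        if design.spike_noise_sd > 0:
            val += rng.normal(0.0, design.spike_noise_sd)
        spike_rows.append({"spike": name, "copies": copies,
                           "ct": float(np.clip(val, 10.0, 40.0))})
    spikes = pd.DataFrame(spike_rows).set_index("spike")

    panel = SingleCellPanel(
        ct=pd.DataFrame(ct, index=cells, columns=list(design.genes)),
        spikes=spikes,
        metadata={"seed": design.seed, "slope": design.slope,
                  "spike_intercept": design.spike_intercept},
    )
    return panel
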
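import numpy as np
import pandas as pd
import pytest

from mascsig import syndata
from mascsig.core import GeneSignature


@pytest.fixture(scope="session")
def population_data():
    """Default planted four-population design (shared across tests)."""
    design = syndata.PopulationDesign(seed=11)
    return syndata.simulate_populations(design)


@pytest.fixture(scope="session")
def cohort_data():
    """A moderately-powered survival cohort with planted activation."""
    design = syndata.CohortDesign(n_tumours=400, beta=0.9, seed=5,
                                  n_genes=200, n_signature=25)
    return syndata.simulate_cohort(design)


@pytest.fixture()
def small_matrix():
    rng = np.random.default_rng(3)
    genes = [f"g{i}" for i in range(30)]
    samples = [f"s{i}" for i in range(12)]
    return pd.DataFrame(rng.normal(7, 1, (30, 12)), index=genes, columns=samples)


@pytest.fixture()
def toy_signature():
    return GeneSignature(genes=["g0", "g1", "g2", "g3", "g4"])


def figure_like_panel() -> syndata.SingleCellPanel:
    """A 32-cell two-gene detection pattern with counts (2, 7, 3, 20):
    double-negative, Krt15-only, Vim-only, double-positive."""
    cells = [f"cell{i + 1:02d}" for i in range(32)]
    krt15 = np.full(32, np.nan)
    vim = np.full(32, np.nan)
    # 2 double-negative (cells 1-2), 7 Krt15-only (3-9), 3 Vim-only
    # (10-12), 20 double-positive (13-32)
    krt15[2:9] = 24.0
    vim[9:12] = 26.0
    krt15[12:] = 22.0
    vim[12:] = 23.0
    ct = pd.DataFrame({"Krt15": krt15, "Vim": vim}, index=cells)
    spikes = pd.DataFrame(
        {"copies": [8400.0, 900.0, 90.0], "ct": [21.0, 24.2, 27.5]},
        index=pd.Index(["LTP4", "LTP6", "TIM"], name="spike"),
    )
    return syndata.SingleCellPanel(ct=ct, spikes=spikes)


@pytest.fixture()
def coexpression_panel():
    return figure_like_panel()
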
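"""Shared fixtures: hand-built micro-datasets and scaled-down stands."""

import math

import numpy as np
import pytest

from bamboohcb import (CulmRecord, Dataset, PlotRecord, SyntheticConfig,
                       derive_covariates, generate_dataset)


@pytest.fixture
def one_plot_dataset() -> Dataset:
    """One 400 m2 plot, three culms with dbh 10/12/14 cm (hand-checkable)."""
    plot = PlotRecord(plot_id="P1", block_id="A", area_m2=400.0, cd=0.6)
    culms = [
        CulmRecord("A", "P1", "c10", dbh=10.0, h=11.0, hcb=6.0),
        CulmRecord("A", "P1", "c12", dbh=12.0, h=12.5, hcb=7.0),
        CulmRecord("A", "P1", "c14", dbh=14.0, h=14.0, hcb=8.0),
    ]
    return Dataset(blocks=["A"], plots=[plot], culms=culms)


@pytest.fixture
def small_cfg() -> SyntheticConfig:
    """A scaled-down stand (3 blocks x 2 plots, ~12 culms/plot) for fast fits."""
    return SyntheticConfig(
        n_blocks=3,
        plot_allocation=(2, 2, 2),
        measured_fraction=0.115,
        seed=20230330,
    )


@pytest.fixture
def small_stand(small_cfg) -> Dataset:
    return generate_dataset(small_cfg, seed=11)


@pytest.fixture
def study_cfg() -> SyntheticConfig:
    """The default study-scale configuration (38 plots, ~1370 culms)."""
    return SyntheticConfig()


def make_noise_free_stand(beta, cds=(0.45, 0.6, 0.75, 0.85), n_per_plot=12, seed=0):
    """Several plots with distinct canopy densities so all four coefficients
    of the extended logistic are identified; HCB is exactly the model."""
    rng = np.random.default_rng(seed)
    plots, culms = [], []
    for j, cd in enumerate(cds):
        pid = f"P{j + 1}"
        plots.append(PlotRecord(plot_id=pid, block_id="A", cd=cd))
        for k, d in enumerate(rng.uniform(7.0, 14.0, n_per_plot)):
            culms.append(CulmRecord("A", pid, f"c{k}", dbh=float(d),
                                    h=float(2.6 * d ** 0.65)))
    ds = derive_covariates(Dataset(["A"], plots, culms))
    b1, b2, b3, b4 = beta
    cd_of = {p.plot_id: p.cd for p in ds.plots}
    for c in ds.culms:
        x = b1 + b2 * c.dbh + b3 * c.bal + b4 * cd_of[c.plot_id]
        c.hcb = c.h / (1.0 + math.exp(x))
    return ds


def make_noise_free_dataset(beta, cd=0.6, n=12, seed=0, block="A", plot="P1",
                            u1=0.0, u2=0.0):
    """A single plot whose HCB is exactly the logistic model (no residual),
    optionally with known intercept/slope offsets baked in."""
    rng = np.random.default_rng(seed)
    plot_rec = PlotRecord(plot_id=plot, block_id=block, cd=cd)
    culms = [CulmRecord(block, plot, f"c{k}", dbh=float(d), h=float(2.6 * d ** 0.65))
             for k, d in enumerate(rng.uniform(7.0, 14.0, n))]
    ds = derive_covariates(Dataset([block], [plot_rec], culms))
    b1, b2, b3, b4 = beta
    for c in ds.culms:
        x = (b1 + u1) + (b2 + u2) * c.dbh + b3 * c.bal + b4 * cd
        c.hcb = c.h / (1.0 + math.exp(x))
    return ds
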
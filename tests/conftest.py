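"""Shared fixtures: analytic growth-curve fixtures and seeded synthetic panels."""

import numpy as np
import pandas as pd
import pytest

import gcscreen as g

PANEL_SEED = 17


def piecewise_lysis_curve(step: float = 10.0) -> g.GrowthCurve:
    """Piecewise-linear lysis fixture with closed-form GC7 values.

    Rise 0.1 -> 0.8 over t in [0, 100]; linear drop to 0.1 at t = 200;
    flat at 0.1 until t = 300; linear rise to 0.2 at t = 400. Closed form:
    peak_count 1, drop_slope -0.007 OD/min, drop_magnitude 0.7,
    od_at_bottom 0.1, time_peak_to_bottom 100 min, time_bottom_to_rise
    110 min (1.10 x 0.1 = 0.11 crossed at t = 310), AUC(bottom..end) =
    0.1*100 + (0.1+0.2)/2*100 = 25 OD*min.
    """
    t = np.arange(0.0, 400.0 + step, step)
    od = np.piecewise(
        t,
        [t <= 100, (t > 100) & (t <= 200), (t > 200) & (t <= 300), t > 300],
        [
            lambda x: 0.1 + 0.007 * x,
            lambda x: 0.8 - 0.007 * (x - 100),
            lambda x: 0.1,
            lambda x: 0.1 + 0.001 * (x - 300),
        ],
    )
    return g.GrowthCurve(times=t, od=od, sample_id="piecewise", role="infected")


def smooth_lysis_curve(step: float = 10.0) -> g.GrowthCurve:
    """Infinitely smooth sigmoid-based lysis fixture (for grid-density tests)."""
    t = np.arange(0.0, 1441.0, step)
    sig = lambda x: 1.0 / (1.0 + np.exp(-x))
    od = (
        0.15
        + 0.75 * sig((t - 120) / 40)
        - 0.72 * sig((t - 500) / 90)
        + 0.12 * sig((t - 1150) / 50)
    )
    return g.GrowthCurve(times=t, od=od, sample_id="smooth", role="infected")


@pytest.fixture
def piecewise_curve() -> g.GrowthCurve:
    return piecewise_lysis_curve()


@pytest.fixture(scope="session")
def panel() -> g.synthetic.SyntheticPanel:
    """Default 7-archetype x 3-replicate panel at MOI 0.01, low noise."""
    return g.simulate_panel(seed=PANEL_SEED)


@pytest.fixture(scope="session")
def processed(panel):
    curves, prov = g.preprocess_dataset(panel.run, panel.annotations)
    return curves, prov


@pytest.fixture(scope="session")
def curves(processed):
    return processed[0]


@pytest.fixture(scope="session")
def gc7_matrix(curves):
    matrix, excluded = g.extract_dataset(curves)
    assert not excluded
    return matrix


@pytest.fixture(scope="session")
def species(curves, gc7_matrix) -> pd.Series:
    return pd.Series(
        {c.sample_id: c.species for c in curves if c.role == "infected"}
    ).loc[gc7_matrix.values.index]


@pytest.fixture(scope="session")
def standardized(gc7_matrix):
    return g.standardize(gc7_matrix)
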
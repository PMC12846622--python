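"""GC7 feature extraction: peaks, landmarks, closed-form values, invariants."""

import numpy as np
import pandas as pd
import pytest

import gcscreen as g
from gcscreen.gc7 import FEATURE_NAMES

from conftest import smooth_lysis_curve


def _curve(t, od, sid="x"):
    return g.GrowthCurve(np.asarray(t, float), np.asarray(od, float), sid, "infected")


class TestDetectPeaks:
    def test_single_rise_fall_one_peak(self):
        t = np.arange(0, 210, 10.0)
        od = np.concatenate([np.linspace(0.1, 0.8, 11), np.linspace(0.73, 0.1, 10)])
        assert len(g.detect_peaks(_curve(t, od))) == 1

    def test_monotone_increasing_no_peak(self):
        t = np.arange(0, 210, 10.0)
        assert len(g.detect_peaks(_curve(t, np.linspace(0.1, 1.0, 21)))) == 0

    @pytest.mark.parametrize("hump,expected", [(0.05, 2), (0.005, 1)])
    def test_prominence_threshold_straddles_regrowth_hump(self, hump, expected):
        # main lysis peak plus a late hump whose prominence straddles 0.01
        t = np.arange(0, 410, 10.0)
        od = np.piecewise(
            t,
            [t <= 100, (t > 100) & (t <= 200), (t > 200) & (t <= 300), t > 300],
            [
                lambda x: 0.1 + 0.007 * x,
                lambda x: 0.8 - 0.007 * (x - 100),
                lambda x: 0.1 + hump * (x - 200) / 100,
                lambda x: 0.1 + hump * (400 - x) / 100,
            ],
        )
        assert len(g.detect_peaks(_curve(t, od))) == expected


class TestLocateLandmarks:
    def test_bottom_where_gradient_collapses(self, piecewise_curve):
        lm = g.locate_landmarks(piecewise_curve)
        assert lm.peak_time == 100.0
        assert lm.bottom_time == 200.0
        # central-difference gradient on the linear drop
        assert lm.max_negative_slope == pytest.approx(-0.007)

    def test_regrowth_at_110pct_of_bottom(self, piecewise_curve):
        lm = g.locate_landmarks(piecewise_curve)
        # bottom OD 0.1 -> threshold 0.11, crossed at t = 310
        assert lm.regrowth_time == 310.0
        assert not lm.censored

    def test_regrowth_censored_at_run_end(self):
        t = np.arange(0, 410, 10.0)
        od = np.piecewise(
            t,
            [t <= 100, (t > 100) & (t <= 200), t > 200],
            [lambda x: 0.1 + 0.007 * x, lambda x: 0.8 - 0.007 * (x - 100), 0.1],
        )
        lm = g.locate_landmarks(_curve(t, od))
        assert lm.censored
        assert lm.regrowth_time == 400.0

    def test_no_peak_raises_no_lysis(self):
        t = np.arange(0, 210, 10.0)
        with pytest.raises(g.NoLysisError):
            g.locate_landmarks(_curve(t, np.linspace(0.1, 1.0, 21)))

    def test_bottom_search_follows_first_peak_even_if_later_peak_higher(self):
        # first peak 0.5 at t=100, drop to 0.1 at 200, second higher peak
        # 0.9 at t=300, drop to 0.2 at 400
        t = np.arange(0, 410, 10.0)
        od = np.interp(t, [0, 100, 200, 300, 400], [0.1, 0.5, 0.1, 0.9, 0.2])
        lm = g.locate_landmarks(_curve(t, od))
        assert lm.peak_time == 100.0
        assert 100.0 < lm.bottom_time <= 210.0

    def test_fraction_zero_runs_to_gradient_floor(self, piecewise_curve):
        lm = g.locate_landmarks(piecewise_curve, slope_fraction=0.0)
        assert lm.bottom_time >= 200.0  # completes; collapses to zero-gradient point


class TestExtractGC7:
    def test_closed_form_on_piecewise_fixture(self, piecewise_curve):
        f = g.extract_gc7(piecewise_curve)
        assert f.peak_count == 1
        assert f.drop_magnitude == pytest.approx(0.7)
        assert f.drop_slope == pytest.approx(-0.007)
        assert f.od_at_bottom == pytest.approx(0.1)
        assert f.time_peak_to_bottom == pytest.approx(100.0)
        assert f.time_bottom_to_rise == pytest.approx(110.0)
        assert f.auc_bottom_to_end == pytest.approx(25.0)

    def test_flat_curve_signals_no_lysis(self):
        t = np.arange(0, 1441, 10.0)
        with pytest.raises(g.NoLysisError):
            g.extract_gc7(_curve(t, np.full(t.size, 0.5)))

    def test_homogeneity_doubling_od(self, piecewise_curve):
        doubled = piecewise_curve.copy_with(od=piecewise_curve.od * 2)
        f1 = g.extract_gc7(piecewise_curve)
        f2 = g.extract_gc7(doubled)
        for name in ("drop_slope", "drop_magnitude", "od_at_bottom", "auc_bottom_to_end"):
            assert getattr(f2, name) == pytest.approx(2 * getattr(f1, name))
        for name in ("peak_count", "time_peak_to_bottom", "time_bottom_to_rise"):
            assert getattr(f2, name) == getattr(f1, name)

    def test_offset_invariance_and_dependence(self, piecewise_curve):
        shifted = piecewise_curve.copy_with(od=piecewise_curve.od + 0.25)
        f0 = g.extract_gc7(piecewise_curve)
        f1 = g.extract_gc7(shifted)
        for name in ("drop_slope", "drop_magnitude", "time_peak_to_bottom", "peak_count"):
            assert getattr(f1, name) == pytest.approx(getattr(f0, name))
        # absolute-level features must move with the offset
        assert f1.od_at_bottom == pytest.approx(f0.od_at_bottom + 0.25)
        assert f1.auc_bottom_to_end != pytest.approx(f0.auc_bottom_to_end)
        assert f1.time_bottom_to_rise != pytest.approx(f0.time_bottom_to_rise)

    def test_density_doubling_changes_smooth_features_under_2pct(self):
        coarse = g.extract_gc7(smooth_lysis_curve(step=10.0)).as_array()
        fine = g.extract_gc7(smooth_lysis_curve(step=5.0)).as_array()
        rel = np.abs(fine - coarse) / np.abs(coarse)
        assert np.all(rel < 0.02)

    def test_bottom_insensitive_to_fraction_on_piecewise_gradient_step(self, piecewise_curve):
        # on the piecewise-linear drop the gradient is a step function, so
        # the bottom (and hence all features) is identical across fractions
        feats = [
            g.extract_gc7(piecewise_curve, slope_fraction=f).as_array()
            for f in (0.05, 0.10, 0.15)
        ]
        np.testing.assert_allclose(feats[0], feats[1])
        np.testing.assert_allclose(feats[1], feats[2])


class TestStandardize:
    def test_population_zscore(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [0.0, 1.0, 5.0]}, index=list("xyz"))
        z = g.standardize(g.FeatureMatrix(values=df))
        expected = (np.array([1.0, 2.0, 3.0]) - 2.0) / np.sqrt(2.0 / 3.0)
        np.testing.assert_allclose(z.values["a"], expected, atol=1e-12)
        assert abs(z.values["a"].iloc[0]) == pytest.approx(1.2247, abs=1e-4)

    def test_columns_zero_mean_unit_sd(self, standardized):
        vals = standardized.values
        np.testing.assert_allclose(vals.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(vals.std(axis=0, ddof=0), 1.0, atol=1e-9)

    def test_idempotent(self, standardized):
        again = g.standardize(standardized)
        np.testing.assert_allclose(again.values, standardized.values, atol=1e-9)

    def test_zero_variance_column_names_feature(self):
        df = pd.DataFrame({"peak_count": [1.0, 1.0, 1.0], "b": [0.0, 1.0, 2.0]})
        with pytest.raises(ValueError, match="peak_count"):
            g.standardize(g.FeatureMatrix(values=df))

    def test_fit_on_subset_reused_for_all_rows(self):
        df = pd.DataFrame({"a": [0.0, 1.0, 2.0, 10.0]}, index=list("wxyz"))
        z = g.standardize(g.FeatureMatrix(values=df), fit_on=["w", "x", "y"])
        np.testing.assert_allclose(z.values["a"][:3].mean(), 0.0, atol=1e-12)
        assert z.values.loc["z", "a"] > 3  # scaled by the subset's parameters


def test_panel_feature_extraction_recovers_archetype_structure(gc7_matrix, species):
    """Replicates of the same archetype have near-identical feature vectors."""
    df = gc7_matrix.values
    assert list(df.columns) == list(FEATURE_NAMES)
    assert len(df) == 21
    # multi-peak phenotypes are the only ones with 2 detected peaks
    two_peaked = set(species[df["peak_count"] >= 2].unique())
    assert two_peaked == {"P6", "P7"}
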
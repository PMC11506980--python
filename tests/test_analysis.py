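"""Series normalisation, jump detection, growth-law fits and histograms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evochase.analysis import (EpochSeries, compare_models, detect_jumps,
                               fit_model, jump_histograms, normalize_series)
from evochase.synth import Segment, make_synthetic_series, preset


def series_from(df) -> EpochSeries:
    return EpochSeries.from_frame(df)


class TestNormalize:
    def test_ratio_to_maximum(self):
        s = normalize_series([0, 2, 4])
        assert s.K.tolist() == [0.0, 0.5, 1.0]
        assert s.t.tolist() == [1.0, 2.0, 3.0]

    def test_constant_positive_series_all_one(self):
        assert normalize_series([3, 3, 3]).K.tolist() == [1.0, 1.0, 1.0]

    def test_all_zero_series_rejected(self):
        with pytest.raises(ValueError, match="no catches"):
            normalize_series([0, 0, 0])

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.lists(st.integers(0, 10_000), min_size=2, max_size=50)
           .filter(lambda v: max(v) > 0),
           st.integers(1, 1000))
    def test_idempotent_and_scale_invariant(self, raw, c):
        k1 = normalize_series(raw).K
        k2 = normalize_series(np.asarray(raw) * c).K
        k3 = normalize_series(k1).K
        assert np.allclose(k1, k2)
        assert np.allclose(k1, k3)


class TestDetectJumps:
    def test_constant_series_has_no_jumps(self):
        s = series_from(preset("flat"))
        assert detect_jumps(s) == []

    def test_ideal_noiseless_step_located_exactly(self):
        segs = [Segment("const", 1, 2999, (0.1,)),
                Segment("const", 3000, 6000, (0.5,))]
        s = series_from(make_synthetic_series(segs))
        events = detect_jumps(s, window=1)
        assert len(events) == 1
        assert events[0].location == 3000
        assert events[0].magnitude == pytest.approx(0.4, abs=1e-12)

    def test_monotone_ramp_below_threshold_is_not_a_jump(self):
        t = np.arange(1, 5001, dtype=float)
        s = EpochSeries(t, 0.3 + t * 4e-5)  # total rise 0.2, gradual
        assert detect_jumps(s, threshold=0.15) == []

    def test_two_noisy_jumps_recovered(self):
        df = preset("two_step", sigma=0.02, seed=123)
        events = detect_jumps(series_from(df))
        assert len(events) == 2
        assert abs(events[0].location - 1500) <= 101
        assert abs(events[1].location - 6000) <= 101
        assert events[0].magnitude == pytest.approx(0.30, abs=0.05)
        assert events[1].magnitude == pytest.approx(0.40, abs=0.05)


PRINTED_MODELS = [
    # model name, params, generator window
    ("logarithmic", {"a": 0.16, "b": -0.62}, (2981, 10000)),
    ("logarithmic", {"a": 0.05, "b": -0.03}, (1500, 5999)),
    ("logarithmic", {"a": 0.18, "b": -0.36}, (6000, 10000)),
    ("hyperbolic", {"a": 0.86, "b": 666.5}, (1, 10000)),
    ("power", {"c": 0.0001, "d": 0.36}, (1, 10000)),
    ("linear", {"m": 2.6e-6, "q": 0.32}, (1, 10000)),
]


class TestFitModel:
    @pytest.mark.parametrize("model,params,window", PRINTED_MODELS)
    def test_noiseless_exact_recovery(self, model, params, window):
        """Each growth law regenerates its own noiseless data with R^2 = 1
        and parameters recovered to <= 1e-6 relative error."""
        from evochase.analysis import MODELS
        t = np.arange(window[0], window[1] + 1, dtype=float)
        y = MODELS[model](t, *params.values())
        fit = fit_model(EpochSeries(t, y), model)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)
        for name, truth in params.items():
            assert fit.params[name] == pytest.approx(truth, rel=1e-6)

    def test_log_fit_equals_regression_on_ln_t(self):
        rng = np.random.default_rng(0)
        t = np.arange(100, 5000, dtype=float)
        y = 0.2 * np.log(t) - 0.4 + rng.normal(0, 0.05, t.size)
        fit = fit_model(EpochSeries(t, y), "logarithmic")
        a, b = np.polyfit(np.log(t), y, 1)
        assert fit.params["a"] == pytest.approx(a, abs=1e-8)
        assert fit.params["b"] == pytest.approx(b, abs=1e-8)

    def test_r2_self_consistency(self):
        rng = np.random.default_rng(1)
        t = np.arange(1, 3000, dtype=float)
        y = 0.8 * t / (t + 500) + rng.normal(0, 0.02, t.size)
        fit = fit_model(EpochSeries(t, y), "hyperbolic")
        resid = y - fit.predict(t)
        r2 = 1 - resid @ resid / np.sum((y - y.mean()) ** 2)
        assert fit.r2 == pytest.approx(r2, abs=1e-10)

    def test_constant_window_flagged(self):
        t = np.arange(1, 100, dtype=float)
        with pytest.raises(ValueError, match="constant"):
            fit_model(EpochSeries(t, np.full(t.size, 0.5)), "linear")

    def test_linear_slope_standard_error_reported(self):
        df = preset("flat", sigma=0.01, seed=3)
        s = series_from(df)
        fit = fit_model(s, "linear")
        assert np.isfinite(fit.stderr["m"]) and fit.stderr["m"] > 0


class TestCompareModels:
    def test_log_generated_data_ranks_log_first(self):
        """On data generated from the logarithmic law plus small noise, the
        logarithmic model wins the R^2 ranking in >= 90% of replicates."""
        t = np.arange(500, 8000, dtype=float)
        wins = 0
        reps = 20
        for rep in range(reps):
            rng = np.random.default_rng(1000 + rep)
            y = 0.16 * np.log(t) - 0.62 + rng.normal(0, 0.02, t.size)
            comp = compare_models(EpochSeries(t, y))
            wins += comp.best.model == "logarithmic"
        assert wins >= 0.9 * reps

    def test_qualitative_screens(self):
        t = np.arange(1, 4000, dtype=float)
        rng = np.random.default_rng(2)
        y = 0.7 * t / (t + 300) + rng.normal(0, 0.01, t.size)
        comp = compare_models(EpochSeries(t, y))
        by_name = {f.model: f for f in comp.fits}
        assert "horizontal_asymptote" in by_name["hyperbolic"].flags
        assert "defined_at_zero" in by_name["power"].flags
        assert by_name["logarithmic"].flags == ()

    def test_residual_traces_cover_window(self):
        t = np.arange(100, 2000, dtype=float)
        y = 0.1 * np.log(t)
        comp = compare_models(EpochSeries(t, y))
        tt, rr = comp.residual_traces["logarithmic"]
        assert len(tt) == len(t) and np.all(rr >= 0)


class TestJumpHistograms:
    def test_single_event_single_bar(self):
        from evochase.analysis import JumpEvent
        ev = [JumpEvent(1200.0, 0.3, 0.1, 0.4)]
        hloc, hmag = jump_histograms(ev, bins=5)
        assert hloc.heights.sum() == pytest.approx(1.0)
        assert np.count_nonzero(hloc.heights) == 1

    def test_heights_always_sum_to_one(self):
        from evochase.analysis import JumpEvent
        rng = np.random.default_rng(0)
        ev = [JumpEvent(float(l), float(m), 0.0, float(m))
              for l, m in zip(rng.integers(1, 10000, 40),
                              rng.uniform(0.1, 0.6, 40))]
        hloc, hmag = jump_histograms(ev, bins=8)
        assert hloc.heights.sum() == pytest.approx(1.0)
        assert hmag.heights.sum() == pytest.approx(1.0)

    def test_histogram_converges_to_sampling_distribution(self):
        from evochase.analysis import JumpEvent
        rng = np.random.default_rng(1)
        ks = []
        for n in (50, 2000):
            mags = rng.uniform(0.2, 0.4, n)
            ev = [JumpEvent(1.0, float(m), 0.0, float(m)) for m in mags]
            _, hmag = jump_histograms(ev, bins=10, magnitude_range=(0.2, 0.4))
            ks.append(np.abs(hmag.heights - 0.1).max())
        assert ks[1] < ks[0]

    def test_no_events_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            hloc, _ = jump_histograms([])
        assert hloc.heights.sum() == 0
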
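"""Binning, two-segment regression, and breakpoint recovery."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st

from coroflow import (
    Bin,
    BinnedPF,
    LineFit,
    analyze_ramp,
    bin_pressure_flow,
    detect_beats,
    fit_breakpoint,
    fit_line,
    intersect,
    simulate_ramp_segment,
)
from coroflow.autoregulation import AutoregulationWarning
from coroflow.recover import breakpoint_recovery_study
from _helpers import make_beats


def make_bins(pressures, flows, counts=None):
    """Bins from sorted pressures; edges indexed so they are always unique."""
    counts = counts or [1] * len(pressures)
    return BinnedPF([
        Bin(lower_edge=5.0 * i, center=5.0 * i + 2.5,
            mean_pressure=float(p), mean_flow=float(f), count=int(c))
        for i, (p, f, c) in enumerate(zip(pressures, flows, counts))
    ])


def two_line_bins(knot=50.0, plateau_flow=20.0, ischemic_slope=0.5,
                  zero_flow_p=10.0, lo=12.5, hi=77.5):
    """Noise-free bins from a plateau and an ischemic line meeting at the knot."""
    pressures = np.arange(lo, hi + 1, 5.0)
    flows = np.where(pressures >= knot, plateau_flow,
                     ischemic_slope * (pressures - zero_flow_p))
    return make_bins(pressures, flows)


class TestBinning:
    def test_singleton_beat(self):
        binned = bin_pressure_flow(make_beats([20.0], pressures=[50.0]))
        (b,) = binned.bins
        assert (b.lower_edge, b.mean_pressure, b.mean_flow, b.count) == (50.0, 50.0, 20.0, 1)

    def test_hand_computed_bins(self):
        binned = bin_pressure_flow(
            make_beats([10.0, 12.0, 20.0], pressures=[41.0, 43.0, 47.0]), 5.0
        )
        first, second = binned.bins
        assert first.lower_edge == 40.0
        assert first.mean_pressure == pytest.approx(42.0)
        assert first.mean_flow == pytest.approx(11.0)
        assert first.count == 2
        assert second.lower_edge == 45.0
        assert (second.mean_pressure, second.mean_flow, second.count) == (47.0, 20.0, 1)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            bin_pressure_flow(make_beats([]))

    @given(st.lists(
        st.tuples(st.floats(1.0, 120.0), st.floats(0.0, 80.0)),
        min_size=1, max_size=60,
    ))
    def test_conservation_of_count_and_mean(self, coords):
        pressures = [p for p, _ in coords]
        flows = [f for _, f in coords]
        binned = bin_pressure_flow(make_beats(flows, pressures=pressures))
        assert binned.total_count == len(coords)
        weighted = float((binned.flows * binned.counts).sum() / binned.counts.sum())
        assert weighted == pytest.approx(np.mean(flows), rel=1e-9, abs=1e-9)


class TestFitLine:
    def test_exact_collinear(self):
        fit = fit_line(make_bins([40, 50, 60], [10, 20, 30]))
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(-30.0)
        assert fit.r_squared == 1.0

    def test_horizontal_line_perfect_by_convention(self):
        fit = fit_line(make_bins([50, 55, 60], [20.0, 20.0, 20.0]))
        assert fit.slope == pytest.approx(0.0)
        assert fit.intercept == pytest.approx(20.0)
        assert fit.r_squared == 1.0

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            x = np.sort(rng.uniform(20, 100, rng.integers(3, 15)))
            y = rng.uniform(0, 60, x.size)
            fit = fit_line(make_bins(x, y))
            # closed-form normal equations, independent of the implementation
            X = np.column_stack([x, np.ones_like(x)])
            slope, intercept = np.linalg.solve(X.T @ X, X.T @ y)
            assert fit.slope == pytest.approx(slope, abs=1e-9)
            assert fit.intercept == pytest.approx(intercept, abs=1e-9)

    def test_matches_statsmodels_r_squared(self):
        statsmodels_api = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(7)
        x = np.sort(rng.uniform(20, 100, 10))
        y = 0.3 * x + rng.normal(0, 2, 10)
        fit = fit_line(make_bins(x, y))
        model = statsmodels_api.OLS(y, statsmodels_api.add_constant(x)).fit()
        assert fit.r_squared == pytest.approx(model.rsquared, abs=1e-9)
        assert fit.slope == pytest.approx(model.params[1], abs=1e-9)

    def test_too_few_or_degenerate_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            fit_line(make_bins([40, 50], [10, 20]))
        degenerate = BinnedPF([
            Bin(40.0 + 5 * i, 42.5 + 5 * i, 47.0, float(f), 1)
            for i, f in enumerate((1.0, 2.0, 3.0))
        ])  # distinct bins, identical abscissa
        with pytest.raises(ValueError, match="abscissa"):
            fit_line(degenerate)


class TestIntersect:
    def test_hand_algebra(self):
        plateau = LineFit(0.0, 20.0, 1.0, 3)
        ischemic = LineFit(0.5, -5.0, 1.0, 3)
        p, f = intersect(ischemic, plateau)
        assert (p, f) == (pytest.approx(50.0), pytest.approx(20.0))

    def test_point_satisfies_both_lines(self):
        a = LineFit(0.45, -3.1, 0.99, 5)
        b = LineFit(0.02, 18.0, 0.5, 6)
        p, f = intersect(a, b)
        assert abs(a.predict(p) - f) < 1e-9
        assert abs(b.predict(p) - f) < 1e-9

    def test_parallel_lines_rejected(self):
        line = LineFit(0.5, -5.0, 1.0, 3)
        with pytest.raises(ValueError, match="parallel"):
            intersect(line, LineFit(0.5, 3.0, 1.0, 3))


class TestFitBreakpoint:
    def test_exact_recovery_on_two_line_data(self):
        fit = fit_breakpoint(two_line_bins())
        assert fit.breakpoint_pressure == pytest.approx(50.0, abs=1e-9)
        assert fit.breakpoint_flow == pytest.approx(20.0, abs=1e-9)
        assert fit.ischemic.r_squared == 1.0
        assert fit.plateau.r_squared == 1.0
        assert fit.score == 1.0
        assert fit.in_range

    def test_breakpoint_satisfies_both_line_equations(self):
        fit = fit_breakpoint(two_line_bins(knot=45.0, ischemic_slope=0.6))
        assert abs(fit.ischemic.predict(fit.breakpoint_pressure) - fit.breakpoint_flow) < 1e-9
        assert abs(fit.plateau.predict(fit.breakpoint_pressure) - fit.breakpoint_flow) < 1e-9

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(60):
            n = int(rng.integers(6, 31))
            x = np.sort(rng.uniform(10, 100, n))
            x += np.arange(n) * 1e-3  # ensure distinct
            y = rng.uniform(0, 50, n)
            binned = make_bins(x, y)
            fit = fit_breakpoint(binned)
            # independent brute force: least pooled SSE over all splits
            best_split, best_sse = None, np.inf
            for split in range(3, n - 2):
                sse = 0.0
                for seg in (slice(None, split), slice(split, None)):
                    c = np.polyfit(x[seg], y[seg], 1)
                    sse += float(((y[seg] - np.polyval(c, x[seg])) ** 2).sum())
                if sse < best_sse - 1e-12:
                    best_split, best_sse = split, sse
            assert fit.split_index == best_split
            sst = float(((y - y.mean()) ** 2).sum())
            assert fit.score == pytest.approx(1.0 - best_sse / sst, abs=1e-9)

    def test_beat_order_invariance(self):
        """Binning + fitting gives the same answer however beats are ordered."""
        rng = np.random.default_rng(9)
        pressures = np.linspace(20, 90, 40)
        flows = np.where(pressures >= 50, 20.0, 0.5 * (pressures - 10))
        flows = flows + rng.normal(0, 0.3, flows.size)
        order = rng.permutation(40)
        fit_a = fit_breakpoint(bin_pressure_flow(
            make_beats(flows.clip(0.1), pressures=pressures)))
        fit_b = fit_breakpoint(bin_pressure_flow(
            make_beats(flows.clip(0.1)[order], pressures=pressures[order])))
        assert fit_a.breakpoint_pressure == fit_b.breakpoint_pressure
        assert fit_a.split_index == fit_b.split_index

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError, match="at least 6 bins"):
            fit_breakpoint(make_bins([10, 20, 30, 40, 50], [1, 2, 3, 4, 5]))


class TestAnalyzeRamp:
    def test_default_simulation_recovers_breakpoint(self, config):
        rec = simulate_ramp_segment(config)
        series = detect_beats(rec, config.heart_rate)
        fit = analyze_ramp(series, rec.annotations[0])
        assert fit.breakpoint_pressure == pytest.approx(config.breakpoint_pressure, abs=2.5)
        assert fit.in_range

    def test_noise_free_simulation_recovers_knot_closely(self, noise_free_config):
        cfg = dataclasses.replace(noise_free_config, breakpoint_pressure=50.0)
        rec = simulate_ramp_segment(cfg)
        series = detect_beats(rec, cfg.heart_rate)
        fit = analyze_ramp(series, rec.annotations[0])
        # template averaging leaves sub-0.2 mmHg residue on beat means
        assert fit.breakpoint_pressure == pytest.approx(50.0, abs=0.3)

    def test_monotone_ischemic_limb(self, config):
        rec = simulate_ramp_segment(config)
        series = detect_beats(rec, config.heart_rate)
        fit = analyze_ramp(series, rec.annotations[0])
        assert fit.ischemic.slope > 0
        assert abs(fit.plateau.slope) < abs(fit.ischemic.slope)

    def test_window_without_ischemic_beats_fails(self, config):
        rec = simulate_ramp_segment(config)
        series = detect_beats(rec, config.heart_rate)
        # only the first quarter of the ramp: pressure never crosses the knot
        with pytest.raises(ValueError):
            analyze_ramp(series, rec.annotations[0], end_s=config.ramp_duration / 4)

    def test_out_of_range_breakpoint_warns(self):
        # two nearly-parallel noisy lines whose intersection lies far away
        rng = np.random.default_rng(3)
        pressures = np.arange(22.5, 92.5, 5.0)
        flows = 0.30 * pressures + rng.normal(0, 0.8, pressures.size)
        series = make_beats(flows.clip(0.1), pressures=pressures)
        from coroflow import Annotation
        ann = Annotation("ramp_start", 0.0, len(series) * 0.7)
        with pytest.warns(AutoregulationWarning):
            fit = analyze_ramp(series, ann)
        assert not fit.in_range


class TestRecoveryStudy:
    def test_small_monte_carlo_recovery(self):
        study = breakpoint_recovery_study(n=20, seed=5)
        assert study["median_abs_error_mmhg"] <= 2.5
        assert study["in_range_fraction"] >= 0.95


def test_breakpoint_plot_export(tmp_path):
    from coroflow.plotting import plot_breakpoint
    fit = fit_breakpoint(two_line_bins())
    out = tmp_path / "curve.png"
    plot_breakpoint(fit, out)
    assert out.stat().st_size > 0
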
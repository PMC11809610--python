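"""Tests for confocal photobleaching-step analysis."""

import itertools

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from oligoquant.pbsa import (
    BleachTrace,
    OverviewImage,
    crowding_metrics,
    detect_spots,
    expected_conditional_steps,
    integrated_counts,
    kv_step_fit,
    min_step_size,
    sic_score,
    simulate_bleach_trace,
    steps_counts_regression,
)


def exhaustive_sic(counts, min_step, max_k=2):
    """Independent oracle: exhaustive SIC minimization over <=2 change
    points, followed by the same sub-threshold merge rule."""
    n = counts.size
    best = (sic_score(counts, np.array([], int)), ())
    for k in range(1, max_k + 1):
        for cps in itertools.combinations(range(1, n), k):
            s = sic_score(counts, np.array(cps, int))
            if s < best[0] - 1e-12:
                best = (s, cps)
    cps = np.array(sorted(best[1]), int)
    while cps.size:
        edges = np.concatenate(([0], cps, [n]))
        levels = np.array([counts[a:b].mean() for a, b in zip(edges[:-1], edges[1:])])
        diffs = np.abs(np.diff(levels))
        if diffs.min() >= min_step:
            break
        cps = np.delete(cps, int(np.argmin(diffs)))
    return tuple(cps)


def bleaching_instance(rng, max_steps=2):
    n = int(rng.integers(24, 65))
    k = int(rng.integers(0, max_steps + 1))
    cps = (
        np.sort(rng.choice(np.arange(4, n - 3), size=k, replace=False))
        if k
        else np.array([], int)
    )
    edges = np.concatenate(([0], cps, [n]))
    level = np.empty(n)
    for i, (a, b) in enumerate(zip(edges[:-1], edges[1:])):
        level[a:b] = 10 + (k - i) * 100
    return rng.poisson(level).astype(float), cps


class TestSpotDetection:
    def blob(self, shape, center, amplitude=20.0, sigma=2.0):
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        return amplitude * np.exp(
            -((yy - center[0]) ** 2 + (xx - center[1]) ** 2) / (2 * sigma**2)
        )

    def test_flat_zero_image_has_no_spots(self):
        img = OverviewImage(np.zeros((50, 50), int))
        assert detect_spots(img).shape == (0, 2)

    def test_single_blob_detected_at_maximum(self):
        img = OverviewImage(np.round(self.blob((64, 64), (30, 33))).astype(int))
        spots = detect_spots(img)
        assert spots.shape == (1, 2)
        assert tuple(spots[0]) == (30, 33)

    @pytest.mark.parametrize(
        "separation_nm,expected", [(300, 0), (600, 2)]
    )
    def test_neighbor_exclusion_rule(self, separation_nm, expected):
        # two blobs closer than 450 nm are both dropped (50 nm pixels)
        sep_px = separation_nm // 50
        field = self.blob((64, 64), (20, 20)) + self.blob((64, 64), (20, 20 + sep_px))
        img = OverviewImage(np.round(field).astype(int), pixel_size_nm=50.0)
        assert detect_spots(img).shape[0] == expected

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            OverviewImage(np.empty((0, 0)))


class TestMinStepSize:
    def test_reference_power_gives_50_counts_10khz(self):
        counts = min_step_size(1.36)
        assert counts == pytest.approx(50.0)
        assert counts / 5e-3 == pytest.approx(10_000.0)  # 10 kHz

    def test_linear_homogeneous_in_power(self):
        assert min_step_size(2.72) == pytest.approx(100.0)
        assert min_step_size(0.0) == 0.0
        p = np.array([0.5, 1.0, 2.0])
        vals = np.array([min_step_size(x) for x in p])
        np.testing.assert_allclose(vals / p, vals[1], rtol=1e-12)


class TestKVStepFit:
    def test_noiseless_two_step_trace(self):
        trace = np.concatenate([np.full(20, 100.0), np.full(20, 50.0), np.full(20, 0.0)])
        fit = kv_step_fit(trace, min_step=10.0)
        assert fit.n_steps == 2
        np.testing.assert_array_equal(fit.change_points, [20, 40])
        np.testing.assert_allclose(fit.levels, [100.0, 50.0, 0.0])

    def test_subthreshold_step_rejected(self):
        trace = np.concatenate([np.full(30, 80.0), np.full(30, 50.0)])
        fit = kv_step_fit(trace, min_step=50.0)
        assert fit.n_steps == 0

    def test_matches_exhaustive_sic_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(40):
            counts, _ = bleaching_instance(rng)
            fit = kv_step_fit(counts, min_step=50.0)
            assert tuple(fit.change_points) == exhaustive_sic(counts, 50.0)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            kv_step_fit(np.array([1.0, 2.0, 3.0]), 10.0)

    def test_upward_transitions_reported_not_counted(self):
        trace = np.concatenate(
            [np.full(20, 100.0), np.full(20, 0.0), np.full(20, 100.0), np.full(20, 0.0)]
        )
        fit = kv_step_fit(trace, min_step=10.0)
        assert fit.n_steps == 2
        assert fit.n_upward == 1


class TestIntegratedCounts:
    def test_background_only_trace_gives_zero(self):
        trace = np.full(40, 5.0)
        fit = kv_step_fit(trace, min_step=10.0)
        assert integrated_counts(trace, fit) == 0.0

    def test_rectangular_pulse_counts(self):
        trace = np.concatenate([np.full(10, 100.0), np.zeros(30)])
        fit = kv_step_fit(trace, min_step=10.0)
        assert integrated_counts(trace, fit) == pytest.approx(1000.0)

    def test_monotone_in_brightness(self):
        vals = []
        for b in [50.0, 100.0, 200.0]:
            trace = np.concatenate([np.full(10, b), np.zeros(30)])
            fit = kv_step_fit(trace, min_step=10.0)
            vals.append(integrated_counts(trace, fit))
        assert vals == sorted(vals)


class TestStepsCountsRegression:
    def test_exact_line(self):
        slope, intercept = steps_counts_regression(
            np.array([1, 2, 3]), np.array([2000.0, 4000.0, 6000.0])
        )
        assert slope == pytest.approx(2000.0)
        assert intercept == pytest.approx(0.0, abs=1e-6)

    def test_matches_numeric_tls_oracle(self):
        rng = np.random.default_rng(3)
        n_steps = rng.integers(1, 5, 400)
        n_ph = 2100.0 * n_steps + 500 + rng.normal(0, 300, 400)
        slope, intercept = steps_counts_regression(n_steps, n_ph)

        # oracle: minimize weighted orthogonal distances over the line angle
        xs, ys, ws = [], [], []
        for v in np.unique(n_steps):
            sel = n_steps == v
            xs.append(v)
            ys.append(n_ph[sel].mean())
            ws.append(sel.sum())
        x, y, w = map(np.asarray, (xs, ys, ws))

        def cost(b):
            a = np.average(y, weights=w) - b * np.average(x, weights=w)
            return np.sum(w * (y - a - b * x) ** 2) / (1 + b**2)

        res = minimize_scalar(cost, bounds=(100.0, 50_000.0), method="bounded")
        slope_oracle = res.x
        assert slope == pytest.approx(slope_oracle, rel=1e-6)

    def test_single_step_value_rejected(self):
        with pytest.raises(ValueError):
            steps_counts_regression(np.array([2, 2, 2]), np.array([1.0, 2.0, 3.0]))


class TestCrowding:
    def test_conditional_expectation_values(self):
        assert expected_conditional_steps(1, 0.3) == pytest.approx(1.0)
        assert expected_conditional_steps(2, 0.8) == pytest.approx(1.6 / 0.96)
        assert expected_conditional_steps(2, 1.0) == pytest.approx(2.0)

    def test_invalid_maturation_rejected(self):
        with pytest.raises(ValueError):
            expected_conditional_steps(2, 0.0)

    def test_reference_crowding_factor(self):
        report = crowding_metrics(1.33, 1.92, eta=0.8)
        assert report.ratio_monomer == pytest.approx(1.33)
        assert report.ratio_dimer == pytest.approx(1.152, abs=1e-3)
        assert report.k_crowd == pytest.approx(1.24, abs=0.005)
        assert report.f_no_crowd is None

    def test_ideal_inputs_give_unity(self):
        assert crowding_metrics(1.0, 1.6 / 0.96, eta=0.8).k_crowd == pytest.approx(1.0)
        assert crowding_metrics(1.0, 2.0, eta=1.0).k_crowd == pytest.approx(1.0)

    def test_subunity_crowding_warns(self):
        with pytest.warns(UserWarning):
            crowding_metrics(0.8, 1.2, eta=0.8)


class TestSimulatedTraces:
    def test_zero_maturation_gives_pure_background(self):
        trace = simulate_bleach_trace(
            3, brightness=100.0, bleach_rate_per_bin=0.05, background=5.0, eta=0.0,
            rng=1,
        )
        assert trace.counts.mean() == pytest.approx(5.0, rel=0.2)

    def test_noiseless_trace_has_n_steps(self):
        trace = simulate_bleach_trace(
            3, brightness=100.0, bleach_rate_per_bin=0.02, eta=1.0, rng=2,
            poisson=False,
        )
        fit = kv_step_fit(trace, min_step=50.0)
        assert fit.n_steps == 3

    def test_ensemble_initial_level(self):
        rng = np.random.default_rng(3)
        levels = [
            simulate_bleach_trace(
                2, 100.0, 0.005, background=10.0, eta=0.8, n_bins=20, rng=rng
            ).counts[0]
            for _ in range(800)
        ]
        assert np.mean(levels) == pytest.approx(2 * 0.8 * 100 + 10, rel=0.05)

    def test_seed_reproducibility(self):
        a = simulate_bleach_trace(2, 100.0, 0.02, eta=0.8, rng=42)
        b = simulate_bleach_trace(2, 100.0, 0.02, eta=0.8, rng=42)
        np.testing.assert_array_equal(a.counts, b.counts)


class TestPopulationOrdering:
    def simulate_population(self, n_fluor, co_loc_prob, rng, n_traces=120):
        """Monomer/pseudo-dimer spots; with probability co_loc_prob a second
        independent molecule sits in the same confocal spot (crowding)."""
        steps = []
        for _ in range(n_traces):
            n = n_fluor + (n_fluor if rng.random() < co_loc_prob else 0)
            trace = simulate_bleach_trace(
                n, brightness=120.0, bleach_rate_per_bin=0.02, background=10.0,
                eta=0.8, n_bins=200, rng=rng,
            )
            fit = kv_step_fit(trace, min_step=50.0)
            if fit.n_steps > 0:
                steps.append(fit.n_steps)
        return np.mean(steps)

    def test_dimer_exceeds_monomer_and_crowding_raises_steps(self):
        rng = np.random.default_rng(9)
        mono = self.simulate_population(1, 0.2, rng)
        dimer = self.simulate_population(2, 0.2, rng)
        mono_ideal = self.simulate_population(1, 0.0, rng)
        assert dimer > mono
        assert mono > mono_ideal
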
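import numpy as np
import pytest

from gazeseg import (
    ConstrainedFit,
    GazeTrace,
    ScenarioParams,
    SegmentationConfig,
    estimate_noise,
    refit_continuous,
    segment_gaze,
    segment_signal,
    simulate_recording,
)
from gazeseg.segment import PRUNE_MARGIN, _forward_pass

from reference import constrained_ls_piecewise, unpruned_greedy_dp


def _two_piece_trace(n1=100, n2=100, rate=100.0, slope2=0.4):
    """Noiseless corner: flat then rising at slope2 deg per sample-time."""
    n = n1 + n2
    t = np.arange(n) / rate
    x = np.where(np.arange(n) < n1, 0.0, slope2 * (t - t[n1]))
    y = np.zeros(n)
    return GazeTrace(t, x, y), n1


class TestConstrainedFit:
    def test_collinear_through_constraint(self):
        f = ConstrainedFit(0.0, 0.0)
        for t, v in ((1, 2), (2, 4), (3, 6)):
            f.update(t, v)
        slope, sse = f.eval()
        assert slope == pytest.approx(2.0)
        assert sse == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_example(self):
        f = ConstrainedFit(0.0, 0.0)
        f.update(1.0, 1.0)
        f.update(2.0, 0.0)
        slope, sse = f.eval()
        assert slope == pytest.approx(0.2)
        assert sse == pytest.approx(0.8)

    def test_matches_brute_force_minimisation(self, rng):
        t0, v0 = 1.5, -0.3
        ts = rng.uniform(2, 5, 12)
        vs = rng.normal(0, 1, 12)
        f = ConstrainedFit(t0, v0)
        for t, v in zip(ts, vs):
            f.update(t, v)
        slope, sse = f.eval()
        bs = np.linspace(slope - 1, slope + 1, 20001)
        sses = ((vs[None, :] - (v0 + bs[:, None] * (ts[None, :] - t0))) ** 2).sum(axis=1)
        assert sse <= sses.min() + 1e-9
        assert abs(bs[np.argmin(sses)] - slope) < 2e-4

    def test_incremental_equals_batch(self, rng):
        ts = np.sort(rng.uniform(0, 10, 50))
        vs = rng.normal(0, 2, 50)
        inc = ConstrainedFit(0.0, 0.5)
        results = []
        for t, v in zip(ts, vs):
            inc.update(t, v)
            results.append(inc.eval())
        batch = ConstrainedFit(0.0, 0.5)
        for t, v in zip(ts, vs):
            batch.update(t, v)
        assert results[-1][0] == pytest.approx(batch.eval()[0], abs=1e-10)
        assert results[-1][1] == pytest.approx(batch.eval()[1], abs=1e-10)

    def test_all_times_at_constraint(self):
        f = ConstrainedFit(1.0, 2.0)
        f.update(1.0, 3.0)
        f.update(1.0, 4.0)
        slope, sse = f.eval()
        assert slope == 0.0
        assert sse == pytest.approx(1.0 + 4.0)


class TestSegmentSignal:
    def test_exact_two_piece_recovery(self):
        tr, corner = _two_piece_trace(slope2=0.4)  # 40 deg/s at 100 Hz
        seg = segment_signal(tr, SegmentationConfig(sigma=0.1, penalty=6.0))
        assert seg.n_segments == 2
        assert seg.breakpoints[1] == corner
        rec = seg.reconstruct(tr.t)
        assert np.sum((rec[:, 0] - tr.x) ** 2) < 1e-16

    def test_no_spurious_splits_on_constant_noise(self):
        # matched sigma, automatic (table) penalty
        n, rate = 250, 500.0
        for seed in range(10):
            r = np.random.default_rng(seed)
            tr = GazeTrace(np.arange(n) / rate, r.normal(0, 0.5, n), r.normal(0, 0.5, n))
            seg = segment_gaze(tr, SegmentationConfig(sigma=0.5, penalty="auto"))
            assert seg.n_segments == 1, f"seed {seed}: {seg.n_segments} segments"

    def test_pruned_equals_unpruned_reference(self, rng):
        for trial in range(40):
            n = int(rng.integers(10, 150))
            t = np.cumsum(rng.uniform(0.5, 1.5, n))
            t -= t[0]
            x = rng.normal(0, 1, n)
            y = rng.normal(0, 1, n)
            penalty = float(rng.uniform(2, 30))
            bps, obj = _forward_pass(t, x, y, 0.5, penalty, 2, True, PRUNE_MARGIN, 500)
            ref_bps, ref_obj = unpruned_greedy_dp(t, x, y, 0.5, penalty)
            np.testing.assert_array_equal(bps, ref_bps)
            assert obj == pytest.approx(ref_obj, rel=1e-9, abs=1e-9)

    def test_short_trace_yields_single_segment(self):
        tr = GazeTrace([0, 0.01, 0.02], [0, 5, 0], [0, 0, 0])
        seg = segment_signal(tr, SegmentationConfig(sigma=0.5, penalty=1.0))
        assert seg.n_segments == 1

    def test_penalty_monotonicity(self, short_recording):
        tr = short_recording.measured
        counts = []
        for pen in (1.0, 3.0, 10.0, 30.0, 100.0):
            seg = segment_signal(tr, SegmentationConfig(sigma=0.5, penalty=pen))
            counts.append(seg.n_segments)
        assert counts == sorted(counts, reverse=True)

    def test_scale_invariance(self, short_recording):
        tr = short_recording.measured
        c = 7.3
        scaled = GazeTrace(tr.t, c * tr.x, c * tr.y)
        a = segment_signal(tr, SegmentationConfig(sigma=0.5, penalty=8.0))
        b = segment_signal(scaled, SegmentationConfig(sigma=0.5 * c, penalty=8.0))
        np.testing.assert_array_equal(a.breakpoints, b.breakpoints)

    def test_reconstruction_continuity_is_exact(self, short_recording):
        seg = segment_signal(short_recording.measured,
                             SegmentationConfig(sigma=0.5, penalty=6.0))
        # interior nodes are shared by adjacent segments: evaluating the
        # reconstruction at node times must return the node values exactly
        rec = seg.reconstruct(seg.node_times)
        np.testing.assert_array_equal(rec, seg.node_values)

    def test_denoises_across_noise_levels(self):
        for sigma in (0.3, 3.0):
            sim = simulate_recording(ScenarioParams(duration=10.0, sigma=sigma,
                                                    out_rate=500.0, seed=13))
            seg = segment_signal(sim.measured, SegmentationConfig(sigma=sigma, penalty=6.0))
            rec = seg.reconstruct(sim.truth.t)
            mse_rec = np.mean(np.sum((rec - sim.truth.xy) ** 2, axis=1))
            mse_meas = np.mean(np.sum((sim.measured.xy - sim.truth.xy) ** 2, axis=1))
            assert mse_rec < mse_meas


class TestRefitContinuous:
    def test_single_segment_is_ordinary_least_squares(self, rng):
        n = 60
        t = np.sort(rng.uniform(0, 1, n))
        x = rng.normal(0, 1, n)
        tr = GazeTrace(t, x, np.zeros(n))
        seg = refit_continuous(tr, np.array([0]))
        coef = np.polyfit(t, x, 1)
        assert seg.node_values[0, 0] == pytest.approx(np.polyval(coef, t[0]), abs=1e-8)
        assert seg.node_values[1, 0] == pytest.approx(np.polyval(coef, t[-1]), abs=1e-8)

    def test_exactly_representable_data_has_zero_sse(self):
        t = np.arange(0, 2, 0.01)
        knee = 1.0
        x = np.where(t < knee, 2.0 * t, 2.0 * knee - 3.0 * (t - knee))
        tr = GazeTrace(t, x, x[::-1].copy())
        bps = np.array([0, int(knee / 0.01)])
        seg = refit_continuous(tr, bps)
        rec = seg.reconstruct(t)
        assert np.max(np.abs(rec[:, 0] - tr.x)) < 1e-10

    def test_matches_constrained_ls_oracle(self, rng):
        n = 80
        t = np.sort(rng.uniform(0, 4, n))
        t[0], t[-1] = 0.0, 4.0
        x = rng.normal(0, 1, n)
        tr = GazeTrace(t, x, np.zeros(n))
        bps = np.array([0, 20, 35, 55, 70])
        seg = refit_continuous(tr, bps)
        oracle = constrained_ls_piecewise(t, x, seg.node_times)
        np.testing.assert_allclose(seg.node_values[:, 0], oracle, atol=1e-8)


class TestEstimateNoise:
    def test_recovers_known_sigma(self):
        sim = simulate_recording(ScenarioParams(duration=20.0, sigma=0.5,
                                                out_rate=500.0, seed=3))
        cfg = SegmentationConfig(structural_error=0.0)
        total, seg = estimate_noise(sim.measured, cfg, penalty=6.0)
        assert 0.4 < total < 0.6
        assert seg.sigma_used == pytest.approx(total)

    def test_structural_error_adds_to_estimate(self):
        sim = simulate_recording(ScenarioParams(duration=10.0, sigma=0.5,
                                                out_rate=250.0, seed=4))
        t0, _ = estimate_noise(sim.measured, SegmentationConfig(structural_error=0.0),
                               penalty=6.0)
        t1, _ = estimate_noise(sim.measured, SegmentationConfig(structural_error=0.1),
                               penalty=6.0)
        assert t1 - t0 == pytest.approx(0.1, abs=1e-12)

    def test_structural_error_quadrature_option(self):
        sim = simulate_recording(ScenarioParams(duration=10.0, sigma=0.5,
                                                out_rate=250.0, seed=4))
        t0, _ = estimate_noise(sim.measured, SegmentationConfig(structural_error=0.0),
                               penalty=6.0)
        tq, _ = estimate_noise(
            sim.measured,
            SegmentationConfig(structural_error=0.1, structural_combine="quadrature"),
            penalty=6.0)
        assert tq == pytest.approx(np.sqrt(t0 ** 2 + 0.01), abs=1e-12)


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        dict(sigma=-1.0), dict(sigma="guess"), dict(penalty=0.0),
        dict(penalty="table"), dict(min_segment_samples=1),
        dict(structural_combine="multiply"),
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            SegmentationConfig(**kw)
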
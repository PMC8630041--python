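"""Observer model: filters, convolution, evidence, accumulation, decisions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rlci.observer import (
    ModelParams,
    accumulate,
    build_ensemble,
    evidence,
    filter_response,
    run_ensemble,
    simulate_experiment,
    simulate_trial,
    spatial_filter,
    spatial_kernel,
    spatial_weight_matrix,
    temporal_filter,
    temporal_kernel,
)
from rlci.stimulus import StimulusConfig, compose_trial_stimulus, rasterize_to_samples


class TestSpatialFilter:
    def test_center_value(self):
        # 1 - (sigma_c / sigma_s)^2 at the origin
        assert spatial_filter(0.0, 4.15, 17.4) == pytest.approx(0.9431150085876602)

    def test_even(self):
        x = np.linspace(0.3, 80, 40)
        assert np.allclose(spatial_filter(x, 4.15, 17.4), spatial_filter(-x, 4.15, 17.4))

    def test_surround_dominates_tail(self):
        # beyond the center lobe the broader surround wins: weight < 0 -> 0
        x = np.linspace(15, 100, 50)
        w = spatial_filter(x, 4.15, 17.4)
        assert np.all(w < 0)
        assert abs(w[-1]) < abs(w[0])

    def test_requires_broader_surround(self):
        with pytest.raises(ValueError):
            spatial_filter(0.0, 17.4, 4.15)


class TestTemporalFilter:
    def test_zero_at_onset(self):
        assert temporal_filter(0.0, 5, 1.36, 0.47) == 0.0

    def test_frozen_value(self):
        # direct evaluation at t = 5 frames with the fitted constants
        assert temporal_filter(5.0, 5, 1.36, 0.47) == pytest.approx(
            0.12024870045374034, rel=1e-12
        )

    def test_monophasic_when_B_zero(self):
        t = np.linspace(0, 60, 200)
        assert np.all(temporal_filter(t, 5, 1.36, 0.0) >= 0)

    def test_biphasic_when_B_positive(self):
        t = np.arange(0, 40, 0.25)
        w = temporal_filter(t, 5, 1.36, 0.47)
        peak = int(np.argmax(w))
        assert w[peak] > 0
        assert np.min(w[peak:]) < 0  # negative lobe after the positive one

    def test_causality_and_validation(self):
        with pytest.raises(ValueError):
            temporal_filter(-1.0, 5, 1.36, 0.47)
        with pytest.raises(ValueError):
            temporal_filter(1.0, 5, -1.0, 0.47)

    def test_discrete_kernel_integrates_filter(self):
        # frame-window integration: sums to tau * (1 - B) over full support
        p = ModelParams()
        k = temporal_kernel(p)
        assert k.sum() == pytest.approx(p.tau * (1 - p.B), rel=1e-4)
        # fine Riemann sum over one window matches the closed form
        t = np.linspace(3.0, 4.0, 20001)
        riemann = np.trapezoid(temporal_filter(t, p.n_stages, p.tau, p.B), t)
        assert k[3] == pytest.approx(riemann, rel=1e-6)


def brute_force_response(field, params):
    """O(N^2) separable convolution oracle: nested loops, zero padding."""
    n_x, n_t = field.shape
    fs = spatial_kernel(params, n_x)
    ft = temporal_kernel(params)
    out = np.zeros((n_x, n_t))
    for x in range(n_x):
        for t in range(n_t):
            acc = 0.0
            for xp in range(n_x):
                for s in range(min(t + 1, len(ft))):
                    acc += field[xp, t - s] * fs[(n_x - 1) + (x - xp)] * ft[s]
            out[x, t] = acc
    return out


class TestFilterResponse:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        params = ModelParams()
        for _ in range(3):
            field = rng.normal(0, 1, (8, 12))
            fast = filter_response(field, params)
            slow = brute_force_response(field, params)
            assert np.allclose(fast, slow, atol=1e-12)

    def test_impulse_gives_outer_product(self):
        params = ModelParams()
        field = np.zeros((9, 10))
        field[4, 2] = 1.0
        r = filter_response(field, params)
        fs = spatial_kernel(params, 9)
        ft = temporal_kernel(params)
        expected = np.zeros_like(r)
        for x in range(9):
            for t in range(2, 10):
                if t - 2 < len(ft):
                    expected[x, t] = fs[8 + x - 4] * ft[t - 2]
        assert np.allclose(r, expected, atol=1e-12)

    def test_linearity(self):
        rng = np.random.default_rng(1)
        params = ModelParams()
        f1, f2 = rng.normal(0, 1, (2, 10, 15))
        lhs = filter_response(2.0 * f1 - 3.0 * f2, params)
        rhs = 2.0 * filter_response(f1, params) - 3.0 * filter_response(f2, params)
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_bar_matrix_shortcut_equals_rasterized_convolution(self):
        # spatial filtering of a bar-constant field is a matmul with W
        cfg = StimulusConfig()
        params = ModelParams()
        movie = compose_trial_stimulus(cfg, "left", seed=4)
        left, _ = rasterize_to_samples(movie)
        full = filter_response(left, params)
        w = spatial_weight_matrix(params, cfg)
        ft = temporal_kernel(params, max_len=cfg.n_frames)
        g = np.apply_along_axis(
            lambda row: np.convolve(row, ft)[: cfg.n_frames], 1, movie.contrast_left
        )
        assert np.allclose(full, w @ g, atol=1e-9)

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            filter_response(np.zeros(5), ModelParams())


class TestEvidence:
    def test_symmetry_and_antisymmetry(self):
        rng = np.random.default_rng(2)
        r = rng.normal(0, 1, (6, 8))
        assert np.all(evidence(r, r) == 0)
        q = rng.normal(0, 1, (6, 8))
        assert np.allclose(evidence(r, q), -evidence(q, r))

    def test_hand_computed(self):
        r_left = np.array([[3.0], [-1.0]])
        r_right = np.array([[1.0], [1.0]])
        assert evidence(r_left, r_right, t=0) == pytest.approx(2.0)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            evidence(np.zeros((2, 3)), np.zeros((2, 4)))


class TestAccumulate:
    def test_plain_cumsum_limit(self):
        dr = np.array([1.0, -2.0, 3.0, 0.5])
        trace = accumulate(dr, gamma=1.0, epsilon=0.0)
        assert np.allclose(trace.s, np.cumsum(dr))

    def test_geometric_series_closed_form(self):
        gamma, c, n = 0.7, 2.5, 40
        trace = accumulate(np.full(n, c), gamma=gamma, epsilon=0.0)
        T = np.arange(1, n + 1)
        expected = c * (1 - gamma ** T) / (1 - gamma)
        assert np.allclose(trace.s, expected)

    def test_recursive_equals_direct_sum(self):
        # dual-route oracle: D(T) = sum_t gamma^(T-t) dR(t), N(T) = sum eps
        rng = np.random.default_rng(3)
        for seed in range(5):
            dr = rng.normal(0, 5, 50)
            draws = rng.standard_normal(50)
            trace = accumulate(dr, gamma=0.85, epsilon=2.0, noise_draws=draws)
            direct = np.array(
                [
                    sum(0.85 ** (T - t) * dr[t] for t in range(T + 1))
                    + 2.0 * draws[: T + 1].sum()
                    for T in range(50)
                ]
            )
            assert np.allclose(trace.s, direct, atol=1e-9)

    def test_leaked_noise_variant(self):
        rng = np.random.default_rng(4)
        dr = rng.normal(0, 1, 30)
        draws = rng.standard_normal(30)
        trace = accumulate(dr, 0.5, 1.5, noise_draws=draws, leak_internal_noise=True)
        direct = np.array(
            [
                sum(0.5 ** (T - t) * (dr[t] + 1.5 * draws[t]) for t in range(T + 1))
                for T in range(30)
            ]
        )
        assert np.allclose(trace.s, direct, atol=1e-10)

    def test_crossing_detection(self):
        trace = accumulate(np.array([1.0, 1.0, 1.0, 1.0]), 1.0, 0.0, bound=2.5)
        assert trace.crossing_frame == 2

    def test_gamma_validation(self):
        with pytest.raises(ValueError):
            accumulate(np.zeros(3), gamma=0.0, epsilon=0.0)
        with pytest.raises(ValueError):
            accumulate(np.zeros(3), gamma=1.5, epsilon=0.0)


class TestSimulateTrial:
    def test_timeout_with_huge_bound(self):
        cfg = StimulusConfig(alpha=0.2)
        movie = compose_trial_stimulus(cfg, "left", seed=0)
        p = ModelParams(bound=1e12, epsilon=0.0)
        rec = simulate_trial(movie, p, seed=0)
        assert rec.timeout and rec.rt_ms is None and not rec.correct

    def test_deterministic_strong_target(self):
        cfg = StimulusConfig(alpha=0.2)
        p = ModelParams(epsilon=0.0)
        for seed in range(4):
            movie = compose_trial_stimulus(cfg, "left", seed=seed)
            rec = simulate_trial(movie, p, seed=0)
            assert rec.choice == "left" and rec.correct

    def test_rt_arithmetic(self):
        cfg = StimulusConfig(alpha=0.2)
        movie = compose_trial_stimulus(cfg, "left", seed=1)
        rec = simulate_trial(movie, ModelParams(epsilon=0.0), seed=0)
        assert rec.crossing_frame is not None
        # completing frame index k means k + 1 frames of viewing + motor delay
        assert rec.rt_ms == pytest.approx((rec.crossing_frame + 1) * 1000 / 30 + 250)

    def test_reproducible(self):
        cfg = StimulusConfig(alpha=0.05)
        movie = compose_trial_stimulus(cfg, "right", seed=9)
        a = simulate_trial(movie, ModelParams(), seed=77)
        b = simulate_trial(movie, ModelParams(), seed=77)
        assert a.choice == b.choice and a.rt_ms == b.rt_ms

    def test_mirror_symmetry(self):
        """Swapping the fields (and sign-flipping the internal noise)
        flips the choice and preserves the RT exactly."""
        cfg = StimulusConfig(alpha=0.1)
        p = ModelParams()
        rng = np.random.default_rng(5)
        draws = rng.standard_normal(cfg.n_frames)
        movie = compose_trial_stimulus(cfg, "left", seed=13)
        a = simulate_trial(movie, p, noise_draws=draws)
        b = simulate_trial(movie.mirrored(), p, noise_draws=-draws)
        assert not a.timeout
        assert {a.choice, b.choice} == {"left", "right"}
        assert a.rt_ms == b.rt_ms


class TestSimulateExperiment:
    def test_deterministic(self, config_fast, params):
        a = simulate_experiment(config_fast, params, 10, seed=5)
        b = simulate_experiment(config_fast, params, 10, seed=5)
        for ra, rb in zip(a, b):
            assert ra.choice == rb.choice and ra.rt_ms == rb.rt_ms
            assert np.array_equal(ra.noise_left, rb.noise_left)

    def test_sides_balanced(self, small_log):
        sides = [r.target_side for r in small_log]
        assert abs(sides.count("left") - sides.count("right")) <= 1

    def test_batch_matches_per_trial_path(self, config_fast, params, small_log):
        for rec in small_log.records[:6]:
            movie = compose_trial_stimulus(config_fast, rec.target_side, rec.stimulus_seed)
            single = simulate_trial(movie, params, seed=rec.seed)
            assert single.choice == rec.choice
            assert single.rt_ms == rec.rt_ms

    def test_summary_rates(self, small_log):
        s = small_log.summary()
        assert 0 <= s["error_rate"] < 0.2
        assert s["timeout_rate"] < 0.1

    def test_bound_extremes_control_timeouts(self, config_fast):
        ens = build_ensemble(config_fast, 30, seed=8)
        hi = run_ensemble(ens, ModelParams(bound=1e12))
        lo = run_ensemble(ens, ModelParams(bound=1e-6))
        assert hi.timeout_rate == 1.0
        assert lo.timeout_rate == 0.0

    def test_invalid_n_trials(self, config_fast, params):
        with pytest.raises(ValueError):
            simulate_experiment(config_fast, params, 0, seed=1)


class TestParamValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"sigma_c": 20.0},  # center broader than surround
            {"gamma": 0.0},
            {"gamma": 1.2},
            {"tau": -1.0},
            {"B": -0.1},
            {"bound": 0.0},
            {"n_stages": 0},
        ],
    )
    def test_rejects(self, kw):
        with pytest.raises(ValueError):
            ModelParams(**kw)

    def test_roundtrip_dict(self):
        p = ModelParams(sigma_c=3.0, gamma=0.5)
        assert ModelParams.from_dict(p.to_dict()) == p


@settings(deadline=None, max_examples=20, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_convolution_oracle_property(seed):
    """Separable fast convolution equals the nested-loop oracle on random toys."""
    rng = np.random.default_rng(seed)
    field = rng.normal(0, 1, (6, 9))
    params = ModelParams(sigma_c=rng.uniform(1, 3), sigma_s=rng.uniform(4, 9),
                         tau=rng.uniform(0.5, 2.5), B=rng.uniform(0, 1))
    assert np.allclose(
        filter_response(field, params), brute_force_response(field, params), atol=1e-10
    )
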
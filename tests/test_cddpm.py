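"""Noise schedule, forward diffusion, denoiser training and augmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nirsicpp import (
    TrainConfig,
    TrialSegment,
    augment_train_set,
    denoise_step,
    forward_diffuse,
    make_schedule,
    sample_cddpm,
    train_cddpm,
)
from nirsicpp.cddpm import per_trial_betas

from conftest import make_segments


def make_toy(n=64, noise_sd=0.2, seed=0):
    """Two-class constant signals ±1 with small Gaussian jitter."""
    rng = np.random.default_rng(seed)
    segs = []
    for i in range(n):
        lbl = i % 2
        data = np.full((10, 60), 1.0 if lbl else -1.0) + rng.normal(0, noise_sd, (10, 60))
        segs.append(TrialSegment(f"T{i:03d}", 0, "HbO", data, lbl, "female"))
    return segs


class TestSchedule:
    def test_printed_endpoints(self):
        sch = make_schedule()
        assert sch.betas[0] == pytest.approx(0.001)
        assert sch.betas[-1] == pytest.approx(0.02)
        assert sch.T == 200

    def test_final_alpha_bar_matches_direct_product(self):
        sch = make_schedule()
        direct = 1.0
        for t in range(200):
            direct *= 1.0 - (0.001 + (0.02 - 0.001) * t / 199)
        assert sch.alpha_bars[-1] == pytest.approx(direct, rel=1e-12)
        assert sch.alpha_bars[-1] == pytest.approx(0.121, abs=0.001)

    def test_monotonicity_invariants(self):
        for T, b0, b1 in [(200, 0.001, 0.02), (50, 0.005, 0.1), (1, 0.01, 0.01)]:
            sch = make_schedule(T, b0, b1)
            assert np.all(np.diff(sch.betas) >= 0)
            assert np.all(np.diff(sch.alpha_bars) < 0) or T == 1
            assert np.all((sch.betas > 0) & (sch.betas < 1))

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            make_schedule(200, 0.0, 0.02)
        with pytest.raises(ValueError):
            make_schedule(0)

    @settings(max_examples=50, derandomize=True)
    @given(
        T=st.integers(min_value=2, max_value=500),
        b0=st.floats(min_value=1e-5, max_value=0.3),
        spread=st.floats(min_value=0.0, max_value=0.5),
    )
    def test_invariants_for_any_valid_schedule(self, T, b0, spread):
        b1 = min(b0 + spread, 0.99)
        sch = make_schedule(T, b0, b1)
        assert np.all(np.diff(sch.betas) >= -1e-15)
        assert np.all((sch.betas > 0) & (sch.betas < 1))
        assert np.all(np.diff(sch.alpha_bars) < 0)
        assert np.allclose(sch.alphas, 1 - sch.betas)


class TestForwardDiffuse:
    def test_zero_signal_pure_scaled_noise(self):
        sch = make_schedule()
        eps = np.random.default_rng(0).normal(size=(10, 60))
        f_t = forward_diffuse(np.zeros((10, 60)), 100, eps, sch)
        assert np.allclose(f_t, np.sqrt(1 - sch.alpha_bars[99]) * eps)

    def test_t1_near_identity(self):
        sch = make_schedule()
        rng = np.random.default_rng(1)
        f0 = rng.normal(size=(10, 60))
        f1 = forward_diffuse(f0, 1, rng.normal(size=f0.shape), sch)
        assert np.sqrt(np.mean((f1 - f0) ** 2)) / np.sqrt(np.mean(f0**2)) < 0.05

    def test_marginal_moments_match_closed_form(self):
        """Var(f_t) over many draws = ᾱ_t·Var(f0) + (1−ᾱ_t), within 3 MC SE."""
        sch = make_schedule()
        rng = np.random.default_rng(2)
        f0 = np.ones(10_000)
        for t in (10, 100, 200):
            eps = rng.normal(size=f0.shape)
            f_t = forward_diffuse(f0, t, eps, sch)
            ab = sch.alpha_bars[t - 1]
            expected_var = 1 - ab  # Var(f0)=0 here; mean √ᾱ
            se = expected_var * np.sqrt(2 / len(f0))
            assert abs(f_t.var() - expected_var) < 3 * se
            assert abs(f_t.mean() - np.sqrt(ab)) < 3 * np.sqrt(expected_var / len(f0))

    def test_closed_form_equals_iterated_single_steps(self):
        """Mean/var agreement of the closed form with step-by-step noising."""
        sch = make_schedule()
        rng = np.random.default_rng(3)
        n = 10_000
        f0 = np.full(n, 0.7)
        x = f0.copy()
        t_target = 100
        for t in range(1, t_target + 1):
            b = sch.betas[t - 1]
            x = np.sqrt(1 - b) * x + np.sqrt(b) * rng.normal(size=n)
        ab = sch.alpha_bars[t_target - 1]
        se_mean = np.sqrt((1 - ab) / n)
        assert abs(x.mean() - np.sqrt(ab) * 0.7) < 3 * se_mean
        assert abs(x.var() - (1 - ab)) < 3 * (1 - ab) * np.sqrt(2 / n)

    def test_t_out_of_range(self):
        sch = make_schedule()
        with pytest.raises(ValueError):
            forward_diffuse(np.zeros(5), 0, np.zeros(5), sch)
        with pytest.raises(ValueError):
            forward_diffuse(np.zeros(5), 201, np.zeros(5), sch)


class TestTraining:
    def test_loss_decreases_on_toy_problem(self):
        segs = make_toy(32)
        cfg = TrainConfig(epochs=200, batch_size=16, hidden=(64, 32), cond_dim=16)
        state = train_cddpm(segs, cfg, seed=0)
        assert state.training_log[-1] < 0.2 * state.training_log[0]

    def test_seed_determinism(self):
        segs = make_toy(16)
        cfg = TrainConfig(epochs=20, batch_size=16, hidden=(32, 16), cond_dim=8)
        a = train_cddpm(segs, cfg, seed=5)
        b = train_cddpm(segs, cfg, seed=5)
        assert a.training_log == b.training_log

    def test_zero_lr_leaves_loss_flat(self):
        segs = make_toy(16)
        cfg = TrainConfig(epochs=5, batch_size=16, hidden=(32, 16), cond_dim=8, lr=0.0)
        state = train_cddpm(segs, cfg, seed=0)
        assert np.ptp(state.training_log) < 0.3 * state.training_log[0]

    def test_early_training_log_decreasing(self):
        segs = make_toy(32)
        cfg = TrainConfig(epochs=100, batch_size=16, hidden=(64, 32), cond_dim=16)
        state = train_cddpm(segs, cfg, seed=1)
        head = np.array(state.training_log[:20])
        smoothed = np.convolve(head, np.ones(5) / 5, mode="valid")
        assert smoothed[-1] < smoothed[0]


class TestDenoiseStep:
    def test_oracle_eps_reconstruction_error_vanishes_near_t1(self):
        """With ε̂ = true ε, the one-step posterior mean → f0 as ᾱ → 1."""
        sch = make_schedule()
        segs = make_toy(16)
        state = train_cddpm(segs, TrainConfig(epochs=2, batch_size=16,
                                              hidden=(32, 16), cond_dim=8), seed=0)
        rng = np.random.default_rng(4)
        f0 = rng.normal(size=(1, 600))
        errs = []
        for t in (1, 50, 150):
            eps = rng.normal(size=f0.shape)
            f_t = forward_diffuse(f0, t, eps, sch)
            out = denoise_step(f_t, t, 0, np.zeros(10), state,
                               rng=None if t == 1 else np.random.default_rng(0),
                               eps_hat=eps)
            errs.append(np.sqrt(np.mean((out - f0) ** 2)))
        assert errs[0] < 1e-10
        assert errs[0] < errs[1] < errs[2]

    def test_untrained_state_rejected(self):
        from nirsicpp.cddpm import DiffusionModelState
        from nirsicpp._nn import DenoiserNet

        state = DiffusionModelState(
            schedule=make_schedule(), net=DenoiserNet(600, 44), shape=(10, 60),
            channel_mean=np.zeros(10), channel_std=np.ones(10),
            beta_mean=np.zeros(10), beta_std=np.ones(10),
        )
        with pytest.raises(RuntimeError):
            denoise_step(np.zeros(600), 10, 0, np.zeros(10), state,
                         rng=np.random.default_rng(0))

    def test_fixed_sampler_seed_identical_trajectory(self):
        segs = make_toy(32)
        state = train_cddpm(segs, TrainConfig(epochs=30, batch_size=16,
                                              hidden=(32, 16), cond_dim=8), seed=2)
        a = sample_cddpm(state, 3, 1, seed=9)
        b = sample_cddpm(state, 3, 1, seed=9)
        assert np.array_equal(a, b)


class TestSampling:
    def test_toy_class_conditional_means(self):
        """Reduced-scale training recovers the two class means within 0.3."""
        segs = make_toy(64)
        state = train_cddpm(segs, TrainConfig(epochs=500, batch_size=32,
                                              hidden=(128, 64), cond_dim=32), seed=0)
        for label, target in ((0, -1.0), (1, 1.0)):
            s = sample_cddpm(state, 20, label, seed=40 + label)
            assert abs(s.mean() - target) < 0.3

    def test_empty_request(self):
        segs = make_toy(16)
        state = train_cddpm(segs, TrainConfig(epochs=5, batch_size=16,
                                              hidden=(32, 16), cond_dim=8), seed=0)
        assert sample_cddpm(state, 0, 1).shape == (0, 10, 60)

    def test_output_shape(self):
        segs = make_toy(16)
        state = train_cddpm(segs, TrainConfig(epochs=5, batch_size=16,
                                              hidden=(32, 16), cond_dim=8), seed=0)
        assert sample_cddpm(state, 4, 0, seed=1).shape == (4, 10, 60)

    def test_unknown_label_rejected(self):
        segs = make_toy(16)
        state = train_cddpm(segs, TrainConfig(epochs=5, batch_size=16,
                                              hidden=(32, 16), cond_dim=8), seed=0)
        with pytest.raises(ValueError):
            sample_cddpm(state, 2, 3)


class TestAugmentation:
    @pytest.fixture
    def trained(self):
        segs = make_toy(40)
        state = train_cddpm(segs, TrainConfig(epochs=30, batch_size=16,
                                              hidden=(32, 16), cond_dim=8), seed=0)
        return segs, state

    def test_doubles_training_set(self, trained):
        segs, state = trained
        out = augment_train_set(segs, state, seed=1)
        assert len(out) == 2 * len(segs)
        assert sum(s.synthetic for s in out) == len(segs)

    def test_class_proportions_match(self, trained):
        segs, state = trained
        out = augment_train_set(segs, state, seed=1)
        synth = [s for s in out if s.synthetic]
        real_pos = sum(s.label for s in segs)
        assert sum(s.label for s in synth) == real_pos

    def test_test_set_untouched(self, trained):
        segs, state = trained
        test = make_segments(10, seed=99)
        snapshot = [s.data.copy() for s in test]
        augment_train_set(segs, state, test_segments=test, seed=1)
        for before, after in zip(snapshot, test):
            assert np.array_equal(before, after.data)

    def test_leakage_detected(self, trained):
        segs, state = trained
        with pytest.raises(ValueError, match="leakage"):
            augment_train_set(segs, state, test_segments=segs[:3], seed=1)


def test_per_trial_betas_shape_and_signal():
    rng = np.random.default_rng(11)
    segs = []
    for i in range(6):
        data = rng.normal(0, 0.01, (10, 60))
        data[4, :30] += 1.0  # strong response in channel 5 during the task half
        segs.append(TrialSegment(f"s{i}", 0, "HbO", data, 0, "f"))
    B = per_trial_betas(segs)
    assert B.shape == (6, 10)
    assert np.all(np.argmax(np.abs(B), axis=1) == 4)
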
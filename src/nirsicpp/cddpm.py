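"""Conditional denoising diffusion probabilistic model over HbO trial segments.

Forward process: Gaussian noise is added over T steps under a linear
β-schedule (defaults 0.001 → 0.02, T = 200), with the closed-form marginal
f_t = √ᾱ_t·f₀ + √(1−ᾱ_t)·ε. Reverse process: a conditional ε-predicting
network — conditioned on the timestep (sinusoidal embedding), the class
label (normal/ICPP one-hot) and the trial's standardized per-channel GLM
β-vector — drives DDPM ancestral sampling with σ_t² = β_t and no noise at
the final step. Training minimizes the mean-squared error between true
and predicted noise with AdamW (defaults: 500 epochs, batch 64, lr 0.001,
weight decay 0.01); the network carries the clean-signal parameterization
f̂₀ with ε̂ = (f_t − √ᾱ_t·f̂₀)/√(1−ᾱ_t), and the MSE is taken on f₀
uniformly over timesteps — the signal-to-noise-reweighted ε objective,
which keeps the high-noise steps where the conditioning carries all the
information on equal footing. The augmentation protocol generates synthetic
segments equal in number to the real training set, matching its class
proportions, while the test set stays entirely real.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._nn import AdamW, DenoiserNet, sinusoidal_embedding
from .activation import build_design, canonical_hrf, fit_glm
from .features import TrialSegment
from .synthcohort import build_paradigm

__all__ = [
    "NoiseSchedule",
    "make_schedule",
    "forward_diffuse",
    "TrainConfig",
    "DiffusionModelState",
    "train_cddpm",
    "denoise_step",
    "sample_cddpm",
    "augment_train_set",
    "per_trial_betas",
]

CLASS_LABELS = (0, 1)  # normal, ICPP
TIME_EMB_DIM = 32


@dataclass(frozen=True)
class NoiseSchedule:
    """Linear variance schedule β_t with α_t = 1−β_t and ᾱ_t = Πα_s."""

    betas: np.ndarray
    alphas: np.ndarray
    alpha_bars: np.ndarray

    @property
    def T(self) -> int:
        return len(self.betas)


def make_schedule(T: int = 200, beta_start: float = 0.001, beta_end: float = 0.02) -> NoiseSchedule:
    """Linear grid from β_start to β_end over T diffusion steps."""
    if T < 1:
        raise ValueError("T must be >= 1")
    if not (0 < beta_start <= beta_end < 1):
        raise ValueError("need 0 < beta_start <= beta_end < 1")
    if T == 1:
        betas = np.array([beta_start])
    else:
        betas = beta_start + (beta_end - beta_start) * np.arange(T) / (T - 1)
    alphas = 1.0 - betas
    return NoiseSchedule(betas=betas, alphas=alphas, alpha_bars=np.cumprod(alphas))


def forward_diffuse(f0: np.ndarray, t: int, eps: np.ndarray, schedule: NoiseSchedule) -> np.ndarray:
    """Closed-form forward marginal f_t = √ᾱ_t·f₀ + √(1−ᾱ_t)·ε (t is 1-based)."""
    if not 1 <= t <= schedule.T:
        raise ValueError(f"t must be in [1, {schedule.T}]")
    ab = schedule.alpha_bars[t - 1]
    return np.sqrt(ab) * f0 + np.sqrt(1.0 - ab) * eps


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters; defaults follow the study's configuration."""

    epochs: int = 500
    batch_size: int = 64
    lr: float = 1e-3
    weight_decay: float = 0.01
    hidden: tuple[int, int] = (256, 128)
    cond_dim: int = 64
    T: int = 200
    beta_start: float = 0.001
    beta_end: float = 0.02
    # classifier-free guidance: fraction of training rows whose class/β
    # condition is nulled, and the guidance weight applied at sampling
    cond_dropout: float = 0.15
    guidance: float = 3.0

    @classmethod
    def desk_scale(cls) -> "TrainConfig":
        """Reduced profile for laptop-scale experiments and the test suite."""
        return cls(epochs=600, batch_size=32, hidden=(128, 64), cond_dim=32)


@dataclass
class DiffusionModelState:
    """Trained conditional denoiser plus everything needed to sample."""

    schedule: NoiseSchedule
    net: DenoiserNet
    shape: tuple[int, int]  # (channels, time)
    channel_mean: np.ndarray
    channel_std: np.ndarray
    beta_mean: np.ndarray
    beta_std: np.ndarray
    training_log: list = field(default_factory=list)
    guidance: float = 1.0
    seed: int = 0
    train_keys: frozenset = field(default_factory=frozenset)
    train_class_counts: dict = field(default_factory=dict)
    train_betas_by_class: dict = field(default_factory=dict)

    @property
    def trained(self) -> bool:
        return len(self.training_log) > 0


def per_trial_betas(segments: Sequence[TrialSegment], fs: float = 1.0) -> np.ndarray:
    """Per-channel task β from a GLM on each trial's own 60-s window."""
    n_t = segments[0].data.shape[1]
    paradigm = build_paradigm(n_trials=1, prompt_s=0.0, block_s=n_t / (2 * fs), fs=fs)
    design = build_design(paradigm, canonical_hrf(fs))
    return np.stack([fit_glm(seg.data, design).beta_for("MA") for seg in segments])


def _condition_matrix(
    t: np.ndarray,
    labels: np.ndarray,
    betas_std: np.ndarray,
    null_mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Rows of [timestep embedding, class one-hot, standardized β].

    Rows selected by ``null_mask`` get the class/β part zeroed — the null
    condition used for classifier-free guidance (the timestep embedding is
    always kept).
    """
    temb = sinusoidal_embedding(t, TIME_EMB_DIM)
    onehot = np.zeros((len(labels), 2))
    onehot[np.arange(len(labels)), labels.astype(int)] = 1.0
    cond = np.concatenate([onehot, np.asarray(betas_std, dtype=float)], axis=1)
    if null_mask is not None:
        cond = cond.copy()
        cond[np.asarray(null_mask, dtype=bool)] = 0.0
    return np.concatenate([temb, cond], axis=1)


def train_cddpm(
    train_segments: Sequence[TrialSegment],
    config: TrainConfig | None = None,
    betas: Optional[np.ndarray] = None,
    seed: int = 0,
) -> DiffusionModelState:
    """Fit the conditional denoiser on real training segments.

    Segments are standardized per channel on training statistics; the
    conditioning β-vectors (per-trial GLM task amplitudes, computed here if
    not supplied) are standardized likewise. Each optimization step draws
    uniform timesteps and Gaussian noise, forms the closed-form noisy
    segments, and minimizes ‖ε − ε̂‖². Fully deterministic under a fixed
    seed.
    """
    if not train_segments:
        raise ValueError("training requires at least one segment")
    config = config or TrainConfig()
    n_ch, n_t = train_segments[0].data.shape
    X = np.stack([s.data for s in train_segments])  # (N, ch, t)
    labels = np.array([s.label for s in train_segments])
    ch_mean = X.mean(axis=(0, 2))
    ch_std = X.std(axis=(0, 2))
    ch_std = np.where(ch_std == 0, 1.0, ch_std)
    Xs = (X - ch_mean[None, :, None]) / ch_std[None, :, None]
    flat = Xs.reshape(len(X), -1)

    if betas is None:
        betas = per_trial_betas(train_segments)
    betas = np.asarray(betas, dtype=float)
    b_mean = betas.mean(axis=0)
    b_std = betas.std(axis=0)
    b_std = np.where(b_std == 0, 1.0, b_std)
    betas_std = (betas - b_mean) / b_std

    schedule = make_schedule(config.T, config.beta_start, config.beta_end)
    cond_in = TIME_EMB_DIM + 2 + betas.shape[1]
    rng = np.random.default_rng(seed)
    net = DenoiserNet(
        data_dim=n_ch * n_t, cond_in_dim=cond_in, hidden=config.hidden,
        cond_dim=config.cond_dim, seed=int(rng.integers(0, 2**31 - 1)),
    )
    opt = AdamW(lr=config.lr, weight_decay=config.weight_decay)
    n = len(flat)
    log = []
    for epoch in range(config.epochs):
        perm = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = perm[start:start + config.batch_size]
            f0 = flat[idx]
            t = rng.integers(1, schedule.T + 1, size=len(idx))
            eps = rng.normal(size=f0.shape)
            ab = schedule.alpha_bars[t - 1][:, None]
            ft = np.sqrt(ab) * f0 + np.sqrt(1 - ab) * eps
            null_mask = rng.uniform(size=len(idx)) < config.cond_dropout
            u = _condition_matrix(t, labels[idx], betas_std[idx], null_mask=null_mask)
            # The network predicts the clean signal f̂0 (the noise estimate
            # used at sampling time is ε̂ = (f_t − √ᾱ·f̂0)/√(1−ᾱ)); the
            # training objective is the MSE on f0, uniform over timesteps —
            # the ᾱ/(1−ᾱ)-reweighted ε-MSE. Uniform weighting keeps the
            # high-noise timesteps, where the class/β conditioning carries
            # all the information, on equal footing.
            loss, grads = net.loss_and_grads(ft, u, f0)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"NaN/inf training loss at epoch {epoch}: lr={config.lr}, "
                    f"batch={config.batch_size}; inspect input scaling"
                )
            opt.step(net.params, grads)
            losses.append(loss)
        log.append(float(np.mean(losses)))
    return DiffusionModelState(
        schedule=schedule,
        net=net,
        shape=(n_ch, n_t),
        channel_mean=ch_mean,
        channel_std=ch_std,
        beta_mean=b_mean,
        beta_std=b_std,
        training_log=log,
        guidance=config.guidance,
        seed=seed,
        train_keys=frozenset((s.subject_id, s.trial_index) for s in train_segments),
        train_class_counts={c: int(np.sum(labels == c)) for c in CLASS_LABELS},
        train_betas_by_class={c: betas[labels == c] for c in CLASS_LABELS},
    )


def denoise_step(
    f_t: np.ndarray,
    t: int,
    label: int,
    beta_vec: np.ndarray,
    state: DiffusionModelState,
    rng: np.random.Generator | None = None,
    eps_hat: Optional[np.ndarray] = None,
) -> np.ndarray:
    """One DDPM ancestral update f_t → f_{t−1} in standardized space.

    Uses the posterior mean with the network's ε̂ and injects σ_t·z with
    σ_t² = β_t, except at t = 1 where the step is deterministic.
    ``eps_hat`` may be supplied to bypass the network (oracle tests).
    """
    if not state.trained and eps_hat is None:
        raise RuntimeError("denoise_step requires a trained model state")
    if not 1 <= t <= state.schedule.T:
        raise ValueError("t out of range")
    f_t = np.atleast_2d(f_t)
    if eps_hat is None:
        betas_std = (np.atleast_2d(beta_vec) - state.beta_mean) / state.beta_std
        bs = np.broadcast_to(betas_std, (len(f_t), betas_std.shape[1]))
        tt = np.full(len(f_t), t)
        ll = np.full(len(f_t), label)
        f0_hat = state.net.forward(f_t, _condition_matrix(tt, ll, bs))
        if state.guidance != 1.0:
            # classifier-free guidance: push the prediction away from the
            # null-condition estimate toward the class-conditional one
            f0_null = state.net.forward(
                f_t, _condition_matrix(tt, ll, bs, null_mask=np.ones(len(f_t)))
            )
            f0_hat = f0_null + state.guidance * (f0_hat - f0_null)
        ab = state.schedule.alpha_bars[t - 1]
        eps_hat = (f_t - np.sqrt(ab) * f0_hat) / np.sqrt(1.0 - ab)
    sch = state.schedule
    beta_t = sch.betas[t - 1]
    alpha_t = sch.alphas[t - 1]
    ab_t = sch.alpha_bars[t - 1]
    mean = (f_t - beta_t / np.sqrt(1 - ab_t) * eps_hat) / np.sqrt(alpha_t)
    if t == 1:
        return mean
    if rng is None:
        raise ValueError("rng required for stochastic steps (t > 1)")
    return mean + np.sqrt(beta_t) * rng.normal(size=f_t.shape)


def sample_cddpm(
    state: DiffusionModelState,
    n: int,
    label: int,
    beta_vecs: Optional[np.ndarray] = None,
    seed: int = 0,
) -> np.ndarray:
    """Ancestral sampling of n segments for one class, de-standardized.

    ``beta_vecs`` supplies the β conditioning per sample; by default they
    are resampled from the training β-vectors of the requested class.
    Returns an array (n, channels, time).
    """
    if not state.trained:
        raise RuntimeError("model state is untrained")
    if label not in CLASS_LABELS:
        raise ValueError(f"unknown class label {label!r}")
    if n == 0:
        return np.empty((0, *state.shape))
    rng = np.random.default_rng(seed)
    if beta_vecs is None:
        pool = state.train_betas_by_class[label]
        beta_vecs = pool[rng.integers(0, len(pool), size=n)]
    beta_vecs = np.asarray(beta_vecs, dtype=float)
    dim = state.shape[0] * state.shape[1]
    x = rng.normal(size=(n, dim))
    betas_std = (beta_vecs - state.beta_mean) / state.beta_std
    for t in range(state.schedule.T, 0, -1):
        x = denoise_step(x, t, label, beta_vecs, state, rng=rng if t > 1 else None)
    segs = x.reshape(n, *state.shape)
    return segs * state.channel_std[None, :, None] + state.channel_mean[None, :, None]


def augment_train_set(
    real_train: Sequence[TrialSegment],
    state: DiffusionModelState,
    test_segments: Sequence[TrialSegment] = (),
    seed: int = 0,
) -> list[TrialSegment]:
    """Double the training set with class-matched synthetic segments.

    Generates synthetic segments equal in number to the real training set,
    with the synthetic class proportions matching the real ones, and
    appends them (flagged) to the real data. The test set stays untouched
    and entirely real; a model state whose training keys overlap the test
    set raises a leakage error.
    """
    if not state.trained:
        raise RuntimeError("augmentation requires a trained model state")
    test_keys = {(s.subject_id, s.trial_index) for s in test_segments}
    if test_keys & set(state.train_keys):
        raise ValueError("leakage: diffusion model was trained on test segments")
    labels = np.array([s.label for s in real_train])
    n_total = len(real_train)
    counts = {c: int(np.sum(labels == c)) for c in CLASS_LABELS}
    # largest-remainder allocation keeps |synthetic| == |real|
    alloc = {c: counts[c] for c in CLASS_LABELS}
    assert sum(alloc.values()) == n_total
    out = list(real_train)
    rng = np.random.default_rng(seed)
    genders = [s.gender for s in real_train]
    k = 0
    for c in CLASS_LABELS:
        if alloc[c] == 0:
            continue
        samples = sample_cddpm(state, alloc[c], c, seed=int(rng.integers(0, 2**31 - 1)))
        for s in samples:
            out.append(
                TrialSegment(
                    subject_id=f"synthetic{k:04d}",
                    trial_index=0,
                    species=real_train[0].species,
                    data=s,
                    label=c,
                    gender=genders[k % len(genders)],
                    synthetic=True,
                )
            )
            k += 1
    return out
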
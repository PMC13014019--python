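"""Seeded synthetic fNIRS cohorts with known ground truth.

The study's clinical recordings are not deposited, so this module generates
cohorts with the statistical structure the downstream analysis assumes:
a two-trial mental-arithmetic block paradigm, HRF-convolved task responses
with group- and gender-specific per-channel amplitudes, physiological
oscillations (respiration, Mayer waves), slow drift, motion spikes,
occasional high-variability bad channels, and demographic/clinical metadata
drawn near the published cohort summaries. Raw dual-wavelength intensities
are produced by inverting the modified Beer–Lambert law, so the full
preprocessing chain can be exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .activation import HRFKernel, canonical_hrf, hrf_regressor
from .records import (
    BlockEvent,
    HemoRecording,
    NoiseConfig,
    OptodeConfig,
    ParadigmSpec,
    RawIntensityRecording,
    SubjectRecord,
)

__all__ = [
    "build_paradigm",
    "simulate_subject",
    "forward_intensity",
    "sample_cohort",
    "CohortEffect",
]


def build_paradigm(
    n_trials: int = 2, prompt_s: float = 2.0, block_s: float = 30.0, fs: float = 1.0
) -> ParadigmSpec:
    """Alternating MA/rest block paradigm.

    Each trial is prompt → MA block → prompt → rest block; with the default
    2-s prompts and 30-s blocks a trial lasts 64 s and the standard
    two-trial run 128 s.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if prompt_s < 0 or block_s <= 0:
        raise ValueError("durations must be positive (prompt may be 0)")
    events = []
    t = 0.0
    for _ in range(n_trials):
        if prompt_s > 0:
            events.append(BlockEvent("prompt", t, prompt_s))
        t += prompt_s
        events.append(BlockEvent("MA", t, block_s))
        t += block_s
        if prompt_s > 0:
            events.append(BlockEvent("prompt", t, prompt_s))
        t += prompt_s
        events.append(BlockEvent("rest", t, block_s))
        t += block_s
    return ParadigmSpec(sampling_rate=fs, block_events=tuple(events), n_trials=n_trials)


def _oscillation(rng: np.random.Generator, freq: float, amp: float, t: np.ndarray,
                 n_channels: int) -> np.ndarray:
    phases = rng.uniform(0, 2 * np.pi, size=n_channels)
    return amp * np.sin(2 * np.pi * freq * t[None, :] + phases[:, None])


def _spikes(rng: np.random.Generator, rate_per_min: float, amp: float,
            n_channels: int, n: int, fs: float) -> np.ndarray:
    out = np.zeros((n_channels, n))
    expected = rate_per_min * n / fs / 60.0
    for c in range(n_channels):
        k = rng.poisson(expected)
        for _ in range(k):
            i = rng.integers(0, n)
            sign = rng.choice([-1.0, 1.0])
            width = max(1, int(round(fs)))  # ~1-s transient
            j = min(n, i + width)
            out[c, i:j] += sign * amp
    return out


def simulate_subject(
    subject: SubjectRecord,
    paradigm: ParadigmSpec,
    noise: NoiseConfig,
    hrf: HRFKernel | None = None,
    seed: int | None = None,
    negative_pair: tuple[int, int] | None = None,
    pair_amplitude: float = 0.0,
    pair_freq_hz: float = 0.05,
) -> HemoRecording:
    """Ground-truth hemoglobin signals for one subject.

    ΔHbO per channel is the subject's true β times the HRF-convolved MA
    boxcar plus oscillatory, drift, spike and white noise. ΔHbR is the
    task component scaled by −r (the HbO/HbR anticorrelation, reproducing
    the negative deoxy-hemoglobin response) plus its own, r-scaled noise.

    ``negative_pair`` adds a shared slow oscillation with opposite sign to
    two channels — the anticorrelated "negative network" pair whose
    inverse synchrony the feature analysis exploits; ``pair_amplitude``
    (μmol/l) scales it. A seed is mandatory: simulations are reproducible
    by contract.
    """
    if seed is None:
        raise ValueError("simulate_subject requires an explicit seed")
    if subject.true_beta is None:
        raise ValueError("subject must carry a true_beta ground truth")
    if hrf is None:
        hrf = canonical_hrf(paradigm.sampling_rate)
    rng = np.random.default_rng(seed)
    fs = paradigm.sampling_rate
    n = paradigm.n_samples
    n_ch = len(subject.true_beta)
    t = np.arange(n) / fs

    task_shape = hrf_regressor(paradigm.boxcar("MA"), hrf)
    task = subject.true_beta[:, None] * task_shape[None, :]

    def noise_block(scale: float) -> np.ndarray:
        out = np.zeros((n_ch, n))
        if noise.respiratory_amp > 0:
            out += _oscillation(rng, noise.respiratory_freq_hz,
                                scale * noise.respiratory_amp, t, n_ch)
        if noise.mayer_amp > 0:
            out += _oscillation(rng, noise.mayer_freq_hz, scale * noise.mayer_amp, t, n_ch)
        if noise.drift_slope_per_s != 0:
            slopes = scale * noise.drift_slope_per_s * rng.uniform(-1, 1, size=n_ch)
            out += slopes[:, None] * t[None, :]
        if noise.white_sd > 0:
            out += rng.normal(0, scale * noise.white_sd, size=(n_ch, n))
        if noise.spike_rate_per_min > 0:
            out += _spikes(rng, noise.spike_rate_per_min, scale * noise.spike_amp,
                           n_ch, n, fs)
        return out

    r = noise.hbr_anticorrelation
    signal = task.copy()
    if negative_pair is not None and pair_amplitude > 0:
        i, j = negative_pair
        osc = pair_amplitude * np.sin(2 * np.pi * pair_freq_hz * t + rng.uniform(0, 2 * np.pi))
        signal[i] += osc
        signal[j] -= osc
    dHbO = signal + noise_block(1.0)
    dHbR = -r * signal + noise_block(r)
    return HemoRecording(
        dHbO=dHbO,
        dHbR=dHbR,
        dHbT=dHbO + dHbR,
        fs=fs,
        subject=subject,
        paradigm=paradigm,
        provenance=("simulated",),
    )


def forward_intensity(
    hemo: HemoRecording, optodes: OptodeConfig | None = None
) -> RawIntensityRecording:
    """Forward-model raw intensities from hemoglobin changes (MBLL inverse).

    I(λ, t) = I0(λ)·10^(−ΔA(λ, t)) with the attenuation change
    ΔA = d·DPF(λ)·[ε_HbO(λ)ΔHbO + ε_HbR(λ)ΔHbR] (d in cm, ΔHb in mmol/l).
    Converting the result back through the MBLL recovers the input to
    numerical precision.
    """
    if optodes is None:
        optodes = OptodeConfig(n_channels=hemo.n_channels)
    if not (np.all(np.isfinite(hemo.dHbO)) and np.all(np.isfinite(hemo.dHbR))):
        raise ValueError("hemoglobin signals must be finite")
    d_cm = optodes.source_detector_distance_mm / 10.0
    conc_mmol = np.stack([hemo.dHbO, hemo.dHbR]) / 1000.0  # μmol/l → mmol/l
    eps = optodes.extinction_matrix  # rows λ, cols (HbO, HbR)
    dpf = np.asarray(optodes.dpf)
    # ΔA[λ] = d·DPF(λ)·(ε·conc)[λ]
    dA = d_cm * dpf[:, None, None] * np.einsum("ws,sct->wct", eps, conc_mmol)
    I0 = optodes.baseline_intensity
    intensity = I0 * np.power(10.0, -dA)
    return RawIntensityRecording(
        subject=hemo.subject, paradigm=hemo.paradigm, intensity=intensity, optodes=optodes
    )


# ---------------------------------------------------------------------------
# Cohort sampling


@dataclass(frozen=True)
class CohortEffect:
    """Group- and gender-specific distributions of the simulated signals.

    ``mean_beta[(group, gender)]`` is the mean per-channel task β
    (μmol/l); ``beta_sd`` the between-subject SD. Defaults encode the
    study's qualitative activation contrasts: broad prefrontal activation
    in the normal group (strongest in females) and reduced, more focal
    activation in the ICPP group.

    ``negative_pair`` names the two channels carrying the anticorrelated
    "negative network" oscillation, with group-specific mean amplitude
    ``pair_amplitude`` (μmol/l) — stronger inverse synchrony in normal
    development, weakened by the condition. This is the structure the
    negative-correlation feature set keys on.
    """

    mean_beta: dict = field(default_factory=dict)
    beta_sd: float = 0.3
    n_channels: int = 10
    negative_pair: tuple[int, int] = (3, 6)
    pair_amplitude: dict = field(
        default_factory=lambda: {"normal": 0.35, "ICPP": 0.15}
    )
    pair_amplitude_sd: float = 0.05
    pair_freq_hz: float = 0.05

    def mean_for(self, group: str, gender: str) -> np.ndarray:
        if (group, gender) in self.mean_beta:
            return np.asarray(self.mean_beta[(group, gender)], dtype=float)
        base = np.full(self.n_channels, 0.6 if group == "normal" else 0.35)
        if group == "normal" and gender == "female":
            base = base + 0.1
        if group == "ICPP":
            base[[0, 4]] = 0.15  # channels 1 and 5 weakly recruited
        return base

    @classmethod
    def null(cls, n_channels: int = 10, beta_sd: float = 0.3) -> "CohortEffect":
        """No group or gender effect: identical distributions everywhere."""
        zero = {(g, s): np.full(n_channels, 0.4) for g in ("normal", "ICPP")
                for s in ("female", "male")}
        return cls(mean_beta=zero, beta_sd=beta_sd, n_channels=n_channels,
                   pair_amplitude={"normal": 0.25, "ICPP": 0.25})


# Published cohort summaries used to sample plausible metadata
_META = {
    "age": {"normal": (10.67, 2.51), "ICPP": (10.90, 2.37), "lo": 6.0, "hi": 16.0},
    "education": {"normal": (4.71, 2.48), "ICPP": (4.91, 2.32), "lo": 1.0, "hi": 12.0},
    "lh": (4.81, 3.47, 0.1, 20.0),
    "fsh": (4.76, 2.30, 0.1, 15.0),
    "estradiol": (118.58, 98.32, 5.0, 600.0),
    "testosterone": (12.75, 4.69, 0.5, 30.0),
}


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    for _ in range(100):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def _sample_subject(rng: np.random.Generator, sid: str, group: str, gender: str,
                    effect: CohortEffect) -> SubjectRecord:
    age = _trunc_normal(rng, *_META["age"][group], _META["age"]["lo"], _META["age"]["hi"])
    edu = _trunc_normal(rng, *_META["education"][group], _META["education"]["lo"],
                        _META["education"]["hi"])
    kwargs = {}
    if group == "ICPP":
        kwargs["lh_iu_l"] = _trunc_normal(rng, *_META["lh"])
        kwargs["fsh_iu_l"] = _trunc_normal(rng, *_META["fsh"])
        if gender == "female":
            kwargs["estradiol_pmol_l"] = _trunc_normal(rng, *_META["estradiol"])
        else:
            kwargs["testosterone_nmol_l"] = _trunc_normal(rng, *_META["testosterone"])
    beta = rng.normal(effect.mean_for(group, gender), effect.beta_sd)
    return SubjectRecord(subject_id=sid, group=group, gender=gender, age=age,
                         education=edu, true_beta=beta, **kwargs)


def sample_cohort(
    n_per_group: dict[tuple[str, str], int],
    effect: CohortEffect | None = None,
    noise: NoiseConfig | None = None,
    paradigm: ParadigmSpec | None = None,
    optodes: OptodeConfig | None = None,
    hrf: HRFKernel | None = None,
    seed: int | None = None,
) -> list[RawIntensityRecording]:
    """Simulate a full cohort of raw intensity recordings.

    ``n_per_group`` maps (group, gender) → subject count. Per-subject true
    β vectors are drawn from the group×gender effect distributions; bad
    channels are injected with probability ``bad_channel_prob`` by
    amplifying intensity variance past the quality-control threshold.
    """
    if seed is None:
        raise ValueError("sample_cohort requires an explicit seed")
    if not n_per_group or all(v == 0 for v in n_per_group.values()):
        raise ValueError("cohort must contain at least one subject")
    if any(v < 0 for v in n_per_group.values()):
        raise ValueError("subject counts must be >= 0")
    effect = effect or CohortEffect()
    noise = noise or NoiseConfig()
    paradigm = paradigm or build_paradigm()
    optodes = optodes or OptodeConfig(n_channels=effect.n_channels)
    hrf = hrf or canonical_hrf(paradigm.sampling_rate)
    root = np.random.SeedSequence(seed)
    recordings = []
    idx = 0
    for (group, gender), count in sorted(n_per_group.items()):
        for _ in range(count):
            sub_ss, sim_ss, bad_ss = root.spawn(3)
            rng = np.random.default_rng(sub_ss)
            sid = f"S{idx:04d}"
            subject = _sample_subject(rng, sid, group, gender, effect)
            pair_amp = max(
                0.0,
                rng.normal(effect.pair_amplitude.get(group, 0.0),
                           effect.pair_amplitude_sd),
            )
            hemo = simulate_subject(
                subject, paradigm, noise, hrf=hrf,
                seed=int(np.random.default_rng(sim_ss).integers(0, 2**31 - 1)),
                negative_pair=effect.negative_pair,
                pair_amplitude=pair_amp,
                pair_freq_hz=effect.pair_freq_hz,
            )
            raw = forward_intensity(hemo, optodes)
            if noise.bad_channel_prob > 0:
                brng = np.random.default_rng(bad_ss)
                for c in range(raw.n_channels):
                    if brng.uniform() < noise.bad_channel_prob:
                        # multiplicative lognormal wobble pushes CV > 15%
                        wob = brng.lognormal(0.0, 0.25, size=raw.intensity.shape[2])
                        raw.intensity[:, c, :] *= wob[None, :]
            recordings.append(raw)
            idx += 1
    return recordings
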
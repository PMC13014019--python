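"""Core data containers for block-design prefrontal fNIRS recordings.

The study design these containers describe: dual-wavelength (775/855 nm)
continuous-wave NIRS over 10 prefrontal channels sampled at 1 Hz, during a
two-trial mental-arithmetic (MA) paradigm in which each trial is a 2-s
prompt, a 30-s MA block, a 2-s prompt and a 30-s rest block.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "BlockEvent",
    "ParadigmSpec",
    "SubjectRecord",
    "OptodeConfig",
    "NoiseConfig",
    "RawIntensityRecording",
    "HemoRecording",
]

N_CHANNELS_DEFAULT = 10


@dataclass(frozen=True)
class BlockEvent:
    """One paradigm block: a prompt, a mental-arithmetic block or a rest block."""

    label: str  # "prompt" | "MA" | "rest"
    onset_s: float
    duration_s: float

    def __post_init__(self) -> None:
        if self.label not in ("prompt", "MA", "rest"):
            raise ValueError(f"unknown block label {self.label!r}")
        if self.duration_s < 0:
            raise ValueError("block duration must be >= 0")
        if self.onset_s < 0:
            raise ValueError("block onset must be >= 0")


@dataclass(frozen=True)
class ParadigmSpec:
    """Block-design paradigm: sampling rate, ordered non-overlapping events.

    Defaults describe the two-trial mental-arithmetic protocol at 1 Hz.
    """

    sampling_rate: float = 1.0
    block_events: tuple[BlockEvent, ...] = ()
    n_trials: int = 2

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        events = sorted(self.block_events, key=lambda e: e.onset_s)
        for a, b in zip(events, events[1:]):
            if a.onset_s + a.duration_s > b.onset_s + 1e-9:
                raise ValueError(
                    f"overlapping events: {a.label}@{a.onset_s}s and {b.label}@{b.onset_s}s"
                )
        object.__setattr__(self, "block_events", tuple(events))

    @property
    def duration_s(self) -> float:
        if not self.block_events:
            return 0.0
        last = self.block_events[-1]
        return last.onset_s + last.duration_s

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sampling_rate))

    def events(self, label: str) -> list[BlockEvent]:
        return [e for e in self.block_events if e.label == label]

    def boxcar(self, label: str) -> np.ndarray:
        """0/1 indicator of the given block type, sampled at ``sampling_rate``."""
        out = np.zeros(self.n_samples)
        for e in self.events(label):
            i0 = int(round(e.onset_s * self.sampling_rate))
            i1 = int(round((e.onset_s + e.duration_s) * self.sampling_rate))
            out[i0:i1] = 1.0
        return out


@dataclass
class SubjectRecord:
    """One participant: group/gender metadata, clinical markers, ground truth.

    Clinical markers (LH, FSH, estradiol, testosterone) are archived for the
    ICPP group only; ``true_beta`` is the per-channel task amplitude in
    μmol/l that the simulator injected (None for real data).
    """

    subject_id: str
    group: str  # "normal" | "ICPP"
    gender: str  # "female" | "male"
    age: float
    education: float
    lh_iu_l: Optional[float] = None
    fsh_iu_l: Optional[float] = None
    estradiol_pmol_l: Optional[float] = None
    testosterone_nmol_l: Optional[float] = None
    true_beta: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.group not in ("normal", "ICPP"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.gender not in ("female", "male"):
            raise ValueError(f"unknown gender {self.gender!r}")
        if self.group == "normal":
            for name in ("lh_iu_l", "fsh_iu_l", "estradiol_pmol_l", "testosterone_nmol_l"):
                if getattr(self, name) is not None:
                    raise ValueError("clinical markers are archived for ICPP subjects only")
        if self.true_beta is not None:
            self.true_beta = np.asarray(self.true_beta, dtype=float)


# Molar extinction coefficients, l·mmol⁻¹·cm⁻¹, interpolated from standard
# compiled hemoglobin spectra at the device wavelengths.
EXTINCTION_DEFAULT = {
    775: {"HbO": 0.681, "HbR": 1.073},
    855: {"HbO": 1.058, "HbR": 0.781},
}


@dataclass(frozen=True)
class OptodeConfig:
    """Optode geometry and optics for the dual-wavelength measurement.

    ``source_detector_distance_mm`` is the geometric separation (30 mm on
    the device); ``dpf`` the differential pathlength factor per wavelength;
    ``extinction[w][species]`` molar extinction in l·mmol⁻¹·cm⁻¹.
    """

    wavelengths_nm: tuple[int, int] = (775, 855)
    source_detector_distance_mm: float = 30.0
    dpf: tuple[float, float] = (6.0, 6.0)
    extinction: dict = field(
        default_factory=lambda: {w: dict(EXTINCTION_DEFAULT[w]) for w in (775, 855)}
    )
    n_channels: int = N_CHANNELS_DEFAULT
    baseline_intensity: float = 1000.0

    def __post_init__(self) -> None:
        if self.source_detector_distance_mm <= 0:
            raise ValueError("source-detector distance must be positive")
        if any(d <= 0 for d in self.dpf):
            raise ValueError("DPF must be positive")
        if abs(self.extinction_determinant) < 1e-12:
            raise ValueError("extinction coefficient matrix is singular")

    @property
    def extinction_matrix(self) -> np.ndarray:
        """2×2 matrix: rows wavelengths, columns (HbO, HbR)."""
        w1, w2 = self.wavelengths_nm
        return np.array(
            [
                [self.extinction[w1]["HbO"], self.extinction[w1]["HbR"]],
                [self.extinction[w2]["HbO"], self.extinction[w2]["HbR"]],
            ]
        )

    @property
    def extinction_determinant(self) -> float:
        m = np.array(
            [
                [self.extinction[w]["HbO"], self.extinction[w]["HbR"]]
                for w in self.wavelengths_nm
            ]
        )
        return float(m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0])


@dataclass(frozen=True)
class NoiseConfig:
    """Physiological and instrumental noise mixed into simulated signals.

    Frequencies are in Hz and must lie below the Nyquist rate (0.5 Hz at
    the device's 1 Hz sampling); amplitudes are in μmol/l. Cardiac
    pulsation (>0.5 Hz) cannot be represented at this rate and is folded
    into the white-noise term. ``spike_rate_per_min`` controls motion
    artifacts; ``bad_channel_prob`` the chance a channel's raw intensity is
    made high-variance so that quality screening flags it.
    """

    respiratory_freq_hz: float = 0.25
    respiratory_amp: float = 0.05
    mayer_freq_hz: float = 0.1
    mayer_amp: float = 0.08
    drift_slope_per_s: float = 0.002
    white_sd: float = 0.1
    spike_rate_per_min: float = 0.0
    spike_amp: float = 2.0
    bad_channel_prob: float = 0.0
    hbr_anticorrelation: float = 0.3

    def __post_init__(self) -> None:
        for name in ("respiratory_amp", "mayer_amp", "white_sd", "spike_amp",
                     "spike_rate_per_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        nyquist = 0.5
        if self.respiratory_freq_hz >= nyquist or self.mayer_freq_hz >= nyquist:
            raise ValueError("oscillation frequencies must be below Nyquist (0.5 Hz)")
        if not 0.0 <= self.bad_channel_prob <= 1.0:
            raise ValueError("bad_channel_prob must be in [0, 1]")
        if not 0.0 < self.hbr_anticorrelation < 1.0:
            raise ValueError("hbr_anticorrelation must be in (0, 1)")

    @classmethod
    def silent(cls) -> "NoiseConfig":
        """Noise-free configuration, for parameter-recovery tests."""
        return cls(respiratory_amp=0.0, mayer_amp=0.0, drift_slope_per_s=0.0,
                   white_sd=0.0, spike_rate_per_min=0.0, bad_channel_prob=0.0)


@dataclass
class RawIntensityRecording:
    """Detected light intensity, shape [wavelength × channel × time], a.u."""

    subject: SubjectRecord
    paradigm: ParadigmSpec
    intensity: np.ndarray
    optodes: OptodeConfig

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3:
            raise ValueError("intensity must be [wavelength × channel × time]")
        if self.intensity.shape[0] != len(self.optodes.wavelengths_nm):
            raise ValueError("wavelength axis mismatch")
        if self.intensity.shape[2] != self.paradigm.n_samples:
            raise ValueError("time axis does not match paradigm duration")
        if not np.all(self.intensity > 0):
            raise ValueError("intensities must be strictly positive")

    @property
    def n_channels(self) -> int:
        return self.intensity.shape[1]


@dataclass
class HemoRecording:
    """Relative hemoglobin concentration changes, [channel × time], μmol/l.

    ``dHbT`` always equals ``dHbO + dHbR`` elementwise; ``provenance`` is
    the ordered list of processing steps that produced the arrays.
    """

    dHbO: np.ndarray
    dHbR: np.ndarray
    dHbT: np.ndarray
    fs: float
    subject: Optional[SubjectRecord] = None
    paradigm: Optional[ParadigmSpec] = None
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.dHbO = np.asarray(self.dHbO, dtype=float)
        self.dHbR = np.asarray(self.dHbR, dtype=float)
        self.dHbT = np.asarray(self.dHbT, dtype=float)
        if not (self.dHbO.shape == self.dHbR.shape == self.dHbT.shape):
            raise ValueError("species arrays must share one [channel × time] shape")
        if not np.allclose(self.dHbT, self.dHbO + self.dHbR, atol=1e-8):
            raise ValueError("dHbT must equal dHbO + dHbR")
        for a in (self.dHbO, self.dHbR):
            if not np.all(np.isfinite(a)):
                raise ValueError("hemoglobin signals must be finite")

    @property
    def n_channels(self) -> int:
        return self.dHbO.shape[0]

    @property
    def n_samples(self) -> int:
        return self.dHbO.shape[1]

    def species(self, name: str) -> np.ndarray:
        try:
            return {"HbO": self.dHbO, "HbR": self.dHbR, "HbT": self.dHbT}[name]
        except KeyError:
            raise ValueError(f"unknown hemoglobin species {name!r}") from None

    def with_species(self, dHbO: np.ndarray, dHbR: np.ndarray, step: str) -> "HemoRecording":
        return replace(
            self,
            dHbO=dHbO,
            dHbR=dHbR,
            dHbT=dHbO + dHbR,
            provenance=self.provenance + (step,),
        )
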
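"""Empirical mode decomposition by envelope sifting.

Decomposes a 1-D signal into intrinsic mode functions (IMFs) plus a
residue. Each sifting pass interpolates cubic-spline envelopes through the
local maxima and minima (end extrema mirrored to tame boundary swings) and
subtracts the envelope mean; sifting stops on a Cauchy-type criterion
(normalized squared change below ``sd_threshold``, default 0.2).
Decomposition stops when the residue has too few extrema to envelope or
the IMF cap is reached. Completeness — IMFs plus residue summing back to
the input — holds exactly by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = ["EMDConfig", "EMDResult", "emd_decompose"]


@dataclass(frozen=True)
class EMDConfig:
    sd_threshold: float = 0.2
    max_imfs: int = 10
    max_siftings: int = 50


@dataclass
class EMDResult:
    imfs: list  # list of 1-D arrays, fastest mode first
    residue: np.ndarray

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        out = self.residue.copy()
        for imf in self.imfs:
            out = out + imf
        return out


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima (plateaus take their midpoint)."""
    d = np.sign(np.diff(x))
    # collapse zero slopes so flat plateaus register a single turning point
    nz = np.flatnonzero(d != 0)
    maxima, minima = [], []
    for k in range(len(nz) - 1):
        i, j = nz[k], nz[k + 1]
        if d[i] > 0 and d[j] < 0:
            maxima.append((i + 1 + j) // 2)
        elif d[i] < 0 and d[j] > 0:
            minima.append((i + 1 + j) // 2)
    return np.asarray(maxima, dtype=int), np.asarray(minima, dtype=int)


def _envelope(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Cubic-spline envelope through extrema, with mirrored end extrema."""
    n = len(x)
    t = idx.astype(float)
    v = x[idx]
    # mirror the first/last extremum beyond the signal ends
    t_ext = np.concatenate([[-t[0] if t[0] > 0 else -1.0], t, [2 * (n - 1) - t[-1] if t[-1] < n - 1 else n]])
    v_ext = np.concatenate([[v[0]], v, [v[-1]]])
    cs = CubicSpline(t_ext, v_ext)
    return cs(np.arange(n, dtype=float))


def _sift_once(x: np.ndarray) -> np.ndarray | None:
    maxima, minima = _local_extrema(x)
    if len(maxima) < 2 or len(minima) < 2:
        return None
    upper = _envelope(x, maxima)
    lower = _envelope(x, minima)
    return x - 0.5 * (upper + lower)


def emd_decompose(signal: np.ndarray, config: EMDConfig | None = None) -> EMDResult:
    """Decompose ``signal`` into IMFs and a residue.

    Monotone (or extremum-poor) inputs yield zero IMFs with the residue
    equal to the signal.
    """
    config = config or EMDConfig()
    x = np.asarray(signal, dtype=float).ravel()
    if len(x) < 8:
        raise ValueError("EMD needs a signal of length >= 8")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal must be finite")
    residue = x.copy()
    imfs: list[np.ndarray] = []
    while len(imfs) < config.max_imfs:
        h = _sift_once(residue)
        if h is None:
            break
        for _ in range(config.max_siftings):
            h_new = _sift_once(h)
            if h_new is None:
                break
            denom = np.sum(h**2)
            sd = np.sum((h - h_new) ** 2) / denom if denom > 0 else 0.0
            h = h_new
            if sd < config.sd_threshold:
                break
        imfs.append(h)
        residue = residue - h
        maxima, minima = _local_extrema(residue)
        if len(maxima) + len(minima) < 2:
            break
    return EMDResult(imfs=imfs, residue=residue)
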
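"""Trial segmentation and the five hemoglobin feature sets.

From each preprocessed recording, trials are cut as the 30-s
mental-arithmetic block concatenated with its 30-s rest block (prompts
excluded, 60 samples at 1 Hz). Five feature sets are built per trial:

- **A** — time-domain statistics (mean, variance, skewness, kurtosis) of
  the two channels that most frequently show the strongest negative
  Pearson correlation across training trials (8 columns);
- **B** — the first 3 principal-component scores of every channel, PCA
  fitted across training trials (30 columns);
- **C** — A concatenated with the pair channels' first 3 PCs (14 columns);
- **D** — per channel, the first principal-component score of each of the
  first 3 intrinsic mode functions from empirical mode decomposition,
  aligned by IMF index and zero-padded when fewer exist (30 columns);
- **E** — the per-channel task β from a GLM fitted to the trial's own
  60-s window (10 columns).

All data-dependent transforms (channel pair, PCA bases) are fitted on the
training split only and frozen for test-time application.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .activation import HRFKernel, build_design, canonical_hrf, fit_glm
from .emd import EMDConfig, emd_decompose
from .records import HemoRecording, ParadigmSpec
from .synthcohort import build_paradigm

__all__ = [
    "TrialSegment",
    "ChannelPair",
    "FeatureMatrix",
    "TimeStats",
    "segment_trials",
    "select_negative_pair",
    "timedomain_stats",
    "channel_pca",
    "FeatureExtractor",
    "extract_features",
    "FEATURE_SET_WIDTHS",
]

LABEL_BY_GROUP = {"normal": 0, "ICPP": 1}
FEATURE_SET_WIDTHS = {"A": 8, "B": 30, "C": 14, "D": 30, "E": 10}


@dataclass
class TrialSegment:
    """One 60-s trial window of one hemoglobin species, [channel × time]."""

    subject_id: str
    trial_index: int
    species: str
    data: np.ndarray
    label: int  # 1 = ICPP, 0 = normal
    gender: str
    synthetic: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("segment data must be [channel × time]")


@dataclass(frozen=True)
class ChannelPair:
    """The selected negatively-correlated channel pair (0-based, i < j)."""

    i: int
    j: int
    selection_frequency: float = float("nan")
    mean_correlation: float = float("nan")

    def __post_init__(self) -> None:
        if self.i >= self.j:
            raise ValueError("pair must satisfy i < j")


@dataclass
class FeatureMatrix:
    """Trials × features table for one feature set."""

    values: np.ndarray
    columns: tuple[str, ...]
    set_id: str
    labels: np.ndarray
    subject_ids: tuple[str, ...]
    genders: tuple[str, ...]
    pair: Optional[ChannelPair] = None

    def __post_init__(self) -> None:
        if self.values.shape[1] != len(self.columns):
            raise ValueError("column names do not match value width")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.columns))
        df.insert(0, "subject_id", self.subject_ids)
        df.insert(1, "label", self.labels)
        df.insert(2, "gender", self.genders)
        return df


def segment_trials(
    hemo: HemoRecording, paradigm: ParadigmSpec | None = None, species: str = "HbO"
) -> list[TrialSegment]:
    """Cut one segment per trial: MA block samples followed by rest samples."""
    paradigm = paradigm or hemo.paradigm
    if paradigm is None:
        raise ValueError("paradigm required (none attached to recording)")
    if hemo.n_samples != paradigm.n_samples:
        raise ValueError(
            f"recording length {hemo.n_samples} does not match paradigm {paradigm.n_samples}"
        )
    data = hemo.species(species)
    fs = paradigm.sampling_rate
    ma_events = paradigm.events("MA")
    rest_events = paradigm.events("rest")
    if len(ma_events) != len(rest_events):
        raise ValueError("paradigm must pair each MA block with a rest block")
    subject = hemo.subject
    sid = subject.subject_id if subject is not None else "unknown"
    label = LABEL_BY_GROUP.get(subject.group, -1) if subject is not None else -1
    gender = subject.gender if subject is not None else "unknown"
    segments = []
    for k, (ma, rest) in enumerate(zip(ma_events, rest_events)):
        i0 = int(round(ma.onset_s * fs))
        i1 = int(round((ma.onset_s + ma.duration_s) * fs))
        j0 = int(round(rest.onset_s * fs))
        j1 = int(round((rest.onset_s + rest.duration_s) * fs))
        seg = np.concatenate([data[:, i0:i1], data[:, j0:j1]], axis=1)
        segments.append(
            TrialSegment(subject_id=sid, trial_index=k, species=species, data=seg,
                         label=label, gender=gender)
        )
    return segments


def _most_negative_pair(seg: np.ndarray) -> tuple[tuple[int, int], float] | None:
    """Index pair with the most negative Pearson correlation in one segment."""
    sd = seg.std(axis=1)
    valid = np.flatnonzero(sd > 0)
    if len(valid) < len(sd):
        warnings.warn("constant channel excluded from pair selection")
    if len(valid) < 2:
        return None
    corr = np.corrcoef(seg[valid])
    best = None
    for a in range(len(valid)):
        for b in range(a + 1, len(valid)):
            r = corr[a, b]
            if best is None or r < best[1]:
                best = ((int(valid[a]), int(valid[b])), float(r))
    return best


def select_negative_pair(train_segments: list[TrialSegment]) -> ChannelPair:
    """Modal most-negative-correlation channel pair across training trials.

    Per trial, the full 10×10 Pearson matrix is computed and the most
    negative off-diagonal entry recorded; the pair chosen most often wins.
    Ties break toward the more negative mean correlation at selection, then
    lexicographically.
    """
    if not train_segments:
        raise ValueError("pair selection needs at least one training segment")
    votes: Counter = Counter()
    corr_sum: dict[tuple[int, int], float] = {}
    for seg in train_segments:
        hit = _most_negative_pair(seg.data)
        if hit is None:
            continue
        pair, r = hit
        votes[pair] += 1
        corr_sum[pair] = corr_sum.get(pair, 0.0) + r
    if not votes:
        raise ValueError("no valid channel pair (all channels constant?)")
    ranked = sorted(
        votes.items(),
        key=lambda kv: (-kv[1], corr_sum[kv[0]] / kv[1], kv[0]),
    )
    (i, j), count = ranked[0]
    return ChannelPair(
        i=i, j=j,
        selection_frequency=count / len(train_segments),
        mean_correlation=corr_sum[(i, j)] / count,
    )


@dataclass(frozen=True)
class TimeStats:
    mean: float
    variance: float
    skewness: float
    kurtosis: float  # Fisher excess: 0 for a normal population
    degenerate: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([self.mean, self.variance, self.skewness, self.kurtosis])


def timedomain_stats(x: np.ndarray) -> TimeStats:
    """Sample mean, variance (ddof 1), moment skewness g1, excess kurtosis g2.

    Constant signals report zero skewness/kurtosis with the degenerate flag
    set.
    """
    x = np.asarray(x, dtype=float).ravel()
    if len(x) < 4:
        raise ValueError("time-domain statistics need length >= 4")
    mean = float(x.mean())
    var = float(x.var(ddof=1))
    if var == 0:
        return TimeStats(mean=mean, variance=0.0, skewness=0.0, kurtosis=0.0,
                         degenerate=True)
    m2 = float(np.mean((x - mean) ** 2))
    m3 = float(np.mean((x - mean) ** 3))
    m4 = float(np.mean((x - mean) ** 4))
    return TimeStats(
        mean=mean,
        variance=var,
        skewness=m3 / m2**1.5,
        kurtosis=m4 / m2**2 - 3.0,
    )


def channel_pca(train_segments: list[TrialSegment], channel: int, k: int = 3) -> tuple[PCA, np.ndarray]:
    """PCA over trials of one channel's time course.

    Rows are trials, columns time samples; data are mean-centered by the
    fit. Returns the fitted basis and the training scores (trials × k);
    the basis applies unchanged to held-out trials.
    """
    X = np.stack([seg.data[channel] for seg in train_segments])
    if X.shape[0] < k:
        raise ValueError(f"need >= {k} training trials for {k} components")
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < k:
        raise ValueError(f"requested {k} components exceed data rank")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    return pca, scores


class FeatureExtractor:
    """Fit-on-train / apply-anywhere builder for one feature set.

    ``fit`` estimates every data-dependent ingredient — the negative
    channel pair (A, C), per-channel PCA bases (B, C), per-IMF PCA bases
    (D) — from the training segments only. ``transform`` applies the frozen
    state and never refits.
    """

    def __init__(
        self,
        set_id: str,
        k_pcs: int = 3,
        k_imfs: int = 3,
        emd_config: EMDConfig | None = None,
        hrf: HRFKernel | None = None,
        fs: float = 1.0,
    ) -> None:
        if set_id not in FEATURE_SET_WIDTHS:
            raise ValueError(f"unknown feature set {set_id!r}")
        self.set_id = set_id
        self.k_pcs = k_pcs
        self.k_imfs = k_imfs
        self.emd_config = emd_config or EMDConfig()
        self.fs = fs
        self.hrf = hrf or canonical_hrf(fs)
        self.pair: ChannelPair | None = None
        self.pca_bases: dict[int, PCA] = {}
        self.imf_bases: dict[tuple[int, int], PCA] = {}
        self._trial_design = None
        self._fitted = False
        self._train_keys: frozenset = frozenset()

    # -- fitting -----------------------------------------------------------

    def fit(self, train_segments: list[TrialSegment]) -> "FeatureExtractor":
        if not train_segments:
            raise ValueError("cannot fit on an empty training set")
        n_ch = train_segments[0].data.shape[0]
        if self.set_id in ("A", "C"):
            self.pair = select_negative_pair(train_segments)
        if self.set_id == "B":
            for c in range(n_ch):
                self.pca_bases[c], _ = channel_pca(train_segments, c, self.k_pcs)
        if self.set_id == "C":
            for c in (self.pair.i, self.pair.j):
                self.pca_bases[c], _ = channel_pca(train_segments, c, self.k_pcs)
        if self.set_id == "D":
            imf_stacks = self._imf_stacks(train_segments, n_ch)
            for key, X in imf_stacks.items():
                if np.allclose(X, 0):
                    # IMF index absent in every training trial: score is 0
                    self.imf_bases[key] = None
                    continue
                pca = PCA(n_components=1, svd_solver="full")
                pca.fit(X)
                self.imf_bases[key] = pca
        if self.set_id == "E":
            n_t = train_segments[0].data.shape[1]
            block_s = n_t / (2 * self.fs)
            trial_paradigm = build_paradigm(n_trials=1, prompt_s=0.0,
                                            block_s=block_s, fs=self.fs)
            self._trial_design = build_design(trial_paradigm, self.hrf)
        self._train_keys = frozenset((s.subject_id, s.trial_index) for s in train_segments)
        self._fitted = True
        return self

    def _imf_stacks(self, segments: list[TrialSegment], n_ch: int) -> dict:
        n_t = segments[0].data.shape[1]
        stacks: dict[tuple[int, int], list[np.ndarray]] = {
            (c, k): [] for c in range(n_ch) for k in range(self.k_imfs)
        }
        for seg in segments:
            for c in range(n_ch):
                res = emd_decompose(seg.data[c], self.emd_config)
                for k in range(self.k_imfs):
                    imf = res.imfs[k] if k < res.n_imfs else np.zeros(n_t)
                    stacks[(c, k)].append(imf)
        return {key: np.stack(v) for key, v in stacks.items()}

    # -- application -------------------------------------------------------

    def transform(self, segments: list[TrialSegment]) -> FeatureMatrix:
        if not self._fitted:
            raise RuntimeError("FeatureExtractor.transform called before fit")
        rows = [self._row(seg) for seg in segments]
        values = np.stack([r for r, _ in rows])
        columns = rows[0][1]
        return FeatureMatrix(
            values=values,
            columns=tuple(columns),
            set_id=self.set_id,
            labels=np.array([s.label for s in segments]),
            subject_ids=tuple(s.subject_id for s in segments),
            genders=tuple(s.gender for s in segments),
            pair=self.pair,
        )

    def fit_transform(self, train_segments: list[TrialSegment]) -> FeatureMatrix:
        return self.fit(train_segments).transform(train_segments)

    def _row(self, seg: TrialSegment) -> tuple[np.ndarray, list[str]]:
        if self.set_id == "A":
            return self._row_stats(seg)
        if self.set_id == "B":
            return self._row_pca(seg, sorted(self.pca_bases))
        if self.set_id == "C":
            sv, sc = self._row_stats(seg)
            pv, pc = self._row_pca(seg, [self.pair.i, self.pair.j])
            return np.concatenate([sv, pv]), sc + pc
        if self.set_id == "D":
            return self._row_emd(seg)
        if self.set_id == "E":
            return self._row_beta(seg)
        raise AssertionError  # pragma: no cover

    def _row_stats(self, seg: TrialSegment) -> tuple[np.ndarray, list[str]]:
        vals, cols = [], []
        for c in (self.pair.i, self.pair.j):
            st = timedomain_stats(seg.data[c])
            vals.append(st.as_array())
            cols += [f"ch{c + 1}_{name}" for name in ("mean", "var", "skew", "kurt")]
        return np.concatenate(vals), cols

    def _row_pca(self, seg: TrialSegment, channels: list[int]) -> tuple[np.ndarray, list[str]]:
        vals, cols = [], []
        for c in channels:
            scores = self.pca_bases[c].transform(seg.data[c][None, :])[0]
            vals.append(scores)
            cols += [f"ch{c + 1}_pc{k + 1}" for k in range(self.k_pcs)]
        return np.concatenate(vals), cols

    def _row_emd(self, seg: TrialSegment) -> tuple[np.ndarray, list[str]]:
        n_ch, n_t = seg.data.shape
        vals, cols = [], []
        for c in range(n_ch):
            res = emd_decompose(seg.data[c], self.emd_config)
            for k in range(self.k_imfs):
                imf = res.imfs[k] if k < res.n_imfs else np.zeros(n_t)
                pca = self.imf_bases[(c, k)]
                score = 0.0 if pca is None else pca.transform(imf[None, :])[0, 0]
                vals.append(score)
                cols.append(f"ch{c + 1}_imf{k + 1}_pc1")
        return np.asarray(vals), cols

    def _row_beta(self, seg: TrialSegment) -> tuple[np.ndarray, list[str]]:
        res = fit_glm(seg.data, self._trial_design)
        beta = res.beta_for("MA")
        cols = [f"ch{c + 1}_beta" for c in range(len(beta))]
        return beta, cols


def extract_features(
    segments: list[TrialSegment], set_id: str, fitted_state: FeatureExtractor
) -> FeatureMatrix:
    """Apply a fitted extractor to (train or held-out) segments."""
    if fitted_state.set_id != set_id:
        raise ValueError(f"extractor was fitted for set {fitted_state.set_id!r}, not {set_id!r}")
    return fitted_state.transform(segments)
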
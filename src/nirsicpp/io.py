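"""Reading and writing recordings: long-format CSV and a SNIRF-style HDF5.

The CSV interchange format is long/tidy: one row per (subject, wavelength,
channel, time sample) with columns ``subject_id, group, gender,
wavelength_nm, channel, t_s, intensity`` plus one metadata CSV per cohort.
The HDF5 container mirrors the SNIRF layout
(``nirs/data1/dataTimeSeries`` with a ``measurementList``).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .preprocess import QCReport
from .records import (
    HemoRecording,
    OptodeConfig,
    ParadigmSpec,
    RawIntensityRecording,
    SubjectRecord,
)

__all__ = [
    "cohort_to_csv",
    "cohort_from_csv",
    "hemo_to_csv",
    "qc_report_to_json",
    "write_snirf_like",
    "read_snirf_like",
]

_MARKER_COLS = ["lh_iu_l", "fsh_iu_l", "estradiol_pmol_l", "testosterone_nmol_l"]


def cohort_to_csv(recordings: list[RawIntensityRecording], data_path, meta_path) -> None:
    """Write a cohort as a long-format intensity CSV plus a metadata CSV."""
    frames = []
    meta_rows = []
    for rec in recordings:
        s = rec.subject
        wls = rec.optodes.wavelengths_nm
        n_ch, n_t = rec.intensity.shape[1], rec.intensity.shape[2]
        t_s = np.arange(n_t) / rec.paradigm.sampling_rate
        for wi, wl in enumerate(wls):
            for c in range(n_ch):
                frames.append(pd.DataFrame({
                    "subject_id": s.subject_id,
                    "group": s.group,
                    "gender": s.gender,
                    "wavelength_nm": wl,
                    "channel": c + 1,
                    "t_s": t_s,
                    "intensity": rec.intensity[wi, c],
                }))
        row = {"subject_id": s.subject_id, "group": s.group, "gender": s.gender,
               "age": s.age, "education": s.education}
        for col in _MARKER_COLS:
            row[col] = getattr(s, col)
        meta_rows.append(row)
    pd.concat(frames, ignore_index=True).to_csv(data_path, index=False)
    pd.DataFrame(meta_rows).to_csv(meta_path, index=False)


def cohort_from_csv(
    data_path, meta_path, paradigm: ParadigmSpec, optodes: OptodeConfig
) -> list[RawIntensityRecording]:
    """Rebuild recordings from the long CSV pair (paradigm/optodes supplied)."""
    data = pd.read_csv(data_path)
    meta = pd.read_csv(meta_path).set_index("subject_id")
    recordings = []
    for sid, sub_df in data.groupby("subject_id", sort=True):
        m = meta.loc[sid]
        kwargs = {}
        for col in _MARKER_COLS:
            v = m[col]
            if pd.notna(v):
                kwargs[col] = float(v)
        subject = SubjectRecord(
            subject_id=str(sid), group=str(m["group"]), gender=str(m["gender"]),
            age=float(m["age"]), education=float(m["education"]), **kwargs,
        )
        wls = list(optodes.wavelengths_nm)
        channels = sorted(sub_df["channel"].unique())
        n_t = sub_df["t_s"].nunique()
        I = np.empty((len(wls), len(channels), n_t))
        for wi, wl in enumerate(wls):
            for ci, ch in enumerate(channels):
                sel = sub_df[(sub_df["wavelength_nm"] == wl) & (sub_df["channel"] == ch)]
                I[wi, ci] = sel.sort_values("t_s")["intensity"].to_numpy()
        recordings.append(RawIntensityRecording(
            subject=subject, paradigm=paradigm, intensity=I, optodes=optodes))
    return recordings


def hemo_to_csv(hemo: HemoRecording, path) -> None:
    """Write ΔHbO/ΔHbR/ΔHbT as a long CSV (subject, channel, t_s, species columns)."""
    sid = hemo.subject.subject_id if hemo.subject is not None else "unknown"
    t_s = np.arange(hemo.n_samples) / hemo.fs
    frames = []
    for c in range(hemo.n_channels):
        frames.append(pd.DataFrame({
            "subject_id": sid, "channel": c + 1, "t_s": t_s,
            "dHbO": hemo.dHbO[c], "dHbR": hemo.dHbR[c], "dHbT": hemo.dHbT[c],
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def qc_report_to_json(report: QCReport, path) -> None:
    Path(path).write_text(json.dumps({
        "cv_percent": [float(v) for v in report.cv],
        "bad_channels": list(report.bad_channels),
        "subject_discarded": bool(report.subject_discarded),
        "threshold_percent": float(report.threshold),
    }, indent=2))


def write_snirf_like(rec: RawIntensityRecording, path) -> None:
    """Write one recording to an HDF5 container mirroring the SNIRF layout."""
    n_wl, n_ch, n_t = rec.intensity.shape
    with h5py.File(path, "w") as f:
        nirs = f.create_group("nirs")
        data1 = nirs.create_group("data1")
        # columns: one measurement per (channel, wavelength)
        ts = rec.intensity.transpose(2, 1, 0).reshape(n_t, n_ch * n_wl)
        data1.create_dataset("dataTimeSeries", data=ts)
        data1.create_dataset("time", data=np.arange(n_t) / rec.paradigm.sampling_rate)
        k = 1
        for c in range(n_ch):
            for wi in range(n_wl):
                ml = data1.create_group(f"measurementList{k}")
                ml.create_dataset("sourceIndex", data=c + 1)
                ml.create_dataset("detectorIndex", data=c + 1)
                ml.create_dataset("wavelengthIndex", data=wi + 1)
                k += 1
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID", data=rec.subject.subject_id)
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.array(rec.optodes.wavelengths_nm, float))


def read_snirf_like(
    path, subject: SubjectRecord, paradigm: ParadigmSpec, optodes: OptodeConfig
) -> RawIntensityRecording:
    with h5py.File(path, "r") as f:
        ts = f["nirs/data1/dataTimeSeries"][()]
        n_wl = len(f["nirs/probe/wavelengths"][()])
        n_t = ts.shape[0]
        n_ch = ts.shape[1] // n_wl
        I = ts.reshape(n_t, n_ch, n_wl).transpose(2, 1, 0)
    return RawIntensityRecording(subject=subject, paradigm=paradigm, intensity=I,
                                 optodes=optodes)
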
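"""Cohort archive: plain-CSV serialization of sessions, waveforms,
annotations and survival records (UTF-8, header row, '.' decimal)."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import Annotations, MARK_NAMES, Nerve, Session, SurvivalRecord

__all__ = ["write_cohort", "read_cohort", "write_survival", "read_survival"]

WAVEFORM_COLUMNS = ["patient_id", "session_id", "nerve", "stim_index", "sampling_rate_hz",
                    "stim_amplitude_ma", "stim_duration_ms", "sample_index", "voltage_mv"]
SESSION_COLUMNS = ["patient_id", "session_id", "age_years", "sex", "bmi", "source", "label"]


def write_cohort(sessions: Sequence[Session], out_dir: str | Path,
                 survival: Optional[Sequence[SurvivalRecord]] = None) -> Path:
    """Write ``waveforms.csv``, ``sessions.csv``, ``annotations.csv`` (and
    ``survival.csv`` if records are given) under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    chunks = []
    for s in sessions:
        for nerve, wfs in s.waveforms.items():
            for wf in wfs:
                n = wf.n_samples
                chunks.append(pd.DataFrame({
                    "patient_id": np.repeat(s.patient_id, n),
                    "session_id": np.repeat(s.session_id, n),
                    "nerve": np.repeat(nerve.value, n),
                    "stim_index": np.repeat(wf.stim_index, n),
                    "sampling_rate_hz": np.repeat(wf.sampling_rate, n),
                    "stim_amplitude_ma": np.repeat(wf.stim_amplitude, n),
                    "stim_duration_ms": np.repeat(wf.stim_duration, n),
                    "sample_index": np.arange(n),
                    "voltage_mv": wf.samples,
                }))
    wf_frame = (pd.concat(chunks, ignore_index=True) if chunks
                else pd.DataFrame(columns=WAVEFORM_COLUMNS))
    wf_frame.to_csv(out / "waveforms.csv", index=False, float_format="%.6g")

    pd.DataFrame([{
        "patient_id": s.patient_id, "session_id": s.session_id, "age_years": s.age,
        "sex": s.sex, "bmi": s.bmi, "source": s.source, "label": s.label,
    } for s in sessions]).to_csv(out / "sessions.csv", index=False, float_format="%.6g")

    ann_rows = []
    for s in sessions:
        for nerve, anns in s.annotations.items():
            for i, ann in enumerate(anns):
                row = {"patient_id": s.patient_id, "session_id": s.session_id,
                       "nerve": nerve.value, "stim_index": i}
                for mark in MARK_NAMES:
                    pair = getattr(ann, mark)
                    row[f"{mark}_latency_ms"] = None if pair is None else pair[0]
                    row[f"{mark}_amplitude_mv"] = None if pair is None else pair[1]
                ann_rows.append(row)
    pd.DataFrame(ann_rows).to_csv(out / "annotations.csv", index=False, float_format="%.6g")

    if survival is not None:
        write_survival(survival, out / "survival.csv")
    return out


def read_cohort(cohort_dir: str | Path) -> list[Session]:
    """Rebuild sessions (waveforms + annotations + demographics) from CSVs."""
    d = Path(cohort_dir)
    sess_frame = pd.read_csv(d / "sessions.csv")
    wf_frame = pd.read_csv(d / "waveforms.csv")
    ann_path = d / "annotations.csv"
    ann_frame = pd.read_csv(ann_path) if ann_path.exists() else None

    sessions: dict[str, Session] = {}
    for _, row in sess_frame.iterrows():
        sessions[row["session_id"]] = Session(
            patient_id=row["patient_id"], session_id=row["session_id"], label=row["label"],
            age=float(row["age_years"]), sex=row["sex"], bmi=float(row["bmi"]), source=row["source"])

    from .types import Waveform
    for (sid, nerve, stim), grp in wf_frame.groupby(["session_id", "nerve", "stim_index"], sort=True):
        grp = grp.sort_values("sample_index")
        wf = Waveform(
            samples=grp["voltage_mv"].to_numpy(),
            sampling_rate=float(grp["sampling_rate_hz"].iloc[0]),
            nerve=Nerve(nerve), patient_id=grp["patient_id"].iloc[0], session_id=sid,
            stim_index=int(stim), stim_amplitude=float(grp["stim_amplitude_ma"].iloc[0]),
            stim_duration=float(grp["stim_duration_ms"].iloc[0]))
        sessions[sid].waveforms.setdefault(Nerve(nerve), []).append(wf)
    for s in sessions.values():
        for wfs in s.waveforms.values():
            wfs.sort(key=lambda w: w.stim_index)

    if ann_frame is not None:
        for _, row in ann_frame.iterrows():
            marks = {}
            for mark in MARK_NAMES:
                lat = row[f"{mark}_latency_ms"]
                marks[mark] = None if pd.isna(lat) else (float(lat), float(row[f"{mark}_amplitude_mv"]))
            ann = Annotations(**marks)
            sessions[row["session_id"]].annotations.setdefault(Nerve(row["nerve"]), []).append(ann)
    return list(sessions.values())


def write_survival(records: Sequence[SurvivalRecord], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame([{
        "duration_months": r.duration, "event": int(r.event), "sex": r.sex,
        "onset_site": r.onset_site, "family_history": r.family_history,
        "diagnostic_delay_months": r.diagnostic_delay, "age_at_onset_years": r.age_at_onset,
        "bmi": r.bmi, "model_score": r.model_score,
    } for r in records]).to_csv(path, index=False, float_format="%.6g")
    return path


def read_survival(path: str | Path) -> list[SurvivalRecord]:
    frame = pd.read_csv(path)
    return [SurvivalRecord(
        duration=float(r["duration_months"]), event=bool(r["event"]), sex=r["sex"],
        onset_site=r["onset_site"], family_history=r["family_history"],
        diagnostic_delay=float(r["diagnostic_delay_months"]),
        age_at_onset=float(r["age_at_onset_years"]), bmi=float(r["bmi"]),
        model_score=float(r["model_score"])) for _, r in frame.iterrows()]
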
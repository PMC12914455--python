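"""Readers and writers for the pipeline's on-disk formats.

All tabular formats are plain CSV (BORIS-style event logs, interval tables,
IBI tachograms, looking annotations, cohort and result tables); EEG travels
as a float32 ``.npy`` array with a JSON sidecar carrying the sampling rate
and channel names.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .attention import AttentionPhase, LookingRecord
from .cardiac import IBISeries
from .eeg import EEGRecord
from .entropy import SensoryEventLog

__all__ = [
    "write_events_csv",
    "read_events_csv",
    "write_intervals_csv",
    "read_intervals_csv",
    "write_ibi_csv",
    "read_ibi_csv",
    "read_rpeaks_txt",
    "write_looking_csv",
    "read_looking_csv",
    "write_phases_csv",
    "read_phases_csv",
    "write_eeg_npy",
    "read_eeg_npy",
]


# -- caregiver events -------------------------------------------------------

def write_events_csv(log: SensoryEventLog, path) -> None:
    """BORIS-style export: one row per start/stop event, time-ordered."""
    rows = []
    for modality, onset, offset in log.events:
        rows.append({"time_s": onset, "modality": modality, "event": "start"})
        rows.append({"time_s": offset, "modality": modality, "event": "stop"})
    df = pd.DataFrame(rows, columns=["time_s", "modality", "event"])
    df = df.sort_values(["time_s", "modality", "event"], kind="stable")
    df.to_csv(path, index=False)


def read_events_csv(path, session_duration_s: float | None = None) -> SensoryEventLog:
    df = pd.read_csv(path)
    events = []
    open_at: dict[str, float] = {}
    for _, row in df.sort_values("time_s", kind="stable").iterrows():
        m, t, kind = row["modality"], float(row["time_s"]), row["event"]
        if kind == "start":
            if m in open_at:
                raise ValueError(f"start for already-open {m} at t={t}")
            open_at[m] = t
        elif kind == "stop":
            if m not in open_at:
                raise ValueError(f"stop for unopened {m} at t={t}")
            events.append((m, open_at.pop(m), t))
        else:
            raise ValueError(f"unknown event kind {kind!r}")
    if open_at:
        raise ValueError(f"unterminated events: {sorted(open_at)}")
    if session_duration_s is None:
        session_duration_s = max((off for _, _, off in events), default=1.0)
    return SensoryEventLog(events=sorted(events, key=lambda e: (e[1], e[0])),
                           session_duration_s=session_duration_s)


def write_intervals_csv(log: SensoryEventLog, path) -> None:
    pd.DataFrame(
        [{"modality": m, "onset_s": a, "offset_s": b} for m, a, b in log.events]
    ).to_csv(path, index=False)


def read_intervals_csv(path, session_duration_s: float | None = None) -> SensoryEventLog:
    df = pd.read_csv(path)
    events = [
        (row["modality"], float(row["onset_s"]), float(row["offset_s"]))
        for _, row in df.iterrows()
    ]
    if session_duration_s is None:
        session_duration_s = max((off for _, _, off in events), default=1.0)
    return SensoryEventLog(events=sorted(events, key=lambda e: (e[1], e[0])),
                           session_duration_s=session_duration_s)


# -- cardiac ----------------------------------------------------------------

def write_ibi_csv(series: IBISeries, path) -> None:
    """Columns: beat_index, ibi_ms, t_s (time of the interval's closing beat)."""
    ibi = series.ibi_ms
    pd.DataFrame(
        {
            "beat_index": np.arange(len(ibi)),
            "ibi_ms": ibi,
            "t_s": series.beat_times_s[1:],
        }
    ).to_csv(path, index=False)


def read_ibi_csv(path) -> IBISeries:
    df = pd.read_csv(path)
    ibi = df["ibi_ms"].to_numpy(dtype=float)
    t_close = df["t_s"].to_numpy(dtype=float)
    t0 = t_close[0] - ibi[0] / 1000.0
    return IBISeries(beat_times_s=np.concatenate([[t0], t_close]))


def read_rpeaks_txt(path) -> IBISeries:
    """One R-peak time (s) per line."""
    times = np.loadtxt(path, dtype=float, ndmin=1)
    return IBISeries(beat_times_s=times)


# -- looking / phases -------------------------------------------------------

def write_looking_csv(record: LookingRecord, path) -> None:
    pd.DataFrame(
        [{"onset_s": a, "offset_s": b} for a, b in record.intervals]
    ).to_csv(path, index=False)


def read_looking_csv(path, task_onset_s: float = 0.0, task_duration_s: float = 281.0) -> LookingRecord:
    df = pd.read_csv(path)
    return LookingRecord(
        intervals=[(float(r["onset_s"]), float(r["offset_s"])) for _, r in df.iterrows()],
        task_onset_s=task_onset_s,
        task_duration_s=task_duration_s,
    )


def write_phases_csv(phases: list[AttentionPhase], path, dyad_id: str = "") -> None:
    pd.DataFrame(
        [
            {
                "dyad_id": dyad_id,
                "kind": p.kind,
                "onset_s": p.onset_s,
                "offset_s": p.offset_s,
                "trigger_beat_index": p.trigger_beat_index,
                "baseline_median_ms": p.baseline_median_ms,
            }
            for p in phases
        ]
    ).to_csv(path, index=False)


def read_phases_csv(path) -> list[AttentionPhase]:
    df = pd.read_csv(path)
    return [
        AttentionPhase(
            kind=r["kind"],
            onset_s=float(r["onset_s"]),
            offset_s=float(r["offset_s"]),
            trigger_beat_index=int(r["trigger_beat_index"]),
            baseline_median_ms=float(r["baseline_median_ms"]),
        )
        for _, r in df.iterrows()
    ]


# -- EEG --------------------------------------------------------------------

def write_eeg_npy(record: EEGRecord, base_path) -> tuple[Path, Path]:
    """``<base>.npy`` (float32, channels x samples) + ``<base>.json`` sidecar."""
    base = Path(base_path)
    npy_path = base.with_suffix(".npy")
    json_path = base.with_suffix(".json")
    np.save(npy_path, record.data.astype(np.float32))
    json_path.write_text(
        json.dumps(
            {
                "sr_hz": record.sr_hz,
                "channel_names": list(record.channel_names),
                "start_time_s": record.start_time_s,
            },
            indent=1,
        )
    )
    return npy_path, json_path


def read_eeg_npy(base_path) -> EEGRecord:
    base = Path(base_path)
    data = np.load(base.with_suffix(".npy"))
    meta = json.loads(base.with_suffix(".json").read_text())
    return EEGRecord(
        data=np.asarray(data, dtype=float),
        sr_hz=float(meta["sr_hz"]),
        channel_names=list(meta["channel_names"]),
        start_time_s=float(meta.get("start_time_s", 0.0)),
    )
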
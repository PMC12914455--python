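"""Heart-rate-defined sustained attention segmentation.

During sustained attention an infant's heart slows: IBIs lengthen relative to
the immediately preceding baseline.  A sustained-attention (SA) phase opens
when the infant is looking at the stimulus *and* five consecutive IBIs each
exceed (strictly) the median of the five baseline IBIs preceding the phase;
it closes when five consecutive IBIs each fall (strictly) below the median of
the five IBIs immediately preceding that run.  The baseline window is
re-seeded from the five beats following each phase offset.  Phase onsets and
offsets are stamped at the first beat of the triggering run, so every emitted
phase is replayable from its recorded trigger index and baseline median.

Derived indices: total SA duration (s, the behavioral measure) and the mean
heart-rate deceleration (mean IBI within SA minus mean IBI in the 5-s
pre-stimulus window; positive = slower heart, the autonomic measure).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cardiac import IBISeries

__all__ = [
    "LookingRecord",
    "AttentionPhase",
    "AttentionSummary",
    "detect_sustained_attention",
    "replay_phase_onset",
    "total_sa_duration",
    "heart_rate_deceleration",
    "summarize_attention",
]

RUN_LENGTH = 5  # consecutive IBIs required to open/close a phase


@dataclass
class LookingRecord:
    """Screen-directed gaze intervals within the stimulus window."""

    intervals: list[tuple[float, float]]
    task_onset_s: float = 0.0
    task_duration_s: float = 281.0

    def __post_init__(self) -> None:
        ivals = sorted(self.intervals)
        end = self.task_onset_s + self.task_duration_s
        for on, off in ivals:
            if not (self.task_onset_s - 1e-9 <= on < off <= end + 1e-9):
                raise ValueError(f"looking interval [{on}, {off}] outside task window")
        for (_, a1), (b0, _) in zip(ivals, ivals[1:]):
            if b0 < a1 - 1e-12:
                raise ValueError("overlapping looking intervals")
        self.intervals = ivals

    def covers(self, t: float) -> bool:
        for on, off in self.intervals:
            if on - 1e-12 <= t < off + 1e-12:
                return True
        return False


@dataclass
class AttentionPhase:
    kind: str  # "sustained_attention" | "inattention"
    onset_s: float
    offset_s: float
    trigger_beat_index: int = -1  # global IBI index that opened the phase
    baseline_median_ms: float = float("nan")

    def __post_init__(self) -> None:
        if self.kind not in ("sustained_attention", "inattention"):
            raise ValueError(f"unknown phase kind {self.kind!r}")
        if not self.onset_s < self.offset_s:
            raise ValueError("phase onset must precede offset")

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class AttentionSummary:
    total_sa_duration_s: float
    mean_deceleration_ms: float
    n_sa_phases: int
    prestim_baseline_ibi_ms: float


def _ibi_times(ibi: IBISeries) -> tuple[np.ndarray, np.ndarray]:
    """IBI values with each interval stamped at its starting beat time."""
    return ibi.beat_times_s[:-1], ibi.ibi_ms


def detect_sustained_attention(
    ibi: IBISeries,
    looking: LookingRecord,
    require_looking_throughout: bool = False,
) -> list[AttentionPhase]:
    """Scan beats in order and emit SA + inattention phases tiling the task.

    Outside SA a rolling baseline of the five most recent IBIs is kept; the
    onset rule (five consecutive IBIs strictly above the baseline median, with
    the first beat of the run inside a looking interval) opens a phase at that
    first beat.  Inside SA, five consecutive IBIs strictly below the median of
    the five IBIs immediately preceding the run close the phase at the run's
    first beat; the baseline then re-seeds from the following beats.  Ties
    never change state.  A phase still open at the last beat is closed at the
    task-window end.
    """
    t_start = looking.task_onset_s
    t_end = looking.task_onset_s + looking.task_duration_s
    times, values = _ibi_times(ibi)
    in_window = (times >= t_start - 1e-12) & (times < t_end)
    if in_window.sum() + 1 < 10:
        raise ValueError("need at least 10 beats within the task window")
    idx = np.flatnonzero(in_window)
    t = times[idx]
    v = values[idx]
    n = len(v)
    R = RUN_LENGTH

    phases: list[AttentionPhase] = []
    i = R  # first index with a full 5-IBI baseline behind it
    open_onset = None
    open_trigger = -1
    open_median = float("nan")
    sa_start_local = -1

    while i + R <= n:
        if open_onset is None:
            baseline_median = float(np.median(v[i - R : i]))
            run = v[i : i + R]
            if np.all(run > baseline_median) and looking.covers(float(t[i])):
                open_onset = float(t[i])
                open_trigger = int(idx[i])
                open_median = baseline_median
                sa_start_local = i
                i += R  # closing checks need 5 in-phase IBIs behind them
                continue
            i += 1
        else:
            preceding_median = float(np.median(v[i - R : i]))
            run = v[i : i + R]
            terminate = np.all(run < preceding_median)
            if require_looking_throughout and not looking.covers(float(t[i])):
                terminate = True
            if terminate:
                phases.append(
                    AttentionPhase(
                        kind="sustained_attention",
                        onset_s=open_onset,
                        offset_s=float(t[i]),
                        trigger_beat_index=open_trigger,
                        baseline_median_ms=open_median,
                    )
                )
                open_onset = None
                i += R  # baseline re-seeds from the 5 beats after the offset
            else:
                i += 1
    if open_onset is not None:
        phases.append(
            AttentionPhase(
                kind="sustained_attention",
                onset_s=open_onset,
                offset_s=float(min(t_end, ibi.beat_times_s[-1])),
                trigger_beat_index=open_trigger,
                baseline_median_ms=open_median,
            )
        )

    # Inattention = complement of SA within the task window.
    out: list[AttentionPhase] = []
    cursor = t_start
    for ph in phases:
        if ph.onset_s > cursor + 1e-12:
            out.append(AttentionPhase("inattention", cursor, ph.onset_s))
        out.append(ph)
        cursor = ph.offset_s
    if cursor < t_end - 1e-12:
        out.append(AttentionPhase("inattention", cursor, t_end))
    return out


def replay_phase_onset(ibi: IBISeries, looking: LookingRecord, phase: AttentionPhase) -> bool:
    """Re-evaluate the onset rule for an emitted SA phase (audit invariant)."""
    if phase.kind != "sustained_attention":
        raise ValueError("replay applies to sustained_attention phases")
    times, values = _ibi_times(ibi)
    k = phase.trigger_beat_index
    run = values[k : k + RUN_LENGTH]
    return (
        len(run) == RUN_LENGTH
        and bool(np.all(run > phase.baseline_median_ms))
        and looking.covers(float(times[k]))
        and abs(times[k] - phase.onset_s) < 1e-9
    )


def total_sa_duration(phases: list[AttentionPhase]) -> float:
    """Total time (s) spent in heart-rate-defined sustained attention."""
    return float(
        sum(p.duration_s for p in phases if p.kind == "sustained_attention")
    )


def heart_rate_deceleration(
    ibi: IBISeries,
    phases: list[AttentionPhase],
    task_onset_s: float,
    prestim_window_s: float = 5.0,
) -> float:
    """Mean IBI inside SA phases minus mean IBI in the pre-stimulus window.

    Positive values indicate heart-rate deceleration (attentional slowing).
    Returns NaN (a missing value, not zero) when no SA phase was detected.
    """
    times, values = _ibi_times(ibi)
    pre = (times >= task_onset_s - prestim_window_s - 1e-12) & (times < task_onset_s)
    if not pre.any():
        raise ValueError("no beats in the pre-stimulus baseline window")
    sa = [p for p in phases if p.kind == "sustained_attention"]
    if not sa:
        return float("nan")
    in_sa = np.zeros(len(values), dtype=bool)
    for p in sa:
        in_sa |= (times >= p.onset_s - 1e-12) & (times < p.offset_s)
    if not in_sa.any():
        return float("nan")
    return float(np.mean(values[in_sa]) - np.mean(values[pre]))


def summarize_attention(
    ibi: IBISeries,
    phases: list[AttentionPhase],
    task_onset_s: float,
    prestim_window_s: float = 5.0,
) -> AttentionSummary:
    times, values = _ibi_times(ibi)
    pre = (times >= task_onset_s - prestim_window_s - 1e-12) & (times < task_onset_s)
    sa = [p for p in phases if p.kind == "sustained_attention"]
    return AttentionSummary(
        total_sa_duration_s=total_sa_duration(phases),
        mean_deceleration_ms=heart_rate_deceleration(
            ibi, phases, task_onset_s, prestim_window_s
        ),
        n_sa_phases=len(sa),
        prestim_baseline_ibi_ms=float(np.mean(values[pre])) if pre.any() else float("nan"),
    )
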
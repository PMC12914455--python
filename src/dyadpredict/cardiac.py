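"""Baseline autonomic measures from inter-beat-interval (IBI) series.

The inter-beat interval is the latency between successive ECG R-waves, in ms;
longer IBIs mean a slower heart.  Vagally-mediated heart-rate variability is
indexed by the RMSSD, the root mean square of successive IBI differences,
computed here on the beat-domain series.  A uniformly resampled (100 Hz by
default) tachogram is also provided for spectral extensions, and cohort-level
winsorization at the 5th/95th percentiles limits outlier influence on the
HRV variable entering the regressions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "IBISeries",
    "BaselineHRVResult",
    "interpolate_to_grid",
    "rmssd",
    "mean_heart_rate",
    "winsorize",
    "flag_artifacts",
    "interpolate_flagged",
    "baseline_hrv",
]


@dataclass
class IBISeries:
    """R-peak times (s, strictly increasing) and derived IBIs (ms).

    ``quality_flags`` marks beats whose adjacent interval was edited or lies
    outside physiologic bounds; flagged beats are kept, never silently
    dropped.
    """

    beat_times_s: np.ndarray
    quality_flags: np.ndarray = field(default=None)
    _ibi_ms: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.beat_times_s = np.asarray(self.beat_times_s, dtype=float)
        if self.beat_times_s.ndim != 1 or len(self.beat_times_s) < 2:
            raise ValueError("need at least 2 beat times")
        if np.any(np.diff(self.beat_times_s) <= 0):
            raise ValueError("beat times must be strictly increasing")
        if self.quality_flags is None:
            self.quality_flags = np.zeros(len(self.beat_times_s), dtype=bool)
        else:
            self.quality_flags = np.asarray(self.quality_flags, dtype=bool)
            if len(self.quality_flags) != len(self.beat_times_s):
                raise ValueError("quality_flags length mismatch")
        if self._ibi_ms is not None:
            self._ibi_ms = np.asarray(self._ibi_ms, dtype=float)
            if len(self._ibi_ms) != len(self.beat_times_s) - 1:
                raise ValueError("ibi_ms length mismatch")

    @property
    def ibi_ms(self) -> np.ndarray:
        # the exact IBI array is kept when the series was built from IBIs, so
        # that e.g. a constant series has successive differences of exactly 0
        if self._ibi_ms is not None:
            return self._ibi_ms
        return np.diff(self.beat_times_s) * 1000.0

    @property
    def duration_s(self) -> float:
        return float(self.beat_times_s[-1] - self.beat_times_s[0])

    @classmethod
    def from_ibi_ms(cls, ibi_ms, t0_s: float = 0.0) -> "IBISeries":
        ibi_ms = np.asarray(ibi_ms, dtype=float)
        times = t0_s + np.concatenate([[0.0], np.cumsum(ibi_ms) / 1000.0])
        return cls(beat_times_s=times, _ibi_ms=ibi_ms)


@dataclass
class BaselineHRVResult:
    rmssd_ms: float
    mean_hr_bpm: float
    usable_duration_s: float
    usable: bool
    winsorized_rmssd_ms: float = None  # populated at cohort level


def interpolate_to_grid(series: IBISeries, grid_hz: float = 100.0):
    """Linearly interpolate the IBI tachogram onto a uniform time grid.

    Each IBI is anchored at its terminating beat time; endpoints are held at
    the nearest beat's value.  Returns ``(grid_times_s, ibi_ms_on_grid)``.
    """
    if grid_hz <= 0:
        raise ValueError("grid_hz must be positive")
    knots_t = series.beat_times_s[1:]
    knots_v = series.ibi_ms
    if len(knots_t) < 1:
        raise ValueError("need at least 2 beats to interpolate")
    t0, t1 = series.beat_times_s[0], series.beat_times_s[-1]
    n = int(np.floor((t1 - t0) * grid_hz)) + 1
    grid_t = t0 + np.arange(n) / grid_hz
    grid_v = np.interp(grid_t, knots_t, knots_v)
    return grid_t, grid_v


def rmssd(series: IBISeries) -> float:
    """Root mean square of successive beat-domain IBI differences (ms)."""
    ibi = series.ibi_ms
    if len(ibi) < 2:
        raise ValueError("RMSSD needs at least 3 beats (2 IBIs)")
    return float(np.sqrt(np.mean(np.diff(ibi) ** 2)))


def mean_heart_rate(series: IBISeries) -> float:
    """Mean heart rate in bpm, 60000 / mean(IBI in ms)."""
    return float(60000.0 / np.mean(series.ibi_ms))


def winsorize(values, lower_pct: float = 5.0, upper_pct: float = 95.0) -> np.ndarray:
    """Cap values at the given percentiles (linear-interpolation estimator).

    Order and length are preserved; applied at the cohort level to the RMSSD
    variable before modeling.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot winsorize empty input")
    finite = values[np.isfinite(values)]
    if finite.size < 2:
        raise ValueError("need at least 2 finite values")
    if not (0 <= lower_pct < upper_pct <= 100):
        raise ValueError("require 0 <= lower_pct < upper_pct <= 100")
    lo = np.percentile(finite, lower_pct, method="linear")
    hi = np.percentile(finite, upper_pct, method="linear")
    out = values.copy()
    mask = np.isfinite(values)
    out[mask] = np.clip(values[mask], lo, hi)
    return out


def flag_artifacts(
    series: IBISeries,
    bounds_ms: tuple[float, float] = (250.0, 1000.0),
    max_successive_diff_ms: float = 200.0,
) -> np.ndarray:
    """Rule-based per-IBI artifact flags (out-of-bounds or implausible jumps).

    Returns a boolean mask over IBIs; nothing is removed.  Manual R-peak
    editing is out of scope -- these flags feed :func:`interpolate_flagged`.
    """
    ibi = series.ibi_ms
    flags = (ibi < bounds_ms[0]) | (ibi > bounds_ms[1])
    diffs = np.abs(np.diff(ibi))
    jump = np.zeros_like(flags)
    jump[1:] |= diffs > max_successive_diff_ms
    return flags | jump


def interpolate_flagged(series: IBISeries, flags: np.ndarray) -> IBISeries:
    """Replace flagged IBIs by linear interpolation over beat index."""
    ibi = series.ibi_ms.copy()
    flags = np.asarray(flags, dtype=bool)
    if flags.all():
        raise ValueError("all IBIs flagged; nothing to interpolate from")
    idx = np.arange(len(ibi))
    ibi[flags] = np.interp(idx[flags], idx[~flags], ibi[~flags])
    out = IBISeries.from_ibi_ms(ibi, t0_s=series.beat_times_s[0])
    out.quality_flags[1:] = flags
    return out


def baseline_hrv(
    series: IBISeries,
    min_duration_s: float = 60.0,
    clean: bool = True,
) -> BaselineHRVResult:
    """RMSSD + mean HR for a baseline recording, with a usable-duration gate.

    Recordings shorter than ``min_duration_s`` are flagged unusable (their
    metrics are still reported).  With ``clean``, rule-flagged IBIs are
    replaced by interpolation first.
    """
    work = series
    if clean:
        flags = flag_artifacts(series)
        if flags.any() and not flags.all():
            work = interpolate_flagged(series, flags)
    duration = work.duration_s
    return BaselineHRVResult(
        rmssd_ms=rmssd(work),
        mean_hr_bpm=mean_heart_rate(work),
        usable_duration_s=duration,
        usable=duration >= min_duration_s,
    )
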
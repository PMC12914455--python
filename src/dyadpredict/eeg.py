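"""Relative frontal theta power from 1-s EEG segments.

EEG recorded during the sustained-attention task (64-channel geodesic net,
resampled to 250 Hz upstream) is segmented into 1-second windows labeled
attention / inattention from the heart-rate-defined phase table.  Each
segment is Hanning-windowed and FFT-decomposed into 1 Hz power bins; relative
theta is power summed over 4-6 Hz divided by power over the 1-50 Hz total
band, over the frontal channel subset, averaged across segments per
condition.  The attention-minus-inattention change score is the neural index
of sustained-attention quality.

Segment hygiene follows two rules: segments whose frontal peak amplitude lies
more than 3 SD from the median are rejected, and a recording with fewer than
20 usable segments yields missing theta values rather than an estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "FRONTAL_ELECTRODES",
    "EEGRecord",
    "EEGSegmentSet",
    "SpectralSummary",
    "segment_power_spectrum",
    "segment_record",
    "reject_amplitude_outliers",
    "enforce_minimum_segments",
    "relative_theta",
]

# Frontal electrode numbers of the 64-channel geodesic infant montage.
FRONTAL_ELECTRODES = (2, 3, 5, 6, 9, 10, 11, 12, 13, 14, 57, 59, 60)

ATTENTION = "attention"
INATTENTION = "inattention"


def default_channel_names(n_channels: int) -> list[str]:
    return [f"E{i + 1}" for i in range(n_channels)]


def frontal_indices_from_names(channel_names: list[str]) -> list[int]:
    """Map the standard frontal electrode labels onto 0-based channel indices."""
    wanted = {f"E{e}" for e in FRONTAL_ELECTRODES}
    idx = [i for i, name in enumerate(channel_names) if name in wanted]
    if not idx:
        raise ValueError("no frontal electrodes found among channel names")
    return idx


@dataclass
class EEGRecord:
    """Continuous multichannel EEG: (channels x samples) + sampling rate."""

    data: np.ndarray
    sr_hz: float
    channel_names: list[str] = None
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.sr_hz < 125:
            raise ValueError("sampling rate must be >= 125 Hz")
        if self.channel_names is None:
            self.channel_names = default_channel_names(self.data.shape[0])
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length mismatch")


@dataclass
class EEGSegmentSet:
    """1-s (segment x channel x sample) windows with condition labels."""

    segments: np.ndarray
    sr_hz: float
    condition_labels: np.ndarray
    channel_names: list[str]
    frontal_channel_indices: list[int] = field(default=None)
    n_rejected: int = 0

    def __post_init__(self) -> None:
        self.segments = np.asarray(self.segments, dtype=float)
        if self.segments.ndim != 3:
            raise ValueError("segments must be (n_seg, n_chan, n_samp)")
        if self.segments.shape[2] != int(round(self.sr_hz)):
            raise ValueError("each 1-s segment must have sr_hz samples")
        self.condition_labels = np.asarray(self.condition_labels)
        if len(self.condition_labels) != self.segments.shape[0]:
            raise ValueError("condition_labels length mismatch")
        if self.frontal_channel_indices is None:
            try:
                self.frontal_channel_indices = frontal_indices_from_names(
                    list(self.channel_names)
                )
            except ValueError:
                self.frontal_channel_indices = list(range(self.segments.shape[1]))
        if max(self.frontal_channel_indices, default=0) >= self.segments.shape[1]:
            raise ValueError("frontal index outside channel set")

    @property
    def n_segments(self) -> int:
        return self.segments.shape[0]


@dataclass
class SpectralSummary:
    rel_theta_attention: float
    rel_theta_inattention: float
    theta_change: float
    n_segments_attention: int
    n_segments_inattention: int
    n_rejected: int
    log10_theta_attention: float = float("nan")
    log10_theta_inattention: float = float("nan")


def segment_power_spectrum(segment: np.ndarray, sr_hz: float) -> tuple[np.ndarray, np.ndarray]:
    """Hanning-windowed FFT power of one 1-s segment, per channel.

    Returns ``(freqs_hz, power)`` with ``power`` shaped (n_chan, n_bins) at
    1 Hz resolution.  Power is scaled so that its sum over bins equals the
    windowed time-domain energy (Parseval).
    """
    segment = np.atleast_2d(np.asarray(segment, dtype=float))
    n = segment.shape[1]
    if n != int(round(sr_hz)):
        raise ValueError(f"segment length {n} != sr_hz {sr_hz}")
    window = np.hanning(n)
    xw = segment * window
    spec = np.fft.rfft(xw, axis=1)
    power = np.abs(spec) ** 2 / n
    # double the one-sided interior bins so the sum satisfies Parseval
    if n % 2 == 0:
        power[:, 1:-1] *= 2.0
    else:
        power[:, 1:] *= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / sr_hz)
    return freqs, power


def segment_record(record: EEGRecord, phases) -> EEGSegmentSet:
    """Cut a continuous record into labeled 1-s segments.

    A segment is labeled ``attention`` when its midpoint falls inside a
    sustained-attention phase, otherwise ``inattention``.
    """
    n_samp = int(round(record.sr_hz))
    n_seg = record.data.shape[1] // n_samp
    segs = record.data[:, : n_seg * n_samp].reshape(
        record.data.shape[0], n_seg, n_samp
    ).transpose(1, 0, 2)
    sa = [
        (p.onset_s, p.offset_s)
        for p in phases
        if getattr(p, "kind", None) == "sustained_attention"
    ]
    labels = []
    for k in range(n_seg):
        mid = record.start_time_s + (k + 0.5)
        labels.append(
            ATTENTION
            if any(on <= mid < off for on, off in sa)
            else INATTENTION
        )
    return EEGSegmentSet(
        segments=segs,
        sr_hz=record.sr_hz,
        condition_labels=np.array(labels),
        channel_names=list(record.channel_names),
    )


def reject_amplitude_outliers(segset: EEGSegmentSet, z: float = 3.0) -> EEGSegmentSet:
    """Drop segments whose frontal peak amplitude is > z SD from the median.

    The per-segment amplitude summary is the maximum absolute value across the
    frontal channels.  Rejection counts accumulate in ``n_rejected``.
    """
    if segset.n_segments < 2:
        raise ValueError("need at least 2 segments")
    frontal = segset.segments[:, segset.frontal_channel_indices, :]
    summary = np.max(np.abs(frontal), axis=(1, 2))
    med = np.median(summary)
    sd = np.std(summary, ddof=1)
    keep = np.abs(summary - med) <= z * sd if sd > 0 else np.ones(len(summary), bool)
    return replace(
        segset,
        segments=segset.segments[keep],
        condition_labels=segset.condition_labels[keep],
        n_rejected=segset.n_rejected + int((~keep).sum()),
    )


def enforce_minimum_segments(segset: EEGSegmentSet, min_n: int = 20) -> bool:
    """Usability gate: at least ``min_n`` retained segments."""
    return segset.n_segments >= min_n


def _band_slice(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    return (freqs >= band[0] - 1e-9) & (freqs <= band[1] + 1e-9)


def relative_theta(
    segset: EEGSegmentSet,
    theta_band: tuple[float, float] = (4.0, 6.0),
    total_band: tuple[float, float] = (1.0, 50.0),
    min_segments: int = 20,
    log10_of_averages: bool = False,
) -> SpectralSummary:
    """Relative frontal theta per condition and the attention change score.

    Per segment, power is summed across frontal channels within the theta and
    total bands (inclusive 1 Hz bins); the per-segment theta/total ratio is
    averaged across segments of each condition, and the change score is
    attention minus inattention.  With ``log10_of_averages`` the alternative
    normalization (log10 of condition-mean band power, differenced) replaces
    the auxiliary log outputs.  Below ``min_segments`` all outputs are NaN.
    """
    nan = float("nan")
    if not enforce_minimum_segments(segset, min_segments):
        n_att = int(np.sum(segset.condition_labels == ATTENTION))
        n_in = int(np.sum(segset.condition_labels == INATTENTION))
        return SpectralSummary(nan, nan, nan, n_att, n_in, segset.n_rejected)

    freqs, _ = segment_power_spectrum(segset.segments[0], segset.sr_hz)
    theta_mask = _band_slice(freqs, theta_band)
    total_mask = _band_slice(freqs, total_band)

    frontal = segset.segments[:, segset.frontal_channel_indices, :]
    ratios = np.empty(segset.n_segments)
    theta_sums = np.empty(segset.n_segments)
    for k in range(segset.n_segments):
        _, power = segment_power_spectrum(frontal[k], segset.sr_hz)
        chan_sum = power.sum(axis=0)
        theta_sums[k] = chan_sum[theta_mask].sum()
        total = chan_sum[total_mask].sum()
        ratios[k] = theta_sums[k] / total if total > 0 else np.nan

    out = {}
    logs = {}
    for cond in (ATTENTION, INATTENTION):
        mask = segset.condition_labels == cond
        if mask.any():
            out[cond] = float(np.nanmean(ratios[mask]))
            mean_theta = float(np.mean(theta_sums[mask]))
            logs[cond] = float(np.log10(mean_theta)) if mean_theta > 0 else nan
        else:
            out[cond] = nan
            logs[cond] = nan

    if log10_of_averages:
        change = logs[ATTENTION] - logs[INATTENTION]
    else:
        change = out[ATTENTION] - out[INATTENTION]
    return SpectralSummary(
        rel_theta_attention=out[ATTENTION],
        rel_theta_inattention=out[INATTENTION],
        theta_change=float(change),
        n_segments_attention=int(np.sum(segset.condition_labels == ATTENTION)),
        n_segments_inattention=int(np.sum(segset.condition_labels == INATTENTION)),
        n_rejected=segset.n_rejected,
        log10_theta_attention=logs[ATTENTION],
        log10_theta_inattention=logs[INATTENTION],
    )
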
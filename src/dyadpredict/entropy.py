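"""Entropy-rate scoring of caregiver sensory signal sequences.

Caregiver behavior during a dyadic play interaction is micro-coded as timed
on/off events in three sensory modalities (auditory, visual, tactile).  At any
moment the caregiver occupies a *composite sensory state*: the subset of
modalities simultaneously active (including "no signal", the empty set, for a
total of up to eight states).  The unpredictability of the caregiver's signal
stream is quantified as the Shannon entropy rate of the first-order transition
sequence between composite states,

    H = - sum_i pi_i sum_j P(j|i) log2 P(j|i)   [bits per transition]

where ``P(j|i)`` are row-normalized empirical transition counts and ``pi`` is
the empirical frequency of source states.  H is 0 for a perfectly predictable
(deterministic) sequence and log2(k) at most for k observed states.

This module also provides the interrater-reliability statistics (raw percent
agreement and Cohen's kappa over time-binned modality presence) used to
validate the behavioral coding itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MODALITIES",
    "SensoryEventLog",
    "SignalStateSequence",
    "TransitionModel",
    "EntropyRate",
    "state_label",
    "events_to_state_sequence",
    "estimate_transition_model",
    "entropy_rate",
    "interrater_reliability",
]

MODALITIES = ("auditory", "visual", "tactile")
_INITIALS = {"auditory": "A", "visual": "V", "tactile": "T"}


def state_label(state: frozenset) -> str:
    """Human-readable label for a composite state, e.g. ``'A+T'`` or ``'none'``."""
    if not state:
        return "none"
    order = {m: i for i, m in enumerate(MODALITIES)}
    return "+".join(_INITIALS[m] for m in sorted(state, key=order.__getitem__))


@dataclass
class SensoryEventLog:
    """Timed caregiver sensory events: (modality, onset_s, offset_s) intervals."""

    events: list[tuple[str, float, float]]
    session_duration_s: float

    def __post_init__(self) -> None:
        if self.session_duration_s <= 0:
            raise ValueError("session_duration_s must be positive")
        for modality, onset, offset in self.events:
            if modality not in MODALITIES:
                raise ValueError(f"unknown modality {modality!r}")
            if not (0 <= onset < offset <= self.session_duration_s + 1e-9):
                raise ValueError(
                    f"invalid interval [{onset}, {offset}] for {modality} "
                    f"in a {self.session_duration_s} s session"
                )
        # Overlapping intervals of the same modality are a coding error.
        by_modality: dict[str, list[tuple[float, float]]] = {}
        for modality, onset, offset in self.events:
            by_modality.setdefault(modality, []).append((onset, offset))
        for modality, ivals in by_modality.items():
            ivals.sort()
            for (a0, a1), (b0, b1) in zip(ivals, ivals[1:]):
                if b0 < a1 - 1e-12:
                    raise ValueError(
                        f"overlapping {modality} intervals "
                        f"[{a0}, {a1}] and [{b0}, {b1}]"
                    )


@dataclass
class SignalStateSequence:
    """Ordered composite states and the times at which each was entered."""

    states: list[frozenset]
    change_times_s: list[float]

    def __post_init__(self) -> None:
        if len(self.states) != len(self.change_times_s):
            raise ValueError("states and change_times_s must have equal length")
        for a, b in zip(self.states, self.states[1:]):
            if a == b:
                raise ValueError("consecutive identical states (not collapsed)")

    @property
    def n_transitions(self) -> int:
        return max(len(self.states) - 1, 0)

    def labels(self) -> list[str]:
        return [state_label(s) for s in self.states]


@dataclass
class TransitionModel:
    """First-order transition counts/probabilities over observed states."""

    state_set: list
    count_matrix: np.ndarray
    conditional_probs: np.ndarray
    marginal_freqs: np.ndarray
    absent_rows: np.ndarray = field(default=None)  # rows with no outgoing counts

    def __post_init__(self) -> None:
        k = len(self.state_set)
        if self.count_matrix.shape != (k, k):
            raise ValueError("count_matrix shape mismatch")
        if np.any(np.diag(self.count_matrix) != 0):
            raise ValueError("self-transitions are structurally impossible")
        if self.absent_rows is None:
            self.absent_rows = self.count_matrix.sum(axis=1) == 0


@dataclass
class EntropyRate:
    value_bits: float
    n_transitions: int
    n_states_observed: int

    def __post_init__(self) -> None:
        if self.n_states_observed >= 1:
            upper = np.log2(max(self.n_states_observed, 1)) if self.n_states_observed > 1 else 0.0
            if not (-1e-12 <= self.value_bits <= upper + 1e-9):
                raise ValueError(
                    f"entropy {self.value_bits} outside [0, log2({self.n_states_observed})]"
                )


def events_to_state_sequence(
    log: SensoryEventLog, include_leading_empty: bool = True
) -> SignalStateSequence:
    """Convert timed modality intervals into the composite-state change sequence.

    At every time point the active state is the set of modalities whose coded
    intervals cover it (half-open [onset, offset)).  The output records each
    change point; consecutive duplicate states (e.g. an auditory offset
    coinciding with an auditory onset) are collapsed.  With
    ``include_leading_empty`` the session is taken to start in the no-signal
    (empty-set) state at t = 0, so the entry into the first signal counts as a
    transition.
    """
    if not log.events:
        return SignalStateSequence(states=[frozenset()], change_times_s=[0.0])

    # sweep: apply all on/off deltas at each distinct time, then emit the state
    deltas: list[tuple[float, int, str]] = []
    for m, on, off in log.events:
        deltas.append((on, +1, m))
        deltas.append((off, -1, m))
    deltas.sort(key=lambda d: d[0])

    states: list[frozenset] = []
    change_times: list[float] = []
    if include_leading_empty:
        states.append(frozenset())
        change_times.append(0.0)
    counts = dict.fromkeys(MODALITIES, 0)
    i, n = 0, len(deltas)
    while i < n:
        t = deltas[i][0]
        while i < n and abs(deltas[i][0] - t) <= 1e-12:
            _, d, m = deltas[i]
            counts[m] += d
            i += 1
        if t >= log.session_duration_s - 1e-9:
            break  # truncation at the session boundary is not a transition
        active = frozenset(m for m, c in counts.items() if c > 0)
        if not states or active != states[-1]:
            states.append(active)
            change_times.append(t)
    return SignalStateSequence(states=states, change_times_s=change_times)


def estimate_transition_model(seq: SignalStateSequence) -> TransitionModel:
    """Row-normalized transition counts and empirical source-state frequencies."""
    if len(seq.states) < 2:
        raise ValueError("need at least 2 states to estimate transitions")
    observed = sorted(set(seq.states), key=state_label)
    index = {s: i for i, s in enumerate(observed)}
    k = len(observed)
    counts = np.zeros((k, k), dtype=np.int64)
    for a, b in zip(seq.states, seq.states[1:]):
        counts[index[a], index[b]] += 1
    row_sums = counts.sum(axis=1)
    probs = np.zeros((k, k))
    nz = row_sums > 0
    probs[nz] = counts[nz] / row_sums[nz, None]
    pi = row_sums / row_sums.sum()
    return TransitionModel(
        state_set=observed,
        count_matrix=counts,
        conditional_probs=probs,
        marginal_freqs=pi,
        absent_rows=~nz,
    )


def entropy_rate(model: TransitionModel) -> EntropyRate:
    """Plug-in Shannon entropy rate, in bits per transition.

    ``0 * log 0`` is taken as 0; rows with no outgoing counts contribute 0.
    """
    P = model.conditional_probs
    pi = model.marginal_freqs
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(P > 0, P * np.log2(P), 0.0)
    row_entropy = -plogp.sum(axis=1)
    row_entropy[model.absent_rows] = 0.0
    value = float(pi @ row_entropy)
    return EntropyRate(
        value_bits=max(value, 0.0),
        n_transitions=int(model.count_matrix.sum()),
        n_states_observed=len(model.state_set),
    )


def _presence_matrix(log: SensoryEventLog, bin_s: float, n_bins: int) -> np.ndarray:
    """Binary (modality x bin) matrix: modality active during any part of bin."""
    present = np.zeros((len(MODALITIES), n_bins), dtype=bool)
    edges = np.arange(n_bins + 1) * bin_s
    for modality, onset, offset in log.events:
        i = MODALITIES.index(modality)
        lo = int(np.searchsorted(edges, onset, side="right")) - 1
        hi = int(np.searchsorted(edges, offset, side="left"))
        for b in range(max(lo, 0), min(hi, n_bins)):
            if min(offset, edges[b + 1]) - max(onset, edges[b]) > 1e-12:
                present[i, b] = True
    return present


def interrater_reliability(
    log_a: SensoryEventLog, log_b: SensoryEventLog, bin_s: float = 1.0
) -> tuple[float, float]:
    """Raw percent agreement and Cohen's kappa between two coders' event logs.

    The session is discretized into ``bin_s`` bins; per modality the coders'
    binary presence series are compared.  Raw agreement is the fraction of
    matching bins (x100) and kappa is (p_o - p_e)/(1 - p_e) with chance
    agreement p_e from marginal bin rates; both are averaged across the three
    modalities.  Degenerate kappa (p_e == 1, both coders constant) is defined
    as 1 when the constant labels agree and 0 otherwise.
    """
    if bin_s <= 0:
        raise ValueError("bin_s must be positive")
    if abs(log_a.session_duration_s - log_b.session_duration_s) > 1e-9:
        raise ValueError("session durations differ between coders")
    n_bins = int(np.ceil(log_a.session_duration_s / bin_s - 1e-12))
    pa = _presence_matrix(log_a, bin_s, n_bins)
    pb = _presence_matrix(log_b, bin_s, n_bins)
    agreements, kappas = [], []
    for i in range(len(MODALITIES)):
        a, b = pa[i], pb[i]
        p_o = float(np.mean(a == b))
        ra, rb = float(a.mean()), float(b.mean())
        p_e = ra * rb + (1 - ra) * (1 - rb)
        if abs(1 - p_e) < 1e-12:
            kappa = 1.0 if p_o > 1 - 1e-12 else 0.0
        else:
            kappa = (p_o - p_e) / (1 - p_e)
        agreements.append(p_o * 100.0)
        kappas.append(kappa)
    return float(np.mean(agreements)), float(np.mean(kappas))
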
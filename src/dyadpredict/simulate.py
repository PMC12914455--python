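"""Synthetic dyad generators.

Every input the measurement pipeline consumes can be generated here with the
statistical structure the downstream analysis assumes:

* caregiver sensory event logs realized from a first-order Markov chain over
  composite sensory states, with exponential dwell times (the entropy stage
  only uses transition order, so timing merely sets how many transitions fit
  into a 5-min interaction);
* inter-beat-interval series with AR(1) beat-to-beat jitter plus a
  respiratory-frequency sinusoid, calibrated in closed form to a target
  RMSSD, with optional planted deceleration epochs;
* 1/f ("pink") EEG whose 4-6 Hz band power is multiplied by a gain factor
  during attention phases;
* a cohort of dyads drawn from a linear structural model with planted
  standardized effects and per-variable MCAR missingness.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, signal

from .eeg import ATTENTION, EEGRecord
from .entropy import MODALITIES, SensoryEventLog

__all__ = [
    "CaregiverSimConfig",
    "CardiacSimConfig",
    "CohortSimConfig",
    "all_composite_states",
    "stationary_distribution",
    "markov_entropy_rate",
    "transition_matrix_for_entropy",
    "sample_markov_chain",
    "simulate_caregiver_sequence",
    "simulate_ibi",
    "simulate_eeg",
    "simulate_cohort",
    "simulate_cohort_parts",
]


# ---------------------------------------------------------------------------
# Markov-chain caregiver signals
# ---------------------------------------------------------------------------

def all_composite_states(include_empty: bool = True) -> list[frozenset]:
    """The (up to 8) composite sensory states, in a fixed deterministic order."""
    states = []
    for r in range(0 if include_empty else 1, len(MODALITIES) + 1):
        for combo in itertools.combinations(MODALITIES, r):
            states.append(frozenset(combo))
    return states


@dataclass
class CaregiverSimConfig:
    """Markov-chain configuration for a simulated play interaction."""

    state_labels: list
    transition_matrix: np.ndarray
    mean_dwell_s: float = 2.0
    duration_s: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        k = len(self.state_labels)
        P = self.transition_matrix
        if P.shape != (k, k):
            raise ValueError("transition matrix shape must match state_labels")
        if np.any(P < -1e-15):
            raise ValueError("transition probabilities must be non-negative")
        if np.max(np.abs(P.sum(axis=1) - 1.0)) > 1e-12:
            raise ValueError("rows of transition_matrix must sum to 1")
        if np.any(np.abs(np.diag(P)) > 1e-15):
            raise ValueError("diagonal must be 0: an event is a state change")
        if self.mean_dwell_s <= 0 or self.duration_s <= 0:
            raise ValueError("mean_dwell_s and duration_s must be positive")


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of an irreducible chain (left eigenvector)."""
    P = np.asarray(P, dtype=float)
    vals, vecs = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def markov_entropy_rate(P: np.ndarray, pi: np.ndarray | None = None) -> float:
    """Closed-form entropy rate -sum_i pi_i sum_j P(j|i) log2 P(j|i), in bits."""
    P = np.asarray(P, dtype=float)
    if pi is None:
        pi = stationary_distribution(P)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(P > 0, P * np.log2(P), 0.0)
    return float(-(pi * plogp.sum(axis=1)).sum())


def _cycle_spread_matrix(p: float, k: int) -> np.ndarray:
    """Row i: prob 1-p to the cycle-next state, p/(k-2) to each other state."""
    P = np.full((k, k), p / (k - 2))
    np.fill_diagonal(P, 0.0)
    for i in range(k):
        P[i, (i + 1) % k] = 1.0 - p
    return P


def transition_matrix_for_entropy(h_bits: float, n_states: int = 8) -> np.ndarray:
    """A k-state matrix whose entropy rate equals ``h_bits``.

    Uses a one-parameter family interpolating between a deterministic cycle
    (0 bits) and a uniform off-diagonal row (log2(k-1) bits); the family is
    doubly stochastic, so its stationary distribution is uniform and the
    entropy rate equals the common row entropy.
    """
    k = n_states
    if k < 3:
        raise ValueError("need at least 3 states")
    p_max = (k - 2) / (k - 1)  # uniform row
    h_max = np.log2(k - 1)
    if not (0 <= h_bits <= h_max + 1e-12):
        raise ValueError(f"entropy {h_bits} outside [0, log2({k - 1})]")
    if h_bits <= 1e-12:
        return _cycle_spread_matrix(0.0, k)
    if h_bits >= h_max - 1e-12:
        return _cycle_spread_matrix(p_max, k)

    def row_entropy(p):
        return -(1 - p) * np.log2(1 - p) - p * np.log2(p / (k - 2))

    p = optimize.brentq(lambda q: row_entropy(q) - h_bits, 1e-12, p_max)
    return _cycle_spread_matrix(p, k)


def sample_markov_chain(
    P: np.ndarray, n_steps: int, rng: np.random.Generator, init: int | None = None
) -> np.ndarray:
    """Sample a state-index path of length ``n_steps`` from transition matrix P."""
    P = np.asarray(P, dtype=float)
    k = P.shape[0]
    cum = np.cumsum(P, axis=1)
    states = np.empty(n_steps, dtype=np.int64)
    if init is None:
        init = int(rng.choice(k, p=stationary_distribution(P)))
    states[0] = init
    u = rng.random(n_steps)
    for t in range(1, n_steps):
        states[t] = np.searchsorted(cum[states[t - 1]], u[t])
    return states


def simulate_caregiver_sequence(cfg: CaregiverSimConfig) -> SensoryEventLog:
    """Realize the configured chain as a timed caregiver sensory event log.

    Dwell times are exponential with mean ``mean_dwell_s``; the induced
    composite-state sequence is a realization of the configured Markov chain,
    truncated at ``duration_s``.  Modalities active in consecutive states are
    merged into single on/off intervals.
    """
    rng = np.random.default_rng(cfg.seed)
    n_expect = int(np.ceil(cfg.duration_s / cfg.mean_dwell_s * 2)) + 20
    dwells = rng.exponential(cfg.mean_dwell_s, size=n_expect)
    while dwells.sum() < cfg.duration_s:  # pragma: no cover - margin is generous
        dwells = np.concatenate([dwells, rng.exponential(cfg.mean_dwell_s, size=n_expect)])
    t_enter = np.concatenate([[0.0], np.cumsum(dwells)])
    # states entered strictly before duration_s; the last dwell is truncated
    n_states = max(int(np.searchsorted(t_enter, cfg.duration_s)), 2)
    path = sample_markov_chain(cfg.transition_matrix, n_states, rng)

    # modality intervals from the state timeline, merging across contiguity
    events: list[tuple[str, float, float]] = []
    for modality in MODALITIES:
        active = np.array(
            [modality in cfg.state_labels[s] for s in path], dtype=bool
        )
        start = None
        for i, on in enumerate(active):
            t0 = t_enter[i]
            t1 = min(t_enter[i + 1], cfg.duration_s)
            if on and start is None:
                start = t0
            if not on and start is not None:
                events.append((modality, start, t_enter[i]))
                start = None
            if t1 >= cfg.duration_s:
                if on and start is not None:
                    events.append((modality, start, cfg.duration_s))
                    start = None
                break
    events.sort(key=lambda e: (e[1], e[0]))
    return SensoryEventLog(events=events, session_duration_s=cfg.duration_s)


# ---------------------------------------------------------------------------
# Cardiac (IBI) series
# ---------------------------------------------------------------------------

@dataclass
class CardiacSimConfig:
    """IBI-series generator configuration.

    The noise model is AR(1) beat-to-beat jitter plus a respiratory-frequency
    sinusoid, each calibrated in closed form to contribute half of the target
    RMSSD^2.  ``decel_epochs`` plants (onset_s, offset_s, delta_ibi_ms)
    heart-rate decelerations by elevating the IBI inside each window.
    """

    baseline_ibi_ms: float = 400.0
    rmssd_target_ms: float = 11.23
    decel_epochs: list = field(default_factory=list)
    duration_s: float = 300.0
    seed: int = 0
    ar_phi: float = 0.4
    resp_freq_hz: float = 0.6

    def __post_init__(self) -> None:
        if not (250.0 <= self.baseline_ibi_ms <= 1000.0):
            raise ValueError("baseline_ibi_ms must lie in [250, 1000] ms")
        if self.rmssd_target_ms < 0:
            raise ValueError("rmssd_target_ms must be >= 0")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        epochs = sorted(self.decel_epochs)
        for on, off, _ in epochs:
            if not (0 <= on < off <= self.duration_s + 1e-9):
                raise ValueError(f"epoch [{on}, {off}] outside [0, {self.duration_s}]")
        for (_, a1, _), (b0, _, _) in zip(epochs, epochs[1:]):
            if b0 < a1 - 1e-12:
                raise ValueError("decel epochs must not overlap")
        self.decel_epochs = epochs


def simulate_ibi(cfg: CardiacSimConfig):
    """Generate an IBI series with the configured RMSSD and planted epochs.

    Beat-to-beat variability decomposes as RMSSD^2 = 2*sigma_x^2*(1-phi)
    (AR(1) part, stationary variance sigma_x^2) + 2*A^2*sin^2(pi*f*T) (sampled
    sinusoid of amplitude A at the mean beat period T); each part is assigned
    half the target.  Respiratory phase and epoch membership are evaluated on
    the nominal (mean-IBI) beat grid; cumulative beat times carry the jitter.
    """
    from .cardiac import IBISeries

    n_beats = int(np.ceil(cfg.duration_s * 1000.0 / cfg.baseline_ibi_ms)) + 2
    if n_beats < 10:
        raise ValueError("duration too short for at least 10 beats")
    rng = np.random.default_rng(cfg.seed)
    T = cfg.baseline_ibi_ms / 1000.0
    t_nominal = np.arange(n_beats - 1) * T  # one per IBI

    target_sq = cfg.rmssd_target_ms**2
    phi = cfg.ar_phi
    var_x = (target_sq / 2.0) / (2.0 * (1.0 - phi))
    sin_term = np.sin(np.pi * cfg.resp_freq_hz * T) ** 2
    amp = np.sqrt((target_sq / 2.0) / (2.0 * sin_term)) if sin_term > 0 else 0.0

    if var_x > 0:
        innov_sd = np.sqrt(var_x * (1.0 - phi**2))
        e = rng.standard_normal(n_beats - 1) * innov_sd
        e[0] = rng.standard_normal() * np.sqrt(var_x)
        ar = signal.lfilter([1.0], [1.0, -phi], e)
    else:
        ar = np.zeros(n_beats - 1)
    phase0 = rng.uniform(0, 2 * np.pi)
    resp = amp * np.sin(2 * np.pi * cfg.resp_freq_hz * t_nominal + phase0)

    ibi = cfg.baseline_ibi_ms + ar + resp
    for on, off, delta in cfg.decel_epochs:
        ibi[(t_nominal >= on) & (t_nominal < off)] += delta
    ibi = np.maximum(ibi, 100.0)  # physiologic floor; effectively never binds

    beat_times = np.concatenate([[0.0], np.cumsum(ibi) / 1000.0])
    keep = beat_times <= cfg.duration_s + 1e-9
    beat_times = beat_times[keep]
    if len(beat_times) < 10:
        raise ValueError("duration too short for at least 10 beats")
    return IBISeries(beat_times_s=beat_times, _ibi_ms=ibi[: len(beat_times) - 1])


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------

def simulate_eeg(
    phases,
    sr_hz: float = 250.0,
    n_channels: int = 64,
    theta_gain: float = 1.0,
    duration_s: float | None = None,
    theta_band: tuple[float, float] = (4.0, 6.0),
    channel_names: list[str] | None = None,
    seed: int = 0,
    start_time_s: float = 0.0,
) -> EEGRecord:
    """Pink-noise EEG with theta power multiplied by ``theta_gain`` in attention.

    Channels are synthesized second by second in the frequency domain with a
    1/f amplitude spectrum and random phases; for 1-s segments whose midpoint
    falls inside a sustained-attention phase, the amplitudes of the theta-band
    bins are scaled by sqrt(theta_gain), multiplying their power by the gain.
    An empty phase list yields unmodulated noise.
    """
    if sr_hz < 125:
        raise ValueError("sampling rate must be >= 125 Hz")
    if theta_gain <= 0:
        raise ValueError("theta_gain must be positive")
    sa = [
        (p.onset_s, p.offset_s)
        for p in phases
        if getattr(p, "kind", ATTENTION) in ("sustained_attention", ATTENTION)
    ]
    if duration_s is None:
        if not sa:
            raise ValueError("duration_s required when no phases are given")
        duration_s = max(off for _, off in sa) - start_time_s
    n_samp = int(round(sr_hz))
    n_seg = int(np.floor(duration_s))
    if n_seg < 1:
        raise ValueError("duration too short for a single 1-s segment")

    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n_samp, d=1.0 / sr_hz)
    base_amp = np.zeros_like(freqs)
    base_amp[freqs >= 1.0] = 1.0 / np.sqrt(freqs[freqs >= 1.0])
    theta_mask = (freqs >= theta_band[0] - 1e-9) & (freqs <= theta_band[1] + 1e-9)

    data = np.empty((n_channels, n_seg * n_samp))
    gain_amp = np.sqrt(theta_gain)
    for k in range(n_seg):
        mid = start_time_s + k + 0.5
        amp = base_amp.copy()
        if any(on <= mid < off for on, off in sa):
            amp[theta_mask] *= gain_amp
        phases_rand = rng.uniform(0, 2 * np.pi, size=(n_channels, len(freqs)))
        spec = amp * np.exp(1j * phases_rand)
        spec[:, 0] = 0.0
        if n_samp % 2 == 0:
            spec[:, -1] = np.real(spec[:, -1])
        data[:, k * n_samp : (k + 1) * n_samp] = np.fft.irfft(spec, n=n_samp, axis=1)

    if channel_names is None and n_channels == 64:
        channel_names = [f"E{i + 1}" for i in range(64)]
    return EEGRecord(
        data=data, sr_hz=sr_hz, channel_names=channel_names, start_time_s=start_time_s
    )


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

#: Descriptive scale (mean, SD) of each study variable in natural units.
COHORT_SCALES = {
    "entropy_bits": (0.79, 0.32),
    "rmssd_ms": (11.23, 4.65),
    "mean_hr_bpm": (150.0, 12.0),
    "deceleration_ms": (20.16, 22.83),
    "sa_duration_s": (124.13, 67.12),
    "theta_change": (0.01, 0.02),
    "age_months": (3.47, 0.39),
    "gestational_age_weeks": (39.21, 1.22),
}

MEASURED_VARS = (
    "entropy_bits",
    "rmssd_ms",
    "mean_hr_bpm",
    "sa_duration_s",
    "deceleration_ms",
    "theta_change",
)


@dataclass
class CohortSimConfig:
    """Structural model for a cohort of dyads with planted standardized effects.

    The planted betas are *conditional* standardized coefficients of the
    models the pipeline fits: mean heart rate enters the HRV equation as an
    exogenous regressor (``beta_hr_hrv``), so the entropy->HRV coefficient is
    recovered exactly by a regression adjusting for mean HR.  Missingness is
    MCAR, independent per measured variable, at per-variable rates drawn
    uniformly from ``missing_rate_range``.
    """

    n: int = 104
    beta_entropy_theta: float = -0.24
    beta_entropy_decel: float = -0.26
    beta_entropy_hrv: float = -0.25
    beta_hrv_decel: float = 0.25
    beta_entropy_sa: float = -0.07
    beta_hr_hrv: float = -0.40
    missing_rate_range: tuple[float, float] = (0.11, 0.23)
    covariate_effects: dict = field(default_factory=dict)
    prop_male: float = 64 / 104
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ValueError("n must be >= 4")
        lo, hi = self.missing_rate_range
        if not (0 <= lo <= hi < 1):
            raise ValueError("missing rates must lie in [0, 1)")
        for name in (
            "beta_entropy_theta",
            "beta_entropy_decel",
            "beta_entropy_hrv",
            "beta_hrv_decel",
            "beta_entropy_sa",
            "beta_hr_hrv",
        ):
            if not (-1 < getattr(self, name) < 1):
                raise ValueError(f"{name} must lie in (-1, 1)")


def _residual_sd(total_explained_var: float, context: str) -> float:
    resid = 1.0 - total_explained_var
    if resid <= 0:
        raise ValueError(
            f"planted model implies non-positive residual variance for {context}"
        )
    return float(np.sqrt(resid))


def simulate_cohort_parts(cfg: CohortSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Complete cohort table and its boolean MCAR mask (True = missing)."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n

    z_ent = rng.standard_normal(n)
    z_hr = rng.standard_normal(n)
    sex = (rng.random(n) < cfg.prop_male).astype(int)
    z_age = rng.standard_normal(n)
    z_gest = rng.standard_normal(n)
    p = cfg.prop_male
    z_sex = (sex - p) / np.sqrt(p * (1 - p))
    cov_z = {"age_months": z_age, "sex": z_sex, "gestational_age_weeks": z_gest}

    def cov_term(var: str) -> tuple[np.ndarray, float]:
        effects = cfg.covariate_effects.get(var, {})
        contrib = np.zeros(n)
        var_sum = 0.0
        for cov_name, b in effects.items():
            contrib += b * cov_z[cov_name]
            var_sum += b**2
        return contrib, var_sum

    c_hrv, v_hrv = cov_term("rmssd_ms")
    z_hrv = (
        cfg.beta_entropy_hrv * z_ent
        + cfg.beta_hr_hrv * z_hr
        + c_hrv
        + _residual_sd(cfg.beta_entropy_hrv**2 + cfg.beta_hr_hrv**2 + v_hrv, "rmssd_ms")
        * rng.standard_normal(n)
    )

    c_dec, v_dec = cov_term("deceleration_ms")
    # entropy and hrv are correlated predictors of deceleration
    rho_eh = cfg.beta_entropy_hrv
    explained_dec = (
        cfg.beta_entropy_decel**2
        + cfg.beta_hrv_decel**2
        + 2 * cfg.beta_entropy_decel * cfg.beta_hrv_decel * rho_eh
        + v_dec
    )
    z_dec = (
        cfg.beta_entropy_decel * z_ent
        + cfg.beta_hrv_decel * z_hrv
        + c_dec
        + _residual_sd(explained_dec, "deceleration_ms") * rng.standard_normal(n)
    )

    c_theta, v_theta = cov_term("theta_change")
    z_theta = (
        cfg.beta_entropy_theta * z_ent
        + c_theta
        + _residual_sd(cfg.beta_entropy_theta**2 + v_theta, "theta_change")
        * rng.standard_normal(n)
    )

    c_sa, v_sa = cov_term("sa_duration_s")
    z_sa = (
        cfg.beta_entropy_sa * z_ent
        + c_sa
        + _residual_sd(cfg.beta_entropy_sa**2 + v_sa, "sa_duration_s")
        * rng.standard_normal(n)
    )

    def scaled(name: str, z: np.ndarray) -> np.ndarray:
        mean, sd = COHORT_SCALES[name]
        return mean + sd * z

    df = pd.DataFrame(
        {
            "dyad_id": [f"d{i:04d}" for i in range(n)],
            "entropy_bits": scaled("entropy_bits", z_ent),
            "rmssd_ms": scaled("rmssd_ms", z_hrv),
            "mean_hr_bpm": scaled("mean_hr_bpm", z_hr),
            "sa_duration_s": scaled("sa_duration_s", z_sa),
            "deceleration_ms": scaled("deceleration_ms", z_dec),
            "theta_change": scaled("theta_change", z_theta),
            "age_months": scaled("age_months", z_age),
            "sex": sex,
            "gestational_age_weeks": np.clip(
                scaled("gestational_age_weeks", z_gest), 36.0, 42.0
            ),
        }
    )

    lo, hi = cfg.missing_rate_range
    mask = pd.DataFrame(False, index=df.index, columns=list(MEASURED_VARS))
    for var in MEASURED_VARS:
        rate = rng.uniform(lo, hi) if hi > lo else lo
        mask[var] = rng.random(n) < rate
    return df, mask


def simulate_cohort(cfg: CohortSimConfig, apply_missingness: bool = True) -> pd.DataFrame:
    """Cohort table of dyad records (NaN where MCAR-masked)."""
    df, mask = simulate_cohort_parts(cfg)
    if apply_missingness:
        for var in MEASURED_VARS:
            df.loc[mask[var], var] = np.nan
    return df
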
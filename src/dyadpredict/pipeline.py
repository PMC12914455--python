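"""End-to-end orchestration: simulate -> measure -> assemble -> fit -> report.

A run draws a latent cohort from the structural model, realizes each dyad's
raw signals (caregiver event log, baseline and task IBI series, EEG) to match
its latent values, re-measures every analysis variable through the package's
own measurement operations, applies the MCAR masks, and fits the regression
models with the chosen estimator.  All randomness flows from one root seed
via spawned per-stage, per-dyad seed sequences, so a run is reproducible
byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import attention as att
from . import cardiac, eeg, entropy, simulate
from .fiml import FIMLConvergenceError, fit_fiml_regression
from .stats import fit_listwise, fit_mice, fit_robust

__all__ = [
    "RunConfig",
    "RunResult",
    "run_pipeline",
    "assemble_cohort",
    "report_descriptives",
    "MODEL_SPECS",
]

ALL_STAGES = ("entropy", "hrv", "attention", "eeg", "fit")
BASE_COVARIATES = ("age_months", "sex", "gestational_age_weeks")

#: name -> (outcome, predictors, covariates); mean baseline HR is forced into
#: every model involving RMSSD by construction of this table.
MODEL_SPECS = {
    "entropy->decel": ("deceleration_ms", ("entropy_bits",), BASE_COVARIATES),
    "entropy->sa": ("sa_duration_s", ("entropy_bits",), BASE_COVARIATES),
    "entropy->theta": ("theta_change", ("entropy_bits",), BASE_COVARIATES),
    "entropy->hrv": (
        "rmssd_ms",
        ("entropy_bits",),
        ("mean_hr_bpm",) + BASE_COVARIATES,
    ),
    "hrv->decel": (
        "deceleration_ms",
        ("rmssd_ms",),
        ("mean_hr_bpm",) + BASE_COVARIATES,
    ),
    "hrv->sa": ("sa_duration_s", ("rmssd_ms",), ("mean_hr_bpm",) + BASE_COVARIATES),
    "hrv->theta": ("theta_change", ("rmssd_ms",), ("mean_hr_bpm",) + BASE_COVARIATES),
}

_PIPELINE_CHANNELS = (
    [f"E{e}" for e in eeg.FRONTAL_ELECTRODES] + ["E1", "E4", "E7"]
)


@dataclass
class RunConfig:
    """Configuration of a full synthetic-study run."""

    n_dyads: int = 104
    seed: int = 0
    stages: tuple = ALL_STAGES
    estimator: str = "fiml"
    # caregiver interaction
    interaction_duration_s: float = 300.0
    mean_dwell_s: float = 2.0
    n_states: int = 8
    # cardiac
    baseline_duration_s: float = 300.0
    task_onset_s: float = 10.0
    task_duration_s: float = 281.0
    # EEG
    eeg_sr_hz: float = 250.0
    min_eeg_segments: int = 20
    # cohort structural model (planted standardized effects)
    beta_entropy_theta: float = -0.24
    beta_entropy_decel: float = -0.26
    beta_entropy_hrv: float = -0.25
    beta_hrv_decel: float = 0.25
    beta_entropy_sa: float = -0.07
    beta_hr_hrv: float = -0.40
    missing_rate_range: tuple = (0.11, 0.23)
    write_raw: bool = False

    def cohort_config(self, seed: int) -> simulate.CohortSimConfig:
        return simulate.CohortSimConfig(
            n=self.n_dyads,
            beta_entropy_theta=self.beta_entropy_theta,
            beta_entropy_decel=self.beta_entropy_decel,
            beta_entropy_hrv=self.beta_entropy_hrv,
            beta_hrv_decel=self.beta_hrv_decel,
            beta_entropy_sa=self.beta_entropy_sa,
            beta_hr_hrv=self.beta_hr_hrv,
            missing_rate_range=tuple(self.missing_rate_range),
            seed=seed,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "missing_rate_range" in raw:
            raw["missing_rate_range"] = tuple(raw["missing_rate_range"])
        return cls(**raw)

    def to_yaml(self) -> str:
        d = asdict(self)
        d["stages"] = list(d["stages"])
        d["missing_rate_range"] = list(d["missing_rate_range"])
        return yaml.safe_dump(d, sort_keys=True)


@dataclass
class RunResult:
    cohort: pd.DataFrame
    results: pd.DataFrame
    descriptives: pd.DataFrame
    manifest: dict
    models: dict = field(default_factory=dict)


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def assemble_cohort(frames: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Outer-join per-stage outputs on dyad_id; missing measurements stay NaN."""
    out = None
    for name, frame in frames.items():
        if frame["dyad_id"].duplicated().any():
            dup = frame.loc[frame["dyad_id"].duplicated(), "dyad_id"].iloc[0]
            raise ValueError(f"duplicate dyad_id {dup!r} in stage {name!r}")
        out = frame if out is None else out.merge(frame, on="dyad_id", how="outer")
    if out is None:
        raise ValueError("no stage outputs to assemble")
    return out.sort_values("dyad_id", kind="stable").reset_index(drop=True)


def report_descriptives(df: pd.DataFrame, variables=None) -> pd.DataFrame:
    """Mean, SD, range, skew and kurtosis per analysis variable."""
    if variables is None:
        variables = [c for c in df.columns if df[c].dtype.kind in "fiu"]
    rows = []
    for v in variables:
        x = df[v].to_numpy(dtype=float)
        x = x[np.isfinite(x)]
        if len(x) == 0:
            continue
        rows.append(
            {
                "variable": v,
                "n": len(x),
                "mean": float(np.mean(x)),
                "sd": float(np.std(x, ddof=1)) if len(x) > 1 else np.nan,
                "min": float(np.min(x)),
                "max": float(np.max(x)),
                "skew": float(sps.skew(x)) if len(x) > 2 else np.nan,
                "kurtosis": float(sps.kurtosis(x)) if len(x) > 3 else np.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Per-dyad measurement stages
# ---------------------------------------------------------------------------

def _measure_entropy(latent_row, cfg: RunConfig, seed: int):
    h_max = np.log2(cfg.n_states - 1)
    target = float(np.clip(latent_row["entropy_bits"], 0.02, h_max - 0.02))
    P = simulate.transition_matrix_for_entropy(target, cfg.n_states)
    sim_cfg = simulate.CaregiverSimConfig(
        state_labels=simulate.all_composite_states()[: cfg.n_states],
        transition_matrix=P,
        mean_dwell_s=cfg.mean_dwell_s,
        duration_s=cfg.interaction_duration_s,
        seed=seed,
    )
    log = simulate.simulate_caregiver_sequence(sim_cfg)
    seq = entropy.events_to_state_sequence(log)
    if len(seq.states) < 2:
        return np.nan, 0, log
    model = entropy.estimate_transition_model(seq)
    er = entropy.entropy_rate(model)
    return er.value_bits, er.n_transitions, log


def _measure_hrv(latent_row, cfg: RunConfig, seed: int):
    baseline_ibi = float(np.clip(60000.0 / latent_row["mean_hr_bpm"], 250.0, 1000.0))
    sim_cfg = simulate.CardiacSimConfig(
        baseline_ibi_ms=baseline_ibi,
        rmssd_target_ms=max(float(latent_row["rmssd_ms"]), 0.5),
        duration_s=cfg.baseline_duration_s,
        seed=seed,
    )
    series = simulate.simulate_ibi(sim_cfg)
    res = cardiac.baseline_hrv(series, clean=False)
    return res.rmssd_ms, res.mean_hr_bpm, series


def _decel_epochs(cfg: RunConfig, delta: float):
    t0 = cfg.task_onset_s
    windows = [(30, 60), (90, 120), (150, 180), (210, 240)]
    return [(t0 + a, t0 + b, delta) for a, b in windows]


def _measure_attention(latent_row, cfg: RunConfig, seed: int):
    baseline_ibi = float(np.clip(60000.0 / latent_row["mean_hr_bpm"], 250.0, 1000.0))
    delta = float(latent_row["deceleration_ms"])
    sim_cfg = simulate.CardiacSimConfig(
        baseline_ibi_ms=baseline_ibi,
        rmssd_target_ms=max(float(latent_row["rmssd_ms"]), 0.5),
        decel_epochs=_decel_epochs(cfg, delta),
        duration_s=cfg.task_onset_s + cfg.task_duration_s + 2.0,
        seed=seed,
    )
    series = simulate.simulate_ibi(sim_cfg)
    looking = att.LookingRecord(
        intervals=[(cfg.task_onset_s, cfg.task_onset_s + cfg.task_duration_s)],
        task_onset_s=cfg.task_onset_s,
        task_duration_s=cfg.task_duration_s,
    )
    phases = att.detect_sustained_attention(series, looking)
    summary = att.summarize_attention(series, phases, cfg.task_onset_s)
    return summary, phases, series


def _measure_theta(latent_row, cfg: RunConfig, phases, seed: int):
    gain = max(0.25, 1.0 + float(latent_row["theta_change"]) / 0.01)
    record = simulate.simulate_eeg(
        phases=phases,
        sr_hz=cfg.eeg_sr_hz,
        n_channels=len(_PIPELINE_CHANNELS),
        theta_gain=gain,
        duration_s=cfg.task_duration_s,
        channel_names=list(_PIPELINE_CHANNELS),
        seed=seed,
        start_time_s=cfg.task_onset_s,
    )
    segset = eeg.segment_record(record, phases)
    segset = eeg.reject_amplitude_outliers(segset)
    summary = eeg.relative_theta(segset, min_segments=cfg.min_eeg_segments)
    return summary, record


# ---------------------------------------------------------------------------
# The run
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig, outdir=None) -> RunResult:
    """Execute the enabled stages in dependency order and fit the models."""
    unknown = set(config.stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    root = np.random.SeedSequence(config.seed)
    ss_cohort, ss_ent, ss_hrv, ss_att, ss_eeg = root.spawn(5)

    complete, mask = simulate.simulate_cohort_parts(
        config.cohort_config(_seed_int(ss_cohort))
    )
    n = len(complete)
    exclusions: list[dict] = []
    frames: dict[str, pd.DataFrame] = {
        "covariates": complete[
            ["dyad_id", "age_months", "sex", "gestational_age_weeks"]
        ].copy()
    }
    raw_dir = Path(outdir) / "raw" if (outdir and config.write_raw) else None
    if raw_dir:
        raw_dir.mkdir(parents=True, exist_ok=True)

    if "entropy" in config.stages:
        seeds = ss_ent.spawn(n)
        rows = []
        for i, (_, latent) in enumerate(complete.iterrows()):
            value, n_trans, log = _measure_entropy(latent, config, _seed_int(seeds[i]))
            rows.append(
                {
                    "dyad_id": latent["dyad_id"],
                    "entropy_bits": value,
                    "n_transitions": n_trans,
                }
            )
            if raw_dir:
                from .io import write_events_csv

                write_events_csv(log, raw_dir / f"{latent['dyad_id']}_events.csv")
        frames["entropy"] = pd.DataFrame(rows)

    if "hrv" in config.stages:
        seeds = ss_hrv.spawn(n)
        rows = []
        for i, (_, latent) in enumerate(complete.iterrows()):
            rmssd_val, hr_val, series = _measure_hrv(latent, config, _seed_int(seeds[i]))
            rows.append(
                {
                    "dyad_id": latent["dyad_id"],
                    "rmssd_ms": rmssd_val,
                    "mean_hr_bpm": hr_val,
                }
            )
            if raw_dir:
                from .io import write_ibi_csv

                write_ibi_csv(series, raw_dir / f"{latent['dyad_id']}_baseline_ibi.csv")
        frames["hrv"] = pd.DataFrame(rows)

    phases_by_dyad: dict[str, list] = {}
    if "attention" in config.stages:
        seeds = ss_att.spawn(n)
        rows = []
        for i, (_, latent) in enumerate(complete.iterrows()):
            summary, phases, series = _measure_attention(
                latent, config, _seed_int(seeds[i])
            )
            phases_by_dyad[latent["dyad_id"]] = phases
            if summary.n_sa_phases == 0:
                exclusions.append(
                    {"dyad_id": latent["dyad_id"], "reason": "no SA phase"}
                )
            rows.append(
                {
                    "dyad_id": latent["dyad_id"],
                    "sa_duration_s": summary.total_sa_duration_s,
                    "deceleration_ms": summary.mean_deceleration_ms,
                    "n_sa_phases": summary.n_sa_phases,
                }
            )
            if raw_dir:
                from .io import write_ibi_csv, write_phases_csv

                write_ibi_csv(series, raw_dir / f"{latent['dyad_id']}_task_ibi.csv")
                write_phases_csv(
                    phases, raw_dir / f"{latent['dyad_id']}_phases.csv",
                    dyad_id=latent["dyad_id"],
                )
        frames["attention"] = pd.DataFrame(rows)

    if "eeg" in config.stages:
        if "attention" not in config.stages:
            raise ValueError("eeg stage requires the attention stage")
        seeds = ss_eeg.spawn(n)
        rows = []
        for i, (_, latent) in enumerate(complete.iterrows()):
            phases = phases_by_dyad[latent["dyad_id"]]
            summary, record = _measure_theta(latent, config, phases, _seed_int(seeds[i]))
            usable = (
                summary.n_segments_attention + summary.n_segments_inattention
                >= config.min_eeg_segments
            ) and np.isfinite(summary.theta_change)
            if not usable:
                exclusions.append(
                    {
                        "dyad_id": latent["dyad_id"],
                        "reason": f"< {config.min_eeg_segments} EEG segments",
                    }
                )
            rows.append(
                {
                    "dyad_id": latent["dyad_id"],
                    "theta_change": summary.theta_change,
                    "n_eeg_segments": summary.n_segments_attention
                    + summary.n_segments_inattention,
                    "n_eeg_rejected": summary.n_rejected,
                }
            )
            if raw_dir:
                from .io import write_eeg_npy

                write_eeg_npy(record, raw_dir / f"{latent['dyad_id']}_eeg")
        frames["eeg"] = pd.DataFrame(rows)

    cohort = assemble_cohort(frames)

    # MCAR masks from the latent generator
    for var in simulate.MEASURED_VARS:
        if var in cohort.columns:
            masked_ids = complete.loc[mask[var].to_numpy(), "dyad_id"]
            cohort.loc[cohort["dyad_id"].isin(masked_ids), var] = np.nan

    # cohort-level winsorization of the HRV variable
    if "rmssd_ms" in cohort.columns and cohort["rmssd_ms"].notna().sum() >= 2:
        cohort["rmssd_raw_ms"] = cohort["rmssd_ms"]
        cohort["rmssd_ms"] = cardiac.winsorize(cohort["rmssd_ms"].to_numpy())

    results_frames = []
    models: dict = {}
    skipped_models = []
    if "fit" in config.stages:
        fitters = {
            "fiml": fit_fiml_regression,
            "robust": fit_robust,
            "mice": fit_mice,
            "listwise": fit_listwise,
        }
        if config.estimator not in fitters:
            raise ValueError(f"unknown estimator {config.estimator!r}")
        fitter = fitters[config.estimator]
        for name, (outcome, predictors, covariates) in MODEL_SPECS.items():
            needed = [outcome, *predictors, *covariates]
            if any(c not in cohort.columns for c in needed):
                skipped_models.append({"model": name, "reason": "stage disabled"})
                continue
            if cohort[outcome].notna().sum() < 3 or any(
                cohort[p].notna().sum() < 3 for p in predictors
            ):
                skipped_models.append({"model": name, "reason": "insufficient data"})
                continue
            kwargs = {"seed": config.seed} if config.estimator == "mice" else {}
            try:
                res = fitter(cohort, outcome, list(predictors), list(covariates), **kwargs)
            except (ValueError, FIMLConvergenceError) as exc:
                skipped_models.append({"model": name, "reason": str(exc)})
                continue
            models[name] = res
            results_frames.append(res.to_frame(model=name))

    results = (
        pd.concat(results_frames, ignore_index=True)
        if results_frames
        else pd.DataFrame(
            columns=["model", "outcome", "term", "beta", "se", "p", "estimator", "n"]
        )
    )
    descriptives = report_descriptives(
        cohort,
        [
            v
            for v in (
                "entropy_bits",
                "theta_change",
                "deceleration_ms",
                "sa_duration_s",
                "rmssd_ms",
                "mean_hr_bpm",
            )
            if v in cohort.columns
        ],
    )

    config_yaml = config.to_yaml()
    manifest = {
        "config": yaml.safe_load(config_yaml),
        "config_sha256": hashlib.sha256(config_yaml.encode()).hexdigest(),
        "n_input_dyads": n,
        "n_assembled": int(len(cohort)),
        "exclusions": exclusions,
        "skipped_models": skipped_models,
        "stage_seeds": {
            "cohort": _seed_int(ss_cohort),
            "entropy": _seed_int(ss_ent),
            "hrv": _seed_int(ss_hrv),
            "attention": _seed_int(ss_att),
            "eeg": _seed_int(ss_eeg),
        },
    }

    if outdir:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        cohort.to_csv(out / "cohort.csv", index=False)
        results.to_csv(out / "results.csv", index=False)
        descriptives.to_csv(out / "descriptives.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))

    return RunResult(
        cohort=cohort,
        results=results,
        descriptives=descriptives,
        manifest=manifest,
        models=models,
    )
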
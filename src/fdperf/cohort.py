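"""Synthetic forced-desynchrony cohorts: participants and observation streams.

The study population this generator emulates is 17 healthy young adults on
two forced-desynchrony protocols with 42.85-h days: 8 on a Control schedule
(28.57 h wake / 14.28 h sleep opportunity) and 9 on chronic sleep
restriction (CSR: 32.85 h wake / 10 h sleep opportunity).  Each synthetic
participant carries an intrinsic circadian period near 24.2 h, an initial
phase placing the melatonin maximum in the biological night, and subject-
level random offsets on the performance-model parameters.

Streams generated per participant:

* hourly melatonin as a rectified cosine (``max(0, amp*cos)``) plus noise —
  a deliberate simplification whose only job is a well-defined fitted
  maximum for the phase estimator;
* VAS alertness every 30 min of scheduled wake, built from circadian,
  time-awake, and sleep-debt terms plus noise, clipped to [0, 100];
* objective performance at the battery cadences, generated from a
  performance :class:`~fdperf.model.ModelSpec` (log mean reaction time for
  the PVT, with per-trial lognormal reaction times supplying the session
  SD and the >500 ms lapse count; Poisson correct counts for ADD/DSST).

One master seed drives everything; per-participant substreams are derived
deterministically with ``numpy.random.SeedSequence.spawn``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import ModelSpec, VARIABLES, composite_X, predict, _link
from .protocol import CONTROL, CSR, ProtocolSpec, build_schedule, sleep_debt

__all__ = [
    "ParticipantTruth",
    "AlertnessParams",
    "CohortConfig",
    "GENERATING_PARAMS",
    "generating_spec",
    "draw_cohort",
    "true_phase",
    "simulate_melatonin",
    "simulate_alertness",
    "simulate_performance",
    "sample_design",
    "simulate_paired_dataset",
    "generate_cohort_observations",
]

#: Default generating parameters of the logistic performance model, in the
#: units of log(PVT mean reaction time in ms).  b1 = log(~300 ms) floor of a
#: well-rested session; the gain (b2*W + b3) spans roughly one log-unit when
#: rested and grows by b2 per hour of sleep debt; the sigmoid switches over
#: the alertness range (b4 + b5*X crosses 0 near X ~ 62); the circadian
#: amplitude b6 and wake-duration slope b8 are in alertness units.
GENERATING_PARAMS: Mapping[str, float] = {
    "b1": 5.7, "b2": 0.02, "b3": 1.0, "b4": 5.0, "b5": -0.08,
    "b6": 10.0, "b7": 180.0, "b8": -0.5,
}

#: PVT trial-level settings: trials per 10-min session and the lognormal
#: shape of within-session reaction times.
PVT_TRIALS = 90
PVT_RT_SHAPE = 0.35
LAPSE_THRESHOLD_MS = 500.0

#: ADD/DSST correct-count means decrease linearly in P (log PVT mean scale):
#: count_mean = max(0, ADD_INTERCEPT - ADD_SLOPE * P).
COUNT_INTERCEPT = 130.0
COUNT_SLOPE = 12.0


def generating_spec(params: Mapping[str, float] | None = None,
                    form: str = "logistic") -> ModelSpec:
    """Default generative performance model (all four variables active)."""
    return ModelSpec(form, frozenset(VARIABLES), dict(params or GENERATING_PARAMS))


@dataclass(frozen=True)
class AlertnessParams:
    """Generative model of VAS alertness.

    A = clip(a0 + subject intercept + a1*cos(C + phi_deg) + a2*T + a3*W
             + noise, 0, 100)

    Defaults place the alertness trough at the melatonin maximum
    (phi_deg = 180), lose ~0.7 points per hour awake and ~0.35 points per
    hour of sleep debt, with 5-point subject and residual SDs — chosen so
    rested means sit in the 70s-80s and the worst adverse-phase, long-wake,
    high-debt sessions reach the 20s-40s.
    """

    a0: float = 85.0
    a1: float = 10.0
    phi_deg: float = 180.0
    a2: float = -0.7
    a3: float = -0.35
    subject_sd: float = 5.0
    noise_sd: float = 5.0


@dataclass(frozen=True)
class ParticipantTruth:
    """Ground truth for one synthetic participant."""

    participant_id: str
    condition: str                      # "control" | "csr"
    intrinsic_period: float             # hours, in (23.5, 25.0)
    initial_phase: float                # degrees at FD start, [0, 360)
    subject_effects: Mapping[str, float] = field(default_factory=dict)
    noise_sd: float = 0.2               # residual SD of P

    def __post_init__(self) -> None:
        if not 23.5 < self.intrinsic_period < 25.0:
            raise ValueError("intrinsic_period must lie in (23.5, 25.0)")

    @property
    def peak_time(self) -> float:
        """t_elapsed (hours) of the first melatonin maximum at/after FD start."""
        return (-self.initial_phase % 360.0) / 360.0 * self.intrinsic_period

    @property
    def protocol(self) -> ProtocolSpec:
        return CSR if self.condition == "csr" else CONTROL


@dataclass
class CohortConfig:
    """Cohort-level generator settings (JSON/YAML serializable)."""

    n_control: int = 8
    n_csr: int = 9
    period_mean: float = 24.2
    period_sd: float = 0.1
    initial_phase_mean: float = 60.0    # degrees: melatonin max ~4 h before wake
    initial_phase_sd: float = 20.0
    noise_sd: float = 0.2
    re_sd_b1: float = 0.15
    re_sd_b3: float = 0.15
    alert_subject_sd: float = 5.0
    melatonin_amplitude: float = 10.0
    melatonin_noise_sd: float = 2.0
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        return cls(**d)


def _truncated_normal(rng, mean, sd, lo, hi):
    while True:
        x = rng.normal(mean, sd)
        if lo < x < hi:
            return float(x)


def draw_cohort(config: CohortConfig | None = None,
                seed: int | None = None) -> list[ParticipantTruth]:
    """Draw the synthetic cohort (default 8 Control + 9 CSR participants)."""
    cfg = config or CohortConfig()
    master = cfg.seed if seed is None else seed
    n_total = cfg.n_control + cfg.n_csr
    streams = np.random.SeedSequence(master).spawn(n_total)
    truths = []
    for i in range(n_total):
        rng = np.random.default_rng(streams[i])
        condition = "control" if i < cfg.n_control else "csr"
        period = _truncated_normal(rng, cfg.period_mean, cfg.period_sd, 23.5, 25.0)
        phase0 = float(rng.normal(cfg.initial_phase_mean, cfg.initial_phase_sd) % 360.0)
        effects = {
            "b1": float(rng.normal(0.0, cfg.re_sd_b1)),
            "b3": float(rng.normal(0.0, cfg.re_sd_b3)),
            "alert": float(rng.normal(0.0, cfg.alert_subject_sd)),
        }
        truths.append(ParticipantTruth(
            participant_id=f"p{i + 1:02d}",
            condition=condition,
            intrinsic_period=period,
            initial_phase=phase0,
            subject_effects=effects,
            noise_sd=cfg.noise_sd,
        ))
    return truths


def true_phase(truth: ParticipantTruth, t_elapsed) -> np.ndarray:
    """Ground-truth circadian phase in degrees at ``t_elapsed``."""
    t = np.asarray(t_elapsed, dtype=float)
    return (truth.initial_phase + t / truth.intrinsic_period * 360.0) % 360.0


def simulate_melatonin(truth: ParticipantTruth, times,
                       amplitude: float = 10.0, noise_sd: float = 2.0,
                       rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Rectified-cosine melatonin with Gaussian noise at the given times.

    concentration = max(0, amplitude * cos(2*pi*(t - peak)/period)) + noise;
    the peak drifts at the participant's intrinsic period.
    """
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    rng = rng or np.random.default_rng(0)
    t = np.asarray(times, dtype=float)
    phase_rad = 2.0 * np.pi * (t - truth.peak_time) / truth.intrinsic_period
    clean = np.maximum(0.0, amplitude * np.cos(phase_rad))
    conc = clean + (rng.normal(0.0, noise_sd, size=t.shape) if noise_sd > 0 else 0.0)
    return pd.DataFrame({
        "participant_id": truth.participant_id,
        "kind": "melatonin",
        "t_elapsed": t,
        "value": conc,
    })


def _alertness_values(truth: ParticipantTruth, t, t_since_wake, params: AlertnessParams,
                      rng: np.random.Generator | None) -> np.ndarray:
    t = np.asarray(t, float)
    T = np.asarray(t_since_wake, float)
    spec = truth.protocol
    C = true_phase(truth, t)
    W = np.array([sleep_debt(x, spec) for x in t])
    a = (params.a0 + truth.subject_effects.get("alert", 0.0)
         + params.a1 * np.cos(np.radians(C + params.phi_deg))
         + params.a2 * T + params.a3 * W)
    if params.noise_sd > 0 and rng is not None:
        a = a + rng.normal(0.0, params.noise_sd, size=a.shape)
    return np.clip(a, 0.0, 100.0)


def simulate_alertness(truth: ParticipantTruth, schedule: Sequence,
                       params: AlertnessParams | None = None,
                       rng: np.random.Generator | None = None) -> pd.DataFrame:
    """VAS alertness records at every scheduled VAS probe."""
    params = params or AlertnessParams()
    rng = rng or np.random.default_rng(0)
    vas_events = [e for e in schedule if e.kind == "vas"]
    t = np.array([e.t_elapsed for e in vas_events])
    tsw = np.array([e.t_since_wake for e in vas_events])
    return pd.DataFrame({
        "participant_id": truth.participant_id,
        "kind": "vas",
        "t_elapsed": t,
        "value": _alertness_values(truth, t, tsw, params, rng),
    })


def _subject_spec(model: ModelSpec, truth: ParticipantTruth) -> ModelSpec:
    p = dict(model.params)
    p["b1"] = p["b1"] + truth.subject_effects.get("b1", 0.0)
    p["b3"] = p["b3"] + truth.subject_effects.get("b3", 0.0)
    return ModelSpec(model.form, model.include, p)


def simulate_performance(truth: ParticipantTruth, schedule: Sequence,
                         alertness: pd.DataFrame,
                         model: ModelSpec | None = None,
                         rng: np.random.Generator | None = None,
                         noise_sd: float | None = None) -> pd.DataFrame:
    """Objective test records (PVT/ADD/DSST) at the scheduled battery times.

    The latent performance score is P = subject-model prediction + Gaussian
    noise.  PVT rows carry the session mean exp(P) in ms as ``value``, the
    SD of a per-trial lognormal reaction-time stream as ``sd_ms``, and the
    count of trials slower than 500 ms as ``lapses``.  ADD/DSST rows carry
    Poisson correct counts whose mean decreases linearly in P (floored at
    zero).  An alertness record must exist at each test time.
    """
    model = model or generating_spec()
    rng = rng or np.random.default_rng(0)
    sd = truth.noise_sd if noise_sd is None else noise_sd
    spec_p = truth.protocol
    sub = _subject_spec(model, truth)
    a_by_t = dict(zip(np.round(alertness["t_elapsed"].to_numpy(float), 9),
                      alertness["value"].to_numpy(float)))
    rows = []
    for e in schedule:
        if e.kind not in ("pvt", "add", "dsst"):
            continue
        key = round(e.t_elapsed, 9)
        if key not in a_by_t:
            raise ValueError(
                f"no alertness record at test time t={e.t_elapsed} "
                f"for {truth.participant_id}")
        A = a_by_t[key]
        C = float(true_phase(truth, e.t_elapsed))
        T = e.t_since_wake
        W = sleep_debt(e.t_elapsed, spec_p)
        X = composite_X(A, C, T, sub.params, sub.include)
        P = float(predict(sub, X, W))
        if sd > 0:
            P += float(rng.normal(0.0, sd))
        row = {"participant_id": truth.participant_id, "kind": e.kind,
               "t_elapsed": e.t_elapsed, "sd_ms": np.nan, "lapses": np.nan}
        if e.kind == "pvt":
            mean_ms = float(np.exp(P))
            mu = np.log(mean_ms) - 0.5 * PVT_RT_SHAPE ** 2
            trials = rng.lognormal(mu, PVT_RT_SHAPE, size=PVT_TRIALS)
            row["value"] = mean_ms
            row["sd_ms"] = float(np.std(trials, ddof=1))
            row["lapses"] = float(np.sum(trials > LAPSE_THRESHOLD_MS))
        else:
            lam = max(0.0, COUNT_INTERCEPT - COUNT_SLOPE * P)
            row["value"] = float(rng.poisson(lam))
        rows.append(row)
    return pd.DataFrame(rows, columns=["participant_id", "kind", "t_elapsed",
                                       "value", "sd_ms", "lapses"])


def sample_design(truth: ParticipantTruth, n_obs: int,
                  rng: np.random.Generator,
                  alert_params: AlertnessParams | None = None) -> pd.DataFrame:
    """Draw ``n_obs`` test-like design points (A, C, T, W) for one participant.

    Times are uniform over the scheduled wake episodes of the participant's
    protocol on a 0.5-h grid, emulating the covariate distribution of the
    paired-session tables without building the full event schedule; used by
    the parameter-recovery and model-selection simulation studies.
    """
    alert_params = alert_params or AlertnessParams()
    spec = truth.protocol
    grid = []
    for day in range(spec.n_days):
        t0 = day * spec.day_length
        # battery-like times: from 2 h after wake to the end of the episode
        tt = np.arange(t0 + 2.0, t0 + spec.wake_per_day - 1e-9, 0.5)
        grid.append(tt)
    grid = np.concatenate(grid)
    take = rng.choice(len(grid), size=n_obs, replace=n_obs > len(grid))
    t = np.sort(grid[take])
    tsw = t % spec.day_length
    A = _alertness_values(truth, t, tsw, alert_params, rng)
    return pd.DataFrame({
        "participant_id": truth.participant_id,
        "t_elapsed": t,
        "A": A,
        "C": true_phase(truth, t),
        "T": tsw,
        "W": [sleep_debt(x, spec) for x in t],
    })


def simulate_paired_dataset(truths: Sequence[ParticipantTruth],
                            n_obs: int = 300,
                            model: ModelSpec | None = None,
                            rng: np.random.Generator | None = None,
                            noise_sd: float | None = None,
                            alert_params: AlertnessParams | None = None
                            ) -> pd.DataFrame:
    """Ready-to-fit table (participant_id, A, C, T, W, P) for a whole cohort.

    P is the latent performance response generated from ``model`` with each
    participant's subject effects and residual noise — the direct input for
    parameter-recovery and AIC-selection simulation studies.
    """
    model = model or generating_spec()
    rng = rng or np.random.default_rng(0)
    frames = []
    for truth in truths:
        d = sample_design(truth, n_obs, rng, alert_params)
        sub = _subject_spec(model, truth)
        X = composite_X(d["A"], d["C"], d["T"], sub.params, sub.include)
        P = predict(sub, X, d["W"].to_numpy(float))
        sd = truth.noise_sd if noise_sd is None else noise_sd
        if sd > 0:
            P = P + rng.normal(0.0, sd, size=len(d))
        d["P"] = P
        frames.append(d)
    return pd.concat(frames, ignore_index=True)


def generate_cohort_observations(truths: Sequence[ParticipantTruth],
                                 config: CohortConfig | None = None,
                                 model: ModelSpec | None = None,
                                 alert_params: AlertnessParams | None = None,
                                 seed: int | None = None) -> pd.DataFrame:
    """Full long-format observation stream for every participant.

    Runs melatonin, alertness, and performance generation over each
    participant's protocol schedule; per-participant RNG substreams derive
    deterministically from the master seed.
    """
    cfg = config or CohortConfig()
    model = model or generating_spec()
    alert_params = alert_params or AlertnessParams(subject_sd=cfg.alert_subject_sd)
    master = cfg.seed if seed is None else seed
    streams = np.random.SeedSequence([master, 7]).spawn(len(truths))
    frames = []
    for truth, ss in zip(truths, streams):
        rng = np.random.default_rng(ss)
        schedule = build_schedule(truth.protocol, truth.participant_id)
        mel_t = [e.t_elapsed for e in schedule if e.kind == "melatonin"]
        mel = simulate_melatonin(truth, mel_t, cfg.melatonin_amplitude,
                                 cfg.melatonin_noise_sd, rng)
        vas = simulate_alertness(truth, schedule, alert_params, rng)
        perf = simulate_performance(truth, schedule, vas, model, rng)
        mel["sd_ms"] = np.nan
        mel["lapses"] = np.nan
        vas["sd_ms"] = np.nan
        vas["lapses"] = np.nan
        frames.append(pd.concat([mel, vas, perf], ignore_index=True))
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["participant_id", "t_elapsed", "kind"]).reset_index(drop=True)
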
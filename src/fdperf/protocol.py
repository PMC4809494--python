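"""Forced-desynchrony (FD) protocol schedules and elapsed-time accounting.

An FD protocol schedules sleep and wake to a "day" length outside the range
of entrainment of the circadian pacemaker (here 42.85 h), so that circadian
phase and time-since-wake decorrelate over the protocol.  This module builds
the event schedule of such a protocol (wake/sleep episodes, subjective
alertness probes, test batteries, hourly melatonin draws), computes the
cumulative sleep-debt trajectory implied by the schedule, and classifies
circadian phases and wake durations into the adverse/optimal windows used in
the downstream contingency analyses.

Times are decimal hours since the start of the FD portion of the protocol;
wake and sleep episodes are half-open intervals ``[start, end)``.  Baseline
(pre-FD) days are excluded from FD accounting entirely.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ProtocolSpec",
    "ScheduleEvent",
    "CONTROL",
    "CSR",
    "build_schedule",
    "schedule_frame",
    "sleep_debt",
    "sleep_debt_trajectory",
    "classify_phase_window",
    "classify_time_window",
    "ADVERSE_PHASE_DEG",
    "OPTIMAL_PHASE_DEG",
    "ADVERSE_TIME_H",
    "OPTIMAL_TIME_H",
]

#: Reference day: 16 h wakefulness / 8 h sleep per 24 h. Sleep debt is the
#: excess of scheduled wakefulness over this baseline rate.
BASELINE_WAKE_FRACTION = 16.0 / 24.0

# Adverse/optimal windows, closed intervals. Phase in degrees with 0 deg at
# the fitted melatonin maximum; adverse phase -30..90 deg brackets it.
ADVERSE_PHASE_DEG = (330.0, 90.0)  # wraps through 0
OPTIMAL_PHASE_DEG = (150.0, 270.0)
ADVERSE_TIME_H = (20.0, 28.0)
OPTIMAL_TIME_H = (2.0, 10.0)


@dataclass(frozen=True)
class ProtocolSpec:
    """Declarative description of one forced-desynchrony schedule.

    Parameters
    ----------
    name : str
        Label, e.g. ``"control"`` or ``"csr"``.
    day_length : float
        Length of one FD "day" in hours (42.85 in both study protocols).
    wake_per_day : float
        Scheduled wakefulness per FD day, hours.
    sleep_opp_per_day : float
        Scheduled sleep opportunity per FD day, hours.  Must complement
        ``wake_per_day`` to ``day_length``.
    n_days : int
        Number of FD days analysed.
    vas_interval : float
        Cadence of subjective-alertness (VAS) probes during wake, hours.
    battery_interval : float
        Cadence of the test battery (ADD/DSST) during wake, hours.  The
        first battery starts ``battery_interval`` hours after scheduled wake.
    pvt_interval : float
        Cadence of the PVT, hours; aligned to the first battery.
    baseline_days : int
        Pre-FD days; they contribute no events and no sleep debt.
    """

    name: str
    day_length: float = 42.85
    wake_per_day: float = 28.57
    sleep_opp_per_day: float = 14.28
    n_days: int = 12
    vas_interval: float = 0.5
    battery_interval: float = 2.0
    pvt_interval: float = 2.0
    baseline_days: int = 0

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        for name in ("day_length", "vas_interval", "battery_interval", "pvt_interval"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if abs(self.wake_per_day + self.sleep_opp_per_day - self.day_length) > 0.01:
            raise ValueError(
                "wake_per_day + sleep_opp_per_day must equal day_length "
                f"(got {self.wake_per_day} + {self.sleep_opp_per_day} "
                f"!= {self.day_length})"
            )

    @property
    def total_hours(self) -> float:
        return self.n_days * self.day_length

    def sleep_per_24h(self) -> float:
        """Sleep opportunity rescaled to a 24-h day, hours."""
        return self.sleep_opp_per_day / self.day_length * 24.0

    def wake_interval(self, t_elapsed: float) -> tuple[float, float]:
        """Return the [wake_start, sleep_start) interval of the day containing t."""
        day = min(int(t_elapsed // self.day_length), self.n_days - 1)
        start = day * self.day_length
        return start, start + self.wake_per_day

    def is_scheduled_wake(self, t_elapsed: float) -> bool:
        """True if t falls in a scheduled wake episode (half-open)."""
        if not 0 <= t_elapsed <= self.total_hours:
            return False
        rem = t_elapsed % self.day_length
        return rem < self.wake_per_day

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ProtocolSpec":
        return cls(**json.loads(text))


#: The two study protocols. The Control FD ran 14 days but only the first 12
#: are analysed; both specs therefore carry n_days=12.
CONTROL = ProtocolSpec(
    name="control", wake_per_day=28.57, sleep_opp_per_day=14.28,
    battery_interval=2.0, pvt_interval=2.0, baseline_days=3,
)
CSR = ProtocolSpec(
    name="csr", wake_per_day=32.85, sleep_opp_per_day=10.0,
    battery_interval=2.0, pvt_interval=4.0, baseline_days=5,
)

EVENT_KINDS = ("wake_start", "sleep_start", "vas", "pvt", "add", "dsst", "melatonin")


@dataclass(frozen=True)
class ScheduleEvent:
    participant_id: str
    kind: str
    t_elapsed: float
    t_since_wake: float
    day_index: int
    week_index: int


def _week_index(t_elapsed: float, spec: ProtocolSpec) -> int:
    # one FD "week" = four 42.85-h days = 171.4 h
    return int(math.floor(t_elapsed / (4.0 * spec.day_length))) + 1


def _events_for_day(spec: ProtocolSpec, day: int, participant_id: str) -> Iterator[ScheduleEvent]:
    t0 = day * spec.day_length
    wake_end = t0 + spec.wake_per_day

    def ev(kind: str, t: float) -> ScheduleEvent:
        return ScheduleEvent(
            participant_id=participant_id,
            kind=kind,
            t_elapsed=round(t, 9),
            t_since_wake=round(t - t0, 9) if t < wake_end else float("nan"),
            day_index=day + 1,
            week_index=_week_index(t, spec),
        )

    yield ev("wake_start", t0)
    # VAS probes every vas_interval during scheduled wake
    n_vas = int(math.floor(spec.wake_per_day / spec.vas_interval - 1e-9))
    for k in range(1, n_vas + 1):
        yield ev("vas", t0 + k * spec.vas_interval)
    # test batteries start battery_interval after wake; ADD and DSST at every
    # battery, PVT aligned to the first battery at its own cadence
    t_bat = t0 + spec.battery_interval
    while t_bat < wake_end - 1e-9:
        yield ev("add", t_bat)
        yield ev("dsst", t_bat)
        t_bat += spec.battery_interval
    t_pvt = t0 + spec.battery_interval
    while t_pvt < wake_end - 1e-9:
        yield ev("pvt", t_pvt)
        t_pvt += spec.pvt_interval
    yield ScheduleEvent(
        participant_id=participant_id,
        kind="sleep_start",
        t_elapsed=round(wake_end, 9),
        t_since_wake=float("nan"),
        day_index=day + 1,
        week_index=_week_index(wake_end, spec),
    )


def build_schedule(spec: ProtocolSpec, participant_id: str = "") -> list[ScheduleEvent]:
    """Construct the full FD event sequence for one participant.

    Melatonin is sampled hourly throughout the protocol (wake and sleep);
    VAS every ``vas_interval`` during wake; ADD/DSST batteries every
    ``battery_interval`` starting ``battery_interval`` hours after waking;
    PVT every ``pvt_interval`` aligned to the first battery.  Events are
    returned sorted by time (stable on kind order within a timestamp).
    """
    events: list[ScheduleEvent] = []
    for day in range(spec.n_days):
        events.extend(_events_for_day(spec, day, participant_id))
    # hourly melatonin across the entire protocol, including scheduled sleep
    for k in range(int(math.floor(spec.total_hours)) + 1):
        t = float(k)
        rem = t % spec.day_length
        day = min(int(t // spec.day_length), spec.n_days - 1)
        events.append(
            ScheduleEvent(
                participant_id=participant_id,
                kind="melatonin",
                t_elapsed=t,
                t_since_wake=rem if rem < spec.wake_per_day else float("nan"),
                day_index=day + 1,
                week_index=_week_index(t, spec),
            )
        )
    events.sort(key=lambda e: (e.t_elapsed, EVENT_KINDS.index(e.kind)))
    return events


def schedule_frame(events: Sequence[ScheduleEvent]) -> pd.DataFrame:
    """Schedule as a DataFrame with the documented CSV columns."""
    return pd.DataFrame(
        [asdict(e) for e in events],
        columns=["participant_id", "kind", "t_elapsed", "t_since_wake",
                 "day_index", "week_index"],
    )


def sleep_debt(t_elapsed: float, spec: ProtocolSpec) -> float:
    """Cumulative lost hours of sleep at time ``t_elapsed`` into the FD protocol.

    Defined as cumulative scheduled wakefulness in [0, t] minus the
    wakefulness of a reference 16-h-wake/8-h-sleep day over the same span,
    i.e. minus ``(16/24) * t``.  Computed from scheduled sleep opportunity,
    never from realised sleep.  Piecewise linear: slope ``+1 - 16/24``
    during scheduled wake and ``-16/24`` during scheduled sleep.
    """
    t = float(t_elapsed)
    if not math.isfinite(t):
        raise ValueError("t_elapsed must be finite")
    if t < -1e-12 or t > spec.total_hours + 1e-9:
        raise ValueError(
            f"t_elapsed={t} outside protocol [0, {spec.total_hours}]"
        )
    t = min(max(t, 0.0), spec.total_hours)
    full_days = int(t // spec.day_length)
    rem = t - full_days * spec.day_length
    cum_wake = full_days * spec.wake_per_day + min(rem, spec.wake_per_day)
    return cum_wake - BASELINE_WAKE_FRACTION * t


def sleep_debt_trajectory(spec: ProtocolSpec, step: float = 0.5) -> pd.DataFrame:
    """Sleep-debt time series sampled every ``step`` hours (plus breakpoints)."""
    ts = np.arange(0.0, spec.total_hours + step / 2, step)
    breaks = []
    for day in range(spec.n_days):
        breaks.extend([day * spec.day_length, day * spec.day_length + spec.wake_per_day])
    ts = np.unique(np.concatenate([ts, np.asarray(breaks), [spec.total_hours]]))
    ts = ts[(ts >= 0) & (ts <= spec.total_hours + 1e-9)]
    return pd.DataFrame({
        "t_elapsed": ts,
        "debt": [sleep_debt(t, spec) for t in ts],
    })


def classify_phase_window(phase: float) -> str:
    """Classify a circadian phase (degrees) as adverse, optimal, or neither.

    Adverse phase is the biological night, -30 to 90 deg around the fitted
    melatonin maximum; optimal phase is 150-270 deg (biological day).
    Boundaries are closed; ``phase`` is reduced modulo 360 first.
    """
    if not math.isfinite(phase):
        raise ValueError("phase must be finite")
    p = float(phase) % 360.0
    if p >= ADVERSE_PHASE_DEG[0] or p <= ADVERSE_PHASE_DEG[1]:
        return "adverse"
    if OPTIMAL_PHASE_DEG[0] <= p <= OPTIMAL_PHASE_DEG[1]:
        return "optimal"
    return "neither"


def classify_time_window(t_since_wake: float) -> str:
    """Classify hours since scheduled wake as adverse (20-28 h), optimal (2-10 h), or neither."""
    if not math.isfinite(t_since_wake) or t_since_wake < 0:
        raise ValueError("t_since_wake must be finite and non-negative")
    t = float(t_since_wake)
    if ADVERSE_TIME_H[0] <= t <= ADVERSE_TIME_H[1]:
        return "adverse"
    if OPTIMAL_TIME_H[0] <= t <= OPTIMAL_TIME_H[1]:
        return "optimal"
    return "neither"
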
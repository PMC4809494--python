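"""Pair subjective alertness ratings with objective tests and annotate them.

Each objective test (PVT, ADD, DSST) is matched to the single VAS alertness
rating taken within 45 minutes of it, keeping the pair with the shortest
time separation; objective tests with no rating inside the window are
dropped (and counted).  A rating from one battery may serve several
objective kinds, since the battery is a single session.  Pairs are then
annotated with the explanatory variables of the performance models: C
(circadian phase at the test, degrees), T (hours since scheduled wake) and
W (sleep debt, hours), and can be binned by empirical alertness quantiles.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .phase import PhaseFit
from .protocol import ProtocolSpec, sleep_debt

__all__ = ["PAIR_WINDOW_H", "pair_tests", "annotate", "alertness_quantile_bins"]

logger = logging.getLogger(__name__)

#: maximum separation between a VAS rating and an objective test, hours (45 min)
PAIR_WINDOW_H = 0.75

OBJECTIVE_KINDS = ("pvt", "add", "dsst")

PAIR_COLUMNS = ["participant_id", "objective_kind", "t_objective", "t_vas",
                "A", "C", "T", "W", "value", "lapses"]


def _check_unique_times(df: pd.DataFrame, what: str) -> None:
    dup = df.duplicated(subset=["participant_id", "kind", "t_elapsed"])
    if dup.any():
        rows = df.loc[dup, ["participant_id", "kind", "t_elapsed"]].iloc[0]
        raise ValueError(
            f"duplicate {what} timestamp: participant "
            f"{rows['participant_id']} kind {rows['kind']} t={rows['t_elapsed']}")


def pair_tests(vas: pd.DataFrame, objective: pd.DataFrame,
               window: float = PAIR_WINDOW_H) -> pd.DataFrame:
    """Match each objective test to its nearest VAS rating within the window.

    Parameters
    ----------
    vas : DataFrame
        Columns ``participant_id, kind ("vas"), t_elapsed, value``.
    objective : DataFrame
        Columns ``participant_id, kind (pvt/add/dsst), t_elapsed, value``
        and, for PVT rows, ``lapses``.

    Returns a pairs table with ``A`` (the matched rating) filled and the
    annotation columns ``C, T, W`` as NaN until :func:`annotate` runs.
    Ties at equal separation resolve to the earlier rating.  The number of
    dropped objective tests is logged and stored in ``.attrs["n_dropped"]``.
    """
    _check_unique_times(vas, "VAS")
    _check_unique_times(objective, "objective-test")
    bad = set(objective["kind"].unique()) - set(OBJECTIVE_KINDS)
    if bad:
        raise ValueError(f"unknown objective kinds: {sorted(bad)}")

    rows = []
    n_dropped = 0
    for pid, obj_g in objective.groupby("participant_id", sort=True):
        v = vas[vas["participant_id"] == pid].sort_values("t_elapsed")
        vt = v["t_elapsed"].to_numpy(float)
        va = v["value"].to_numpy(float)
        for rec in obj_g.sort_values("t_elapsed").itertuples():
            if len(vt) == 0:
                n_dropped += 1
                continue
            dt = np.abs(vt - rec.t_elapsed)
            best = float(dt.min())
            if best > window + 1e-12:
                n_dropped += 1
                continue
            # earliest rating among ties at the minimal separation
            idx = int(np.flatnonzero(np.isclose(dt, best, rtol=0, atol=1e-12))[0])
            rows.append({
                "participant_id": pid,
                "objective_kind": rec.kind,
                "t_objective": float(rec.t_elapsed),
                "t_vas": float(vt[idx]),
                "A": float(va[idx]),
                "C": np.nan, "T": np.nan, "W": np.nan,
                "value": float(rec.value),
                "lapses": float(getattr(rec, "lapses", np.nan)),
            })
    if n_dropped:
        logger.info("pair_tests: dropped %d objective tests with no VAS "
                    "within %.0f min", n_dropped, window * 60)
    pairs = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    pairs.attrs["n_dropped"] = n_dropped
    return pairs


def annotate(pairs: pd.DataFrame, phase_fits: dict[str, PhaseFit] | PhaseFit,
             spec: ProtocolSpec) -> pd.DataFrame:
    """Fill C (phase), T (hours since wake) and W (sleep debt) per pair.

    ``phase_fits`` maps participant id to that participant's
    :class:`~fdperf.phase.PhaseFit` (or is a single fit applied to all).
    Raises if an objective test falls inside a scheduled sleep episode.
    """
    out = pairs.copy()
    C = np.empty(len(out))
    T = np.empty(len(out))
    W = np.empty(len(out))
    for i, rec in enumerate(out.itertuples()):
        t = float(rec.t_objective)
        if not spec.is_scheduled_wake(t):
            raise ValueError(
                f"objective test at t={t} falls during scheduled sleep")
        fit = (phase_fits if isinstance(phase_fits, PhaseFit)
               else phase_fits[str(rec.participant_id)])
        C[i] = fit.phase_of(t)
        wake_start, _ = spec.wake_interval(t)
        T[i] = t - wake_start
        W[i] = sleep_debt(t, spec)
    out["C"], out["T"], out["W"] = C, T, W
    return out


def alertness_quantile_bins(pairs: pd.DataFrame, n_bins: int = 10
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Assign each pair to an empirical alertness quantile bin.

    Edges are empirical quantiles (linear interpolation) of the pooled
    alertness ratings; values equal to an interior edge go to the lower
    bin.  Returns ``(bin_index array, edges array of length n_bins+1)``.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    a = pairs["A"].to_numpy(float)
    if len(a) < n_bins:
        raise ValueError(f"fewer pairs ({len(a)}) than bins ({n_bins})")
    if np.ptp(a) == 0:
        raise ValueError("all alertness values equal: degenerate quantiles")
    edges = np.quantile(a, np.linspace(0.0, 1.0, n_bins + 1))
    if len(np.unique(edges)) != len(edges):
        raise ValueError("tied quantile edges: too many identical ratings")
    inner = edges[1:-1]
    idx = np.searchsorted(inner, a, side="left")
    return idx, edges
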
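"""Alertness-bin lapse contingency analytics and the PVT mean-SD relationship.

A PVT lapse is a reaction time above 500 ms.  Binning paired test sessions
by alertness decile and cross-tabulating against lapse presence yields a
contingency table whose Pearson chi-square, bottom-vs-top-quintile relative
risk, and per-bin lapse percentages quantify how poorly self-rated
alertness screens for attentional failure.  A packaged reference table of
published counts from a two-protocol forced-desynchrony study (5026 paired
test batteries, 17 participants) ships with the module for those analytics.

Separately, log PVT session standard deviation is modelled as a cubic
polynomial in log PVT session mean; the relationship is tight enough that
the session mean alone predicts its own variability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .pairing import alertness_quantile_bins

__all__ = [
    "ContingencyTable",
    "reference_contingency_table",
    "chi_square",
    "relative_risk",
    "pct_with_lapse",
    "MeanSdFit",
    "fit_mean_sd_poly",
    "LAPSE_THRESHOLD_MS",
]

LAPSE_THRESHOLD_MS = 500.0


@dataclass(frozen=True)
class ContingencyTable:
    """Alertness-bin x lapse-presence counts with marginals and expecteds.

    ``observed[k] = (no-lapse count, >=1-lapse count)`` for alertness bin k
    (lowest alertness first).  Expected cells are recomputed from the
    marginals, ``row_total * column_total / N`` — never read back from any
    rounded source.
    """

    observed: np.ndarray
    bin_labels: tuple[str, ...] = ()
    a_ranges: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        obs = np.asarray(self.observed, dtype=float)
        if obs.ndim != 2 or obs.shape[1] != 2:
            raise ValueError("observed must be an (n_bins, 2) array")
        if np.any(obs < 0) or not np.allclose(obs, np.round(obs)):
            raise ValueError("counts must be non-negative integers")
        object.__setattr__(self, "observed", obs)
        if not self.bin_labels:
            object.__setattr__(
                self, "bin_labels",
                tuple(f"bin{k + 1}" for k in range(obs.shape[0])))

    @classmethod
    def from_pairs(cls, pairs: pd.DataFrame, n_bins: int = 10) -> "ContingencyTable":
        """Tabulate PVT paired sessions by alertness quantile bin.

        Rows with missing lapse counts are rejected; a session contributes
        to the >=1-lapse column when ``lapses >= 1``.
        """
        pvt = pairs[pairs["objective_kind"] == "pvt"] if "objective_kind" in pairs else pairs
        if pvt["lapses"].isna().any():
            raise ValueError("lapse counts missing on some PVT sessions")
        idx, edges = alertness_quantile_bins(pvt, n_bins)
        lapse = (pvt["lapses"].to_numpy(float) >= 1).astype(int)
        obs = np.zeros((n_bins, 2))
        for k in range(n_bins):
            sel = idx == k
            if not sel.any():
                raise ValueError(f"alertness bin {k} is empty")
            obs[k, 0] = np.sum(sel & (lapse == 0))
            obs[k, 1] = np.sum(sel & (lapse == 1))
        labels = tuple(f"{100 * k // n_bins}-{100 * (k + 1) // n_bins}%"
                       for k in range(n_bins))
        ranges = tuple(f"{edges[k]:.1f}-{edges[k + 1]:.1f}" for k in range(n_bins))
        return cls(obs, labels, ranges)

    # -- marginals ---------------------------------------------------------

    @property
    def row_totals(self) -> np.ndarray:
        return self.observed.sum(axis=1)

    @property
    def column_totals(self) -> np.ndarray:
        return self.observed.sum(axis=0)

    @property
    def n(self) -> float:
        return float(self.observed.sum())

    @property
    def expected(self) -> np.ndarray:
        return np.outer(self.row_totals, self.column_totals) / self.n

    def to_frame(self) -> pd.DataFrame:
        e = self.expected
        return pd.DataFrame({
            "bin": self.bin_labels,
            "a_range": self.a_ranges or [""] * len(self.bin_labels),
            "no_lapses": self.observed[:, 0].astype(int),
            "no_lapses_expected": e[:, 0],
            "one_or_more": self.observed[:, 1].astype(int),
            "one_or_more_expected": e[:, 1],
            "row_total": self.row_totals.astype(int),
        })

    # -- statistics --------------------------------------------------------

    def chi_square(self) -> tuple[float, int]:
        """Pearson chi-square sum((O - E)^2 / E) and its degrees of freedom."""
        e = self.expected
        if np.any(e <= 0):
            raise ValueError("zero expected cell: chi-square undefined")
        stat = float(np.sum((self.observed - e) ** 2 / e))
        dof = (self.observed.shape[0] - 1) * (self.observed.shape[1] - 1)
        return stat, dof

    def relative_risk(self, low_bins, high_bins, alpha: float = 0.05) -> dict:
        """Risk of >=1 lapse in ``low_bins`` relative to ``high_bins``.

        Bins index rows (0 = lowest alertness).  The confidence interval is
        the Katz log-normal interval on the log risk ratio.
        """
        low = sorted(set(low_bins))
        high = sorted(set(high_bins))
        if not low or not high or set(low) & set(high):
            raise ValueError("bin index sets must be disjoint and non-empty")
        o = self.observed
        x1, n1 = o[low, 1].sum(), o[low].sum()
        x2, n2 = o[high, 1].sum(), o[high].sum()
        if x2 == 0:
            raise ValueError("zero lapse proportion in the reference bins")
        rr = (x1 / n1) / (x2 / n2)
        if x1 == 0:
            return {"rr": float(rr), "ci_low": 0.0, "ci_high": float("nan")}
        se = np.sqrt(1 / x1 - 1 / n1 + 1 / x2 - 1 / n2)
        z = stats.norm.ppf(1 - alpha / 2)
        return {
            "rr": float(rr),
            "ci_low": float(rr * np.exp(-z * se)),
            "ci_high": float(rr * np.exp(z * se)),
        }

    def pct_with_lapse(self, bins) -> float:
        """Percentage of sessions in the given bins with at least one lapse."""
        bins = sorted(set(bins))
        if not bins:
            raise ValueError("bins must be non-empty")
        o = self.observed[bins]
        total = o.sum()
        if total == 0:
            raise ValueError("zero row total in selected bins")
        return 100.0 * o[:, 1].sum() / total


def reference_contingency_table() -> ContingencyTable:
    """Packaged published counts: alertness decile x lapse presence, N=5026."""
    with resources.files("fdperf.data").joinpath(
            "fd_alertness_lapse_counts.csv").open() as fh:
        df = pd.read_csv(fh)
    return ContingencyTable(
        df[["no_lapses", "one_or_more"]].to_numpy(float),
        tuple(df["percentile_label"]),
        tuple(df["a_range"]),
    )


def chi_square(table: ContingencyTable) -> tuple[float, int]:
    return table.chi_square()


def relative_risk(table: ContingencyTable, low_bins, high_bins, **kw) -> dict:
    return table.relative_risk(low_bins, high_bins, **kw)


def pct_with_lapse(table: ContingencyTable, bins) -> float:
    return table.pct_with_lapse(bins)


@dataclass(frozen=True)
class MeanSdFit:
    """Cubic fit of log session SD on log session mean.

    ``coefficients`` are ascending powers (c0 + c1 x + c2 x^2 + c3 x^3 on
    x = log mean).  ``per_subject`` holds optional subject intercept
    offsets from the mixed variant.
    """

    coefficients: tuple[float, float, float, float]
    adj_r2: float
    n_obs: int
    per_subject: dict | None = None

    def predict(self, log_mean) -> np.ndarray:
        x = np.asarray(log_mean, dtype=float)
        c = self.coefficients
        return c[0] + c[1] * x + c[2] * x ** 2 + c[3] * x ** 3


def fit_mean_sd_poly(sessions: pd.DataFrame, degree: int = 3,
                     mixed: bool = False) -> MeanSdFit:
    """Least-squares cubic of log(PVT SD) on log(PVT mean).

    ``sessions`` needs columns ``value`` (session mean, ms) and ``sd_ms``
    (and ``participant_id`` for the mixed variant, which adds per-subject
    random intercepts).  The polynomial is linear in its coefficients, so
    ordinary least squares attains the same minimum as any iterative
    least-squares routine.
    """
    if degree != 3:
        raise ValueError("the mean-SD relationship is modelled as a cubic")
    sub = sessions.dropna(subset=["value", "sd_ms"])
    if len(sub) < 5:
        raise ValueError("need at least 5 sessions")
    m = sub["value"].to_numpy(float)
    s = sub["sd_ms"].to_numpy(float)
    if np.any(m <= 0) or np.any(s <= 0):
        raise ValueError("session means and SDs must be positive")
    x = np.log(m)
    y = np.log(s)
    D = np.vander(x, degree + 1, increasing=True)
    n = len(y)

    if not mixed:
        coef, *_ = np.linalg.lstsq(D, y, rcond=None)
        resid = y - D @ coef
        from .model import adjusted_r2_from_resid
        adj = adjusted_r2_from_resid(y, resid, degree + 1)
        return MeanSdFit(tuple(coef.tolist()), adj, n)

    import statsmodels.api as sm
    groups = sub["participant_id"].astype(str).to_numpy()
    md = sm.regression.mixed_linear_model.MixedLM(y, D, groups=groups)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = md.fit(reml=False)
    coef = np.asarray(res.fe_params)
    offsets = {str(g): float(np.asarray(u)[0])
               for g, u in res.random_effects.items()}
    fitted = D @ coef + np.array([offsets[g] for g in groups])
    resid = y - fitted
    from .model import adjusted_r2_from_resid
    adj = adjusted_r2_from_resid(y, resid, degree + 1)
    return MeanSdFit(tuple(coef.tolist()), adj, n, per_subject=offsets)
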
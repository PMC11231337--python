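"""Kaplan-Meier estimation and two-group log-rank testing.

The product-limit estimator uses the events-before-censoring convention at
tied times: subjects censored at time t are still at risk for an event at t.
The log-rank test is the Mantel-Haenszel form: over pooled event times,
U = sum(O_A - E_A) with hypergeometric variance V per time; the statistic
U^2 / V is referred to a chi-square with 1 df.  Both routines are implemented
directly so the observed/expected event tables are available to reports; the
test suite cross-checks them against lifelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .io import ValidationError

__all__ = ["SurvivalCurve", "LogRankResult", "km_estimate", "logrank_test", "km_by_strata"]


@dataclass(frozen=True)
class SurvivalCurve:
    """Right-continuous Kaplan-Meier step function over the distinct event times."""

    event_times: np.ndarray   # distinct times with >= 1 event, ascending
    survival: np.ndarray      # S(t) just after each event time
    at_risk: np.ndarray       # n_i at each event time
    events: np.ndarray        # d_i at each event time
    n: int                    # cohort size

    def survival_at(self, t: float) -> float:
        """S(t); 1.0 before the first event time."""
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])


@dataclass(frozen=True)
class LogRankResult:
    """Two-group Mantel-Haenszel log-rank test."""

    chi_square: float
    df: int
    p_value: float
    observed: dict[str, float]
    expected: dict[str, float]
    n: dict[str, int]


def _check_surv(times, events) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.size == 0:
        raise ValidationError("empty survival input")
    if times.size != events.size:
        raise ValidationError("times and events must have equal length")
    if not np.all(np.isfinite(times)) or (times < 0).any():
        raise ValidationError("times must be finite and non-negative")
    if not set(np.unique(events).tolist()) <= {0, 1}:
        raise ValidationError("event flags must be 0/1")
    return times, events.astype(int)


def km_estimate(times, events) -> SurvivalCurve:
    """Product-limit survival estimate S(t) = prod_{t_i <= t} (1 - d_i / n_i)."""
    times, events = _check_surv(times, events)
    event_times = np.unique(times[events == 1])
    at_risk = np.array([(times >= t).sum() for t in event_times], dtype=int)
    d = np.array([((times == t) & (events == 1)).sum() for t in event_times], dtype=int)
    with np.errstate(invalid="ignore"):
        surv = np.cumprod(1.0 - d / at_risk) if event_times.size else np.array([])
    return SurvivalCurve(event_times=event_times, survival=surv,
                         at_risk=at_risk, events=d, n=int(times.size))


def logrank_test(times, events, group) -> LogRankResult:
    """Two-group log-rank (Mantel-Haenszel) test; p from chi-square, 1 df."""
    times, events = _check_surv(times, events)
    group = np.asarray(group)
    if group.size != times.size:
        raise ValidationError("group labels must align with times")
    levels = sorted(pd.unique(group).tolist())
    if len(levels) != 2:
        raise ValidationError(f"exactly 2 group levels required, got {levels[:5]}")
    if events.sum() == 0:
        raise ValidationError("log-rank statistic undefined with no events")
    a = group == levels[0]
    event_times = np.unique(times[events == 1])
    u = 0.0
    v = 0.0
    o_a = 0.0
    e_a = 0.0
    for t in event_times:
        at_risk = times >= t
        n_t = int(at_risk.sum())
        n_a = int((at_risk & a).sum())
        d_t = int(((times == t) & (events == 1)).sum())
        d_a = int(((times == t) & (events == 1) & a).sum())
        e_t = d_t * n_a / n_t
        o_a += d_a
        e_a += e_t
        u += d_a - e_t
        if n_t > 1:
            v += d_t * (n_t - d_t) * n_a * (n_t - n_a) / (n_t**2 * (n_t - 1))
    if v == 0.0:
        warnings.warn("log-rank variance is zero; reporting chi-square 0")
        chi_sq = 0.0
    else:
        chi_sq = u * u / v
    total_events = float(events.sum())
    return LogRankResult(
        chi_square=float(chi_sq),
        df=1,
        p_value=float(chi2.sf(chi_sq, df=1)),
        observed={str(levels[0]): float(o_a), str(levels[1]): total_events - o_a},
        expected={str(levels[0]): float(e_a), str(levels[1]): total_events - e_a},
        n={str(levels[0]): int(a.sum()), str(levels[1]): int((~a).sum())},
    )


def km_by_strata(cohort: pd.DataFrame, strata: pd.DataFrame, endpoint: str = "pfs") -> dict:
    """KM curve per combined PD-L1 x EMT stratum, with the headline log-rank contrasts.

    The contrasts are EMT-high vs EMT-low within PD-L1-high and, separately,
    within PD-L1-low.  An empty or event-free contrast is skipped with a
    warning and reported as None.
    """
    if endpoint not in ("pfs", "os"):
        raise ValueError("endpoint must be 'pfs' or 'os'")
    tcol, ecol = f"{endpoint}_time", f"{endpoint}_event"
    df = cohort.merge(strata, on="sample_id", how="inner")
    for col in (tcol, ecol):
        if col not in df.columns:
            raise ValidationError(f"cohort table lacks column {col!r}")
    df = df[df[tcol].notna() & df[ecol].notna()]
    curves: dict[str, SurvivalCurve] = {}
    for label, sub in df.groupby("combined", dropna=True):
        curves[str(label)] = km_estimate(sub[tcol], sub[ecol])
    contrasts: dict[str, LogRankResult | None] = {}
    for pdl1 in ("high", "low"):
        key = f"pdl1_{pdl1}_emt_high_vs_low"
        sub = df[df["pdl1_group"] == pdl1]
        sub = sub[sub["emt_group"].notna()]
        try:
            contrasts[key] = logrank_test(sub[tcol], sub[ecol], sub["emt_group"])
        except ValidationError as exc:
            warnings.warn(f"contrast {key} skipped: {exc}")
            contrasts[key] = None
    return {"curves": curves, "contrasts": contrasts}
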
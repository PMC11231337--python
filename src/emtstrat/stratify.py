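"""Cohort stratification, group comparisons, correlations and ROC cutpoints.

Median splits follow the convention value > median -> "high" (ties at the
median go low).  The PD-L1 tumor proportion score (TPS) split is inclusive:
TPS >= cutoff (default 1) is PD-L1-high.  ROC cutpoints minimize the Euclidean
distance to the perfect classifier, sqrt((1-sens)^2 + (1-spec)^2), over
candidate thresholds placed at midpoints between consecutive observed marker
values (plus sentinels outside the observed range); the positive call is
marker >= threshold, and markers whose low values predict the event are
negated first so one convention serves all.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ValidationError

__all__ = [
    "GroupComparison",
    "ROCCutpoint",
    "median_split",
    "tps_split",
    "assign_strata",
    "spearman",
    "compare_groups",
    "roc_points",
    "euclidean_cutpoint",
    "tumor_volume",
]


@dataclass(frozen=True)
class GroupComparison:
    """Two-group test result (Welch t or Mann-Whitney), two-sided."""

    labels: tuple[str, str]
    statistic: float
    p_value: float
    method: str
    n: tuple[int, int]


@dataclass(frozen=True)
class ROCCutpoint:
    """Threshold minimizing Euclidean distance to (sens, spec) = (1, 1)."""

    marker: str
    threshold: float
    sensitivity: float
    specificity: float
    distance: float
    direction: str  # ">=" : high marker calls the event; "<=" : low marker does


def median_split(values) -> pd.Series:
    """Label each value "high" (> median) or "low" (<= median); missing -> <NA>."""
    s = pd.Series(values, dtype=float)
    obs = s.dropna()
    if obs.size < 2:
        raise ValidationError("median split needs >= 2 non-missing values")
    med = obs.median()
    out = pd.Series(pd.NA, index=s.index, dtype="object")
    out[s.notna()] = np.where(s.dropna() > med, "high", "low")
    return out


def tps_split(tps, cutoff: float = 1.0) -> pd.Series:
    """PD-L1 TPS split: high iff TPS >= cutoff (inclusive); missing -> <NA>."""
    s = pd.Series(tps, dtype=float)
    obs = s.dropna()
    if ((obs < 0) | (obs > 100)).any():
        raise ValidationError("TPS values must lie in [0, 100]")
    out = pd.Series(pd.NA, index=s.index, dtype="object")
    out[s.notna()] = np.where(obs >= cutoff, "high", "low")
    return out


def assign_strata(pdl1_group: pd.Series, emt_group: pd.Series) -> pd.DataFrame:
    """Combine PD-L1 and EMT group labels into the four-way stratum table."""
    df = pd.DataFrame({"pdl1_group": pdl1_group, "emt_group": emt_group})
    both = df["pdl1_group"].notna() & df["emt_group"].notna()
    df["combined"] = pd.Series(pd.NA, index=df.index, dtype="object")
    df.loc[both, "combined"] = (
        "PD-L1-" + df.loc[both, "pdl1_group"].astype(str)
        + "/EMT-" + df.loc[both, "emt_group"].astype(str)
    )
    return df


def spearman(x, y) -> tuple[float, float]:
    """Tie-corrected Spearman rho with two-sided p (t approximation, n-2 df).

    Pairs with a missing value in either variable are dropped.  Constant input
    leaves rho undefined: returns (nan, nan) with a warning.
    """
    x = pd.Series(x, dtype=float)
    y = pd.Series(y, dtype=float).set_axis(x.index)
    keep = x.notna() & y.notna()
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValidationError("Spearman correlation needs >= 3 complete pairs")
    if x.nunique() < 2 or y.nunique() < 2:
        warnings.warn("constant input: Spearman rho undefined")
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def compare_groups(a, b, method: str = "t_test",
                   labels: tuple[str, str] = ("a", "b")) -> GroupComparison:
    """Two-sided comparison of two value lists (Welch t-test or Mann-Whitney U)."""
    a = np.asarray(pd.Series(a, dtype=float).dropna())
    b = np.asarray(pd.Series(b, dtype=float).dropna())
    if method == "t_test":
        if a.size < 2 or b.size < 2:
            raise ValidationError("t-test needs >= 2 values per group")
        stat, p = stats.ttest_ind(a, b, equal_var=False)
    elif method == "mann_whitney":
        if a.size < 1 or b.size < 1:
            raise ValidationError("Mann-Whitney needs >= 1 value per group")
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown method {method!r}")
    return GroupComparison(labels=labels, statistic=float(stat),
                           p_value=min(float(p), 1.0), method=method,
                           n=(int(a.size), int(b.size)))


def _check_binary_outcome(marker: np.ndarray, outcome: np.ndarray) -> None:
    if marker.size != outcome.size:
        raise ValidationError("marker and outcome must have equal length")
    levels = set(np.unique(outcome).tolist())
    if not levels <= {0, 1}:
        raise ValidationError(f"outcome must be 0/1, got {sorted(levels)[:5]}")
    if levels != {0, 1}:
        raise ValidationError("both outcome classes must be present")


def roc_points(marker, outcome) -> pd.DataFrame:
    """(threshold, sensitivity, specificity) over all candidate thresholds.

    Candidates are midpoints of consecutive sorted unique marker values plus
    one sentinel below the minimum and one above the maximum; a sample is
    called positive iff marker >= threshold.
    """
    marker = np.asarray(marker, dtype=float)
    outcome = np.asarray(outcome)
    _check_binary_outcome(marker, outcome)
    if not np.all(np.isfinite(marker)):
        raise ValidationError("marker values must be finite")
    u = np.unique(marker)
    thresholds = np.concatenate([[u[0] - 1.0], (u[:-1] + u[1:]) / 2.0, [u[-1] + 1.0]])
    pos = outcome == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    called = marker[None, :] >= thresholds[:, None]
    tp = (called & pos[None, :]).sum(axis=1)
    tn = (~called & ~pos[None, :]).sum(axis=1)
    return pd.DataFrame({
        "threshold": thresholds,
        "sensitivity": tp / n_pos,
        "specificity": tn / n_neg,
    })


def euclidean_cutpoint(marker, outcome, marker_name: str = "marker",
                       higher_predicts_event: bool = True) -> ROCCutpoint:
    """Pick the ROC threshold closest (Euclidean) to perfect classification.

    Ties on distance are broken by larger Youden index (sens + spec - 1),
    then by smaller threshold.  With ``higher_predicts_event=False`` the
    marker is negated before the search and the returned threshold is mapped
    back, with direction "<=".
    """
    marker = np.asarray(marker, dtype=float)
    work = marker if higher_predicts_event else -marker
    pts = roc_points(work, outcome)
    dist = np.hypot(1.0 - pts["sensitivity"], 1.0 - pts["specificity"])
    youden = pts["sensitivity"] + pts["specificity"] - 1.0
    # lexicographic: min distance, then max Youden, then min threshold
    order = np.lexsort((pts["threshold"], -youden, dist))
    best = pts.iloc[order[0]]
    threshold = float(best["threshold"])
    direction = ">="
    if not higher_predicts_event:
        threshold = -threshold
        direction = "<="
    return ROCCutpoint(marker=marker_name, threshold=threshold,
                       sensitivity=float(best["sensitivity"]),
                       specificity=float(best["specificity"]),
                       distance=float(math.hypot(1 - best["sensitivity"], 1 - best["specificity"])),
                       direction=direction)


def tumor_volume(longest_mm: float, shortest_mm: float) -> float:
    """Caliper tumor volume in mm^3: (longest diameter x shortest diameter^2) / 2."""
    if longest_mm < 0 or shortest_mm < 0:
        raise ValidationError("diameters must be non-negative")
    if shortest_mm > longest_mm:
        warnings.warn("shortest diameter exceeds longest; arguments may be swapped")
    return longest_mm * shortest_mm**2 / 2.0
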
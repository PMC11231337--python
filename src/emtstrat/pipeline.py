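"""End-to-end cohort analyses: score, stratify, compare, correlate, survive.

Two entry points mirror the two cohort designs.  ``run_rnaseq_cohort`` takes
an expression matrix plus clinical metadata, computes per-sample EMT and
immune signature scores, median-splits PD-L1 expression and EMT score,
compares PR vs PD within each PD-L1 stratum, correlates scores, and runs
Kaplan-Meier / log-rank analyses for the single and combined splits.
``run_ihc_cohort`` takes an H-score table, splits on PD-L1 TPS >= 1, selects
per-marker ROC-Euclidean cutpoints against progression, correlates PD-L1 and
EMT-marker H-scores by response group, and runs survival by combined strata.

Reports are plain nested dicts (JSON-serializable via :func:`report_to_json`),
deterministic for fixed inputs, and independent of input row order (samples
are sorted by identifier on ingest).  Non-fatal issues are accumulated in the
report's ``warnings`` list.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from importlib.metadata import PackageNotFoundError, version as _pkg_version

import numpy as np
import pandas as pd

from .emt import emt_score_cohort
from .io import EMTSignature, ExpressionMatrix, ValidationError, validate_cohort
from .sigscore import score_signatures
from .stratify import (
    assign_strata,
    compare_groups,
    euclidean_cutpoint,
    median_split,
    spearman,
    tps_split,
)
from .survival import km_by_strata, logrank_test

__all__ = ["run_rnaseq_cohort", "run_ihc_cohort", "report_to_json"]


def _version() -> str:
    try:
        return _pkg_version("emtstrat")
    except PackageNotFoundError:
        return "unknown"


def _hash_frame(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()[:16]


def _jsonable(obj):
    """Recursively convert report values to JSON-safe plain Python types."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if not np.isfinite(f) else f
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if obj is None or isinstance(obj, str):
        return obj
    if obj is pd.NA or (isinstance(obj, float) and np.isnan(obj)):
        return None
    return str(obj)


def report_to_json(report: dict, indent: int = 2) -> str:
    return json.dumps(_jsonable(report), indent=indent, sort_keys=True)


def _comparison_record(a, b, labels, method="t_test", min_n=2):
    if len(a) < min_n or len(b) < min_n:
        return None
    cmp = compare_groups(a, b, method=method, labels=labels)
    return {
        "labels": list(cmp.labels),
        "statistic": cmp.statistic,
        "p_value": cmp.p_value,
        "method": cmp.method,
        "n": list(cmp.n),
        "mean": [float(np.mean(a)), float(np.mean(b))],
    }


def _correlation_record(x, y):
    try:
        rho, p = spearman(x, y)
    except ValidationError:
        return None
    return {"rho": rho, "p_value": p, "n": int(pd.Series(x).notna().mul(pd.Series(y).notna().to_numpy()).sum())}


def _curve_record(curve):
    return {
        "event_times": curve.event_times,
        "survival": curve.survival,
        "at_risk": curve.at_risk,
        "events": curve.events,
        "n": curve.n,
    }


def _logrank_record(res):
    if res is None:
        return None
    return {
        "chi_square": res.chi_square,
        "df": res.df,
        "p_value": res.p_value,
        "observed": res.observed,
        "expected": res.expected,
        "n": res.n,
    }


def _survival_section(df: pd.DataFrame, strata: pd.DataFrame, endpoint: str,
                      report_warnings: list[str]) -> dict | None:
    tcol, ecol = f"{endpoint}_time", f"{endpoint}_event"
    if tcol not in df.columns or ecol not in df.columns:
        return None
    section: dict = {}
    surv_df = df[df[tcol].notna() & df[ecol].notna()]
    for split_col, key in (("pdl1_group", "pdl1_split"), ("emt_group", "emt_split")):
        if split_col not in surv_df.columns:
            continue
        sub = surv_df[surv_df[split_col].notna()]
        try:
            section[key] = _logrank_record(logrank_test(sub[tcol], sub[ecol], sub[split_col]))
        except ValidationError as exc:
            report_warnings.append(f"{endpoint} {key} skipped: {exc}")
            section[key] = None
    combined = km_by_strata(df[["sample_id", tcol, ecol]], strata, endpoint=endpoint)
    section["combined"] = {
        "curves": {k: _curve_record(c) for k, c in sorted(combined["curves"].items())},
        "contrasts": {k: _logrank_record(v) for k, v in combined["contrasts"].items()},
    }
    return section


def run_rnaseq_cohort(
    expr: ExpressionMatrix,
    meta: pd.DataFrame,
    emt_signature: EMTSignature,
    immune_signatures=None,
    min_genes_emt: int = 10,
    min_genes_immune: int = 3,
    pdl1_col: str = "pdl1_expr",
) -> dict:
    """Full RNA-seq-cohort analysis; returns a deterministic nested-dict report."""
    meta = validate_cohort(meta)
    if pdl1_col not in meta.columns:
        raise ValidationError(f"metadata lacks PD-L1 column {pdl1_col!r}")
    report_warnings: list[str] = []

    # deterministic sample order
    order = sorted(s for s in expr.sample_ids if s in set(meta["sample_id"]))
    if not order:
        raise ValidationError("no overlap between expression samples and metadata")
    expr = ExpressionMatrix(expr.data[order])
    meta = meta.set_index("sample_id").loc[order]

    scores = emt_score_cohort(expr, emt_signature, min_genes=min_genes_emt).set_index("sample_id")
    df = meta.join(scores["score"].rename("emt_score"))

    imm_table = None
    if immune_signatures:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            imm_table = score_signatures(expr, immune_signatures, min_genes=min_genes_immune)
            report_warnings.extend(str(w.message) for w in caught)
        df = df.join(imm_table.scores)

    strata = assign_strata(median_split(df[pdl1_col]), median_split(df["emt_score"]))
    strata.insert(0, "sample_id", df.index)
    strata = strata.reset_index(drop=True)
    df = df.join(strata.set_index("sample_id")[["pdl1_group", "emt_group", "combined"]])

    # PR vs PD comparisons of EMT and immune scores within each PD-L1 stratum
    score_cols = ["emt_score"] + (list(imm_table.scores.columns) if imm_table is not None else [])
    comparisons: dict = {}
    has_response = "response" in df.columns and df["response"].isin(["PR", "PD"]).any()
    if has_response:
        for stratum in ("high", "low"):
            block: dict = {}
            sub = df[df["pdl1_group"] == stratum]
            pr = sub[sub["response"] == "PR"]
            pd_ = sub[sub["response"] == "PD"]
            for col in score_cols:
                rec = _comparison_record(pr[col].dropna(), pd_[col].dropna(), ("PR", "PD"))
                if rec is None:
                    report_warnings.append(
                        f"comparison {col} in PD-L1-{stratum} skipped: group too small")
                block[col] = rec
            comparisons[f"pdl1_{stratum}"] = block
    else:
        report_warnings.append("response labels missing or degenerate; comparisons skipped")

    # correlations
    correlations: dict = {"pdl1_vs_emt_by_response": {}, "immune_vs_emt": {}}
    if has_response:
        for resp in ("PR", "PD"):
            sub = df[df["response"] == resp]
            correlations["pdl1_vs_emt_by_response"][resp] = (
                _correlation_record(sub[pdl1_col], sub["emt_score"]) if len(sub) >= 3 else None
            )
    if imm_table is not None:
        for stratum in ("high", "low"):
            for resp in ("PR", "PD") if has_response else ("all",):
                sub = df[df["pdl1_group"] == stratum]
                if resp != "all":
                    sub = sub[sub["response"] == resp]
                key = f"pdl1_{stratum}_{resp}"
                correlations["immune_vs_emt"][key] = {
                    sig: (_correlation_record(sub[sig], sub["emt_score"]) if len(sub) >= 3 else None)
                    for sig in imm_table.scores.columns
                }

    survival = {}
    for endpoint in ("pfs", "os"):
        section = _survival_section(df.reset_index(), strata, endpoint, report_warnings)
        if section is not None:
            survival[endpoint] = section

    report = {
        "provenance": {
            "package_version": _version(),
            "n_samples": int(len(df)),
            "n_genes": int(expr.n_genes),
            "emt_signature": emt_signature.name,
            "expression_hash": hashlib.sha256(expr.values.tobytes()).hexdigest()[:16],
            "metadata_hash": _hash_frame(meta.reset_index()),
        },
        "samples": df.reset_index()[
            ["sample_id", "emt_score", "pdl1_group", "emt_group", "combined"]
            + ([c for c in score_cols if c != "emt_score"])
        ].to_dict(orient="records"),
        "comparisons": comparisons,
        "correlations": correlations,
        "survival": survival,
        "warnings": report_warnings,
    }
    return _jsonable(report)


def run_ihc_cohort(
    meta: pd.DataFrame,
    markers: tuple[str, ...] = ("slug", "twist1", "vimentin", "ecadherin"),
    tps_cutoff: float = 1.0,
    outcome_response: str = "PD",
) -> dict:
    """Full IHC-cohort analysis; H-score cutpoints, correlations, survival."""
    meta = validate_cohort(meta)
    if "pdl1_tps" not in meta.columns:
        raise ValidationError("IHC metadata lacks 'pdl1_tps' column")
    report_warnings: list[str] = []
    df = meta.sort_values("sample_id").set_index("sample_id")
    df["pdl1_group"] = tps_split(df["pdl1_tps"], cutoff=tps_cutoff)

    outcome = (df["response"] == outcome_response).astype(int) if "response" in df.columns else None
    cutpoints: dict = {}
    marker_groups: dict[str, pd.Series] = {}
    for marker in markers:
        col = f"hscore_{marker}"
        if col not in df.columns:
            report_warnings.append(f"marker {marker} skipped: column {col!r} absent")
            cutpoints[marker] = None
            continue
        if outcome is None or outcome.nunique() < 2:
            report_warnings.append(f"marker {marker} skipped: outcome degenerate")
            cutpoints[marker] = None
            continue
        higher = marker != "ecadherin"   # low E-cadherin marks the mesenchymal phenotype
        try:
            cp = euclidean_cutpoint(df[col], outcome, marker_name=marker,
                                    higher_predicts_event=higher)
        except ValidationError as exc:
            report_warnings.append(f"marker {marker} skipped: {exc}")
            cutpoints[marker] = None
            continue
        cutpoints[marker] = {
            "threshold": cp.threshold,
            "sensitivity": cp.sensitivity,
            "specificity": cp.specificity,
            "distance": cp.distance,
            "direction": cp.direction,
        }
        called = df[col] >= cp.threshold if cp.direction == ">=" else df[col] <= cp.threshold
        marker_groups[marker] = pd.Series(np.where(called, "high", "low"), index=df.index)

    correlations: dict = {}
    if "hscore_pdl1" in df.columns:
        groups = {"all": df}
        if "response" in df.columns:
            groups["CR_PR"] = df[df["response"].isin(["CR", "PR"])]
            groups["SD"] = df[df["response"] == "SD"]
            groups["PD"] = df[df["response"] == "PD"]
        for gname, sub in groups.items():
            correlations[gname] = {}
            for marker in markers:
                col = f"hscore_{marker}"
                if col not in sub.columns or len(sub) < 3:
                    correlations[gname][marker] = None
                    continue
                correlations[gname][marker] = _correlation_record(sub["hscore_pdl1"], sub[col])
    else:
        report_warnings.append("hscore_pdl1 absent; correlation section skipped")

    survival: dict = {}
    for marker, groups in marker_groups.items():
        strata = assign_strata(df["pdl1_group"], groups)
        strata.insert(0, "sample_id", df.index)
        strata = strata.reset_index(drop=True)
        marker_surv = {}
        for endpoint in ("os", "pfs"):
            section = _survival_section(df.reset_index(), strata, endpoint, report_warnings)
            if section is not None:
                marker_surv[endpoint] = {
                    "marker_split_within_pdl1_high": section["combined"]["contrasts"][
                        "pdl1_high_emt_high_vs_low"],
                    "marker_split_within_pdl1_low": section["combined"]["contrasts"][
                        "pdl1_low_emt_high_vs_low"],
                    "curves": section["combined"]["curves"],
                }
        survival[marker] = marker_surv

    report = {
        "provenance": {
            "package_version": _version(),
            "n_samples": int(len(df)),
            "tps_cutoff": float(tps_cutoff),
            "metadata_hash": _hash_frame(meta.sort_values("sample_id")),
        },
        "strata": df.reset_index()[["sample_id", "pdl1_group"]].to_dict(orient="records"),
        "cutpoints": cutpoints,
        "correlations": correlations,
        "survival": survival,
        "warnings": report_warnings,
    }
    return _jsonable(report)
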
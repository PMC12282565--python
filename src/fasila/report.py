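"""Cohort scoring and the full evaluation report.

Glue between the scoring formulas and the diagnostics operations: append
score columns to a cohort table, then assemble the evaluation report (group
comparison, correlations vs the score, per-threshold diagnostic panels,
AUROC comparisons and the transfusion logistic model), both as a plain dict
for JSON and as formatted text tables.  No statistic is computed here that
is not a direct call into :mod:`fasila.diagnostics`.
"""
from __future__ import annotations

import math
import warnings
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Mapping, Optional

import numpy as np
import pandas as pd

from . import __version__
from .diagnostics import (
    CIMethod,
    DegenerateDataError,
    GroupTest,
    auroc_bootstrap_compare,
    auroc_mann_whitney,
    confusion_from_threshold,
    diagnostic_metrics,
    group_comparison,
    logistic_irls,
    odds_ratio,
    pearson_correlation,
    two_proportion_power,
)
from .scores import (
    DEFAULT_CUTOFF,
    IndeterminatePolicy,
    Management,
    UnscorableError,
    abc_score,
    fasila_risk_class,
    fasila_score,
)

__all__ = [
    "SCORE_COLUMNS",
    "OUTCOME_PRESETS",
    "REPORT_SCHEMA_VERSION",
    "score_dataframe",
    "outcome_vector",
    "evaluate_cohort",
    "render_text_report",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (presentation convention for reported
    percentages, e.g. 3.25 -> 3.3), unlike banker's rounding."""
    q = Decimal("1").scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))

REPORT_SCHEMA_VERSION = "1"

SCORE_COLUMNS = (
    "fast_points",
    "si_points",
    "lactate_points",
    "fasila_total",
    "fasila_class",
    "abc_total",
    "abc_mtp_predicted",
    "systolic_si",
    "diastolic_si",
)

_SURGICAL = {Management.SURGICAL.value, Management.SURGICAL_PLUS_IR.value}

#: named outcome definitions used across tables and figures
OUTCOME_PRESETS: Mapping[str, Callable[[pd.DataFrame], pd.Series]] = {
    "surgery": lambda df: df["management"].isin(_SURGICAL),
    "laparotomy": lambda df: df["laparotomy"].astype(bool),
    "transfusion": lambda df: df["transfused"].astype(bool),
    "mtp": lambda df: df["mtp"].astype(bool),
    "mortality": lambda df: df["mortality"].astype(bool),
}


def _as_bool(series: pd.Series) -> pd.Series:
    if series.dtype == object:
        return series.astype(str).str.strip().str.lower().isin(("true", "1"))
    return series.astype(bool)


def outcome_vector(df: pd.DataFrame, outcome: str) -> np.ndarray:
    """Boolean vector for a named outcome preset."""
    if outcome not in OUTCOME_PRESETS:
        raise KeyError(
            f"unknown outcome {outcome!r}; choose from {sorted(OUTCOME_PRESETS)}"
        )
    frame = df.copy()
    for col in ("laparotomy", "transfused", "mtp", "mortality"):
        if col in frame:
            frame[col] = _as_bool(frame[col])
    return OUTCOME_PRESETS[outcome](frame).to_numpy()


def score_dataframe(
    df: pd.DataFrame,
    cutoff: int = DEFAULT_CUTOFF,
    indeterminate_policy: IndeterminatePolicy = IndeterminatePolicy.STRICT,
) -> tuple[pd.DataFrame, int]:
    """Append score columns to a cohort table.

    Unscorable rows (e.g. indeterminate FAST under the strict policy) are
    flagged in a ``score_flag`` column and keep empty score cells; they are
    never dropped.  Returns the scored frame and the number of flagged rows.
    """
    out = df.copy()
    values: dict[str, list] = {c: [] for c in SCORE_COLUMNS}
    flags: list[str] = []
    n_flagged = 0
    for _, row in df.iterrows():
        try:
            bd = fasila_score(
                str(row["fast"]).strip().lower(),
                float(row["hr"]),
                float(row["sbp"]),
                float(row["lactate"]),
                indeterminate_policy=indeterminate_policy,
            )
            abc = abc_score(
                str(row["mechanism"]).strip().lower(),
                str(row["fast"]).strip().lower(),
                float(row["sbp"]),
                float(row["hr"]),
                indeterminate_policy=indeterminate_policy,
            )
        except UnscorableError as exc:
            n_flagged += 1
            flags.append(str(exc))
            for c in SCORE_COLUMNS:
                values[c].append(np.nan)
            continue
        flags.append("")
        values["fast_points"].append(bd.fast_points)
        values["si_points"].append(bd.si_points)
        values["lactate_points"].append(bd.lactate_points)
        values["fasila_total"].append(bd.total)
        values["fasila_class"].append(fasila_risk_class(bd.total, cutoff).value)
        values["abc_total"].append(abc.total)
        values["abc_mtp_predicted"].append(abc.mtp_predicted)
        values["systolic_si"].append(float(row["hr"]) / float(row["sbp"]))
        values["diastolic_si"].append(float(row["hr"]) / float(row["dbp"]))
    for c in SCORE_COLUMNS:
        out[c] = values[c]
    out["score_flag"] = flags
    return out, n_flagged


# ---------------------------------------------------------------------------
# report assembly helpers


def _panel_dict(panel) -> dict:
    def _ci(p) -> Optional[dict]:
        if p is None:
            return None
        return {
            "estimate": p.estimate,
            "lo": p.lo,
            "hi": p.hi,
            "method": p.method.value,
        }

    return {
        "sensitivity": _ci(panel.sensitivity),
        "specificity": _ci(panel.specificity),
        "ppv": _ci(panel.ppv),
        "npv": _ci(panel.npv),
        "auc_binary": panel.auc_binary,
    }


def _binary_group_entry(
    low: np.ndarray, high: np.ndarray
) -> dict:
    table = np.array(
        [
            [int(high.sum()), int(low.sum())],
            [int((~high).sum()), int((~low).sum())],
        ]
    )
    res = group_comparison(table, GroupTest.CHI_SQUARE)
    return {
        "low_count": int(low.sum()),
        "low_pct": 100.0 * low.mean() if low.size else math.nan,
        "high_count": int(high.sum()),
        "high_pct": 100.0 * high.mean() if high.size else math.nan,
        "test": res.test_used.value,
        "statistic": res.statistic,
        "p_value": res.p_value,
    }


def _numeric_group_entry(low: np.ndarray, high: np.ndarray) -> dict:
    low = low[~np.isnan(low)]
    high = high[~np.isnan(high)]
    with warnings.catch_warnings():
        # fixture-style columns can be near-constant within a group; the
        # resulting precision warning is expected, not actionable
        warnings.simplefilter("ignore", RuntimeWarning)
        res = group_comparison([low, high], GroupTest.WELCH_T)
    return {
        "low_mean": float(low.mean()),
        "low_sd": float(low.std(ddof=1)),
        "high_mean": float(high.mean()),
        "high_sd": float(high.std(ddof=1)),
        "test": res.test_used.value,
        "statistic": res.statistic,
        "p_value": res.p_value,
    }


_CORRELATION_VARS = (
    ("systolic_si", None),
    ("diastolic_si", None),
    ("rts", None),
    ("triss", None),
    ("iss", None),
    ("lactate", None),
    ("sofa", None),
    ("blood_units", "transfused"),  # among transfused patients only
    ("icu_los", None),
    ("fibrinogen", None),
    ("abdominal_ais", None),
)

_THRESHOLD_TESTS = (
    # (name, score column, cutoff source, strict inequality)
    ("fasila", "fasila_total", None, False),
    ("systolic_si", "systolic_si", 0.80, True),
    ("diastolic_si", "diastolic_si", 2.2, True),
)

_AUROC_SCORES = ("fasila_total", "abc_total", "systolic_si", "diastolic_si", "sofa")
_AUROC_OUTCOMES = ("mtp", "transfusion", "surgery")

_REGRESSION_PREDICTORS = ("fasila_total", "abdominal_ais", "iss", "sofa", "fibrinogen")


def evaluate_cohort(
    df: pd.DataFrame,
    *,
    outcome: str = "surgery",
    cutoff: int = DEFAULT_CUTOFF,
    ci_method: CIMethod | str = CIMethod.CLOPPER_PEARSON,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Run the full evaluation on a scored cohort table.

    ``df`` must already carry the score columns (see :func:`score_dataframe`);
    flagged rows are excluded with a logged count.  The primary ``outcome``
    drives the diagnostic panels; a single-class primary outcome raises
    :class:`~fasila.diagnostics.DegenerateDataError`.
    """
    missing = [c for c in SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise KeyError(f"input is not a scored cohort; missing columns {missing}")
    scored = df[df["fasila_total"].notna()].reset_index(drop=True)
    n_excluded = len(df) - len(scored)

    y = outcome_vector(scored, outcome)
    if y.all() or not y.any():
        raise DegenerateDataError(
            f"outcome '{outcome}' has a single class; evaluation undefined"
        )
    totals = scored["fasila_total"].to_numpy(dtype=float)
    high = totals >= cutoff

    report: dict = {
        "meta": {
            "schema_version": REPORT_SCHEMA_VERSION,
            "package_version": __version__,
            "n_input": int(len(df)),
            "n_scored": int(len(scored)),
            "n_excluded_unscorable": int(n_excluded),
            "outcome": outcome,
            "cutoff": int(cutoff),
            "ci_method": CIMethod(ci_method).value,
            "n_boot": int(n_boot),
            "seed": int(seed),
        }
    }

    # score distribution over the 7 levels
    level_counts = {
        str(k): int((totals == k).sum()) for k in range(7)
    }
    report["score_distribution"] = {
        "per_level": level_counts,
        "n_high": int(high.sum()),
        "n_low": int((~high).sum()),
    }

    # low-vs-high group comparison (Table 2 style)
    comparison: dict = {}
    num = scored.apply(pd.to_numeric, errors="coerce")
    comparison["age"] = _numeric_group_entry(
        num.loc[~high, "age"].to_numpy(float), num.loc[high, "age"].to_numpy(float)
    )
    for col in ("systolic_si", "diastolic_si", "iss", "sofa", "abdominal_ais", "rts", "triss"):
        comparison[col] = _numeric_group_entry(
            num.loc[~high, col].to_numpy(float), num.loc[high, col].to_numpy(float)
        )
    male = (scored["sex"].astype(str).str.lower() == "male").to_numpy()
    comparison["male_sex"] = _binary_group_entry(male[~high], male[high])
    pen = (scored["mechanism"].astype(str).str.lower() == "penetrating").to_numpy()
    comparison["penetrating"] = _binary_group_entry(pen[~high], pen[high])
    fib = num["fibrinogen"].to_numpy(float)
    has_fib = ~np.isnan(fib)
    hypofib = fib < 2.0
    comparison["hypofibrinogenemia"] = _binary_group_entry(
        hypofib[has_fib & ~high], hypofib[has_fib & high]
    )
    for name in OUTCOME_PRESETS:
        v = outcome_vector(scored, name)
        comparison[name] = _binary_group_entry(v[~high], v[high])
    report["group_comparison"] = comparison

    # correlations vs the score total (Table 3 style), pairwise deletion
    correlations: dict = {}
    for col, restrict in _CORRELATION_VARS:
        if col not in num.columns:
            continue
        x = totals
        v = num[col].to_numpy(float)
        if restrict is not None:
            keep = _as_bool(scored[restrict]).to_numpy()
            x, v = x[keep], v[keep]
        try:
            res = pearson_correlation(x, v)
            correlations[col] = {"r": res.r, "n": res.n, "p_two_sided": res.p_two_sided}
        except DegenerateDataError as exc:
            correlations[col] = {"error": str(exc)}
    report["correlations"] = correlations

    # diagnostic panels at the stated thresholds (Table 4 style)
    panels: dict = {}
    for name, col, cut, strict in _THRESHOLD_TESTS:
        cut = float(cutoff) if cut is None else cut
        scores = num[col].to_numpy(float)
        conf = confusion_from_threshold(scores, y, cut, strict=strict)
        panel = diagnostic_metrics(conf, ci_method)
        entry = _panel_dict(panel)
        entry["confusion"] = {"tp": conf.tp, "fp": conf.fp, "fn": conf.fn, "tn": conf.tn}
        entry["cutoff"] = cut
        entry["strict_inequality"] = strict
        entry["auc_continuous"] = auroc_mann_whitney(scores, y).auc
        try:
            orr = odds_ratio(conf)
            entry["odds_ratio"] = {
                "estimate": orr.or_estimate,
                "lo": orr.lo,
                "hi": orr.hi,
                "continuity_corrected": orr.continuity_corrected,
            }
        except DegenerateDataError as exc:
            entry["odds_ratio"] = {"error": str(exc)}
        panels[name] = entry
    report["diagnostic_panels"] = panels

    # AUROC comparison set (Figure 2 style)
    auroc: dict = {}
    for out_name in _AUROC_OUTCOMES:
        v = outcome_vector(scored, out_name)
        entry: dict = {}
        if v.all() or not v.any():
            entry["error"] = f"outcome '{out_name}' has a single class"
        else:
            for col in _AUROC_SCORES:
                entry[col] = auroc_mann_whitney(num[col].to_numpy(float), v).auc
            cmp_res = auroc_bootstrap_compare(
                num["fasila_total"].to_numpy(float),
                num["abc_total"].to_numpy(float),
                v,
                n_boot=n_boot,
                seed=seed,
            )
            entry["fasila_vs_abc"] = {
                "delta": cmp_res.delta,
                "delta_ci": list(cmp_res.delta_ci),
                "fasila_ci": list(cmp_res.ci_a),
                "abc_ci": list(cmp_res.ci_b),
                "n_boot": cmp_res.n_boot,
            }
        auroc[out_name] = entry
    report["auroc"] = auroc

    # multivariable logistic regression for blood transfusion (Figure 3 style)
    tx = outcome_vector(scored, "transfusion")
    X = num[list(_REGRESSION_PREDICTORS)].to_numpy(float)
    complete = ~np.isnan(X).any(axis=1)
    reg: dict = {
        "outcome": "transfusion",
        "predictors": list(_REGRESSION_PREDICTORS),
        "n_used": int(complete.sum()),
        "n_dropped_listwise": int((~complete).sum()),
    }
    try:
        fit = logistic_irls(
            X[complete], tx[complete].astype(float), names=_REGRESSION_PREDICTORS
        )
        ci = fit.or_ci()
        reg["terms"] = {
            name: {
                "coef": float(fit.coef[j]),
                "se": float(fit.se[j]),
                "odds_ratio": float(fit.odds_ratios[j]),
                "or_lo": float(ci[j, 0]),
                "or_hi": float(ci[j, 1]),
            }
            for j, name in enumerate(fit.names)
        }
        reg["converged"] = fit.converged
        reg["iterations"] = fit.iterations
        reg["log_likelihood"] = fit.log_likelihood
    except DegenerateDataError as exc:
        reg["error"] = str(exc)
    report["logistic_regression"] = reg

    # post-hoc two-proportion power on transfusion, low vs high group
    p_low = float(tx[~high].mean())
    p_high = float(tx[high].mean())
    try:
        report["post_hoc_power"] = {
            "p_low": p_low,
            "p_high": p_high,
            "n_low": int((~high).sum()),
            "n_high": int(high.sum()),
            "alpha": 0.05,
            "power": two_proportion_power(
                p_low, p_high, int((~high).sum()), int(high.sum())
            ),
        }
    except DegenerateDataError as exc:  # pragma: no cover
        report["post_hoc_power"] = {"error": str(exc)}

    return report


# ---------------------------------------------------------------------------
# text rendering


def _pct(x: Optional[float]) -> str:
    return "undefined" if x is None else f"{100 * x:.1f}%"


def _ci_str(entry: Optional[dict]) -> str:
    if entry is None:
        return "undefined"
    return f"{100 * entry['estimate']:.1f}% ({100 * entry['lo']:.1f}%-{100 * entry['hi']:.1f}%)"


def render_text_report(report: dict) -> str:
    """Human-readable tables mirroring the JSON report."""
    lines: list[str] = []
    meta = report["meta"]
    lines.append(
        f"Cohort evaluation (n={meta['n_scored']}, outcome={meta['outcome']}, "
        f"cutoff={meta['cutoff']}, seed={meta['seed']})"
    )
    dist = report["score_distribution"]
    lines.append("")
    lines.append("Score distribution (levels 0-6): " + ", ".join(
        f"{k}:{v}" for k, v in sorted(dist["per_level"].items())
    ))
    lines.append(f"Low (< cutoff): {dist['n_low']}   High (>= cutoff): {dist['n_high']}")

    lines.append("")
    lines.append("Low vs high comparison")
    lines.append(f"{'variable':<22}{'low':>22}{'high':>22}{'p':>10}")
    for var, e in report["group_comparison"].items():
        if "low_mean" in e:
            low = f"{e['low_mean']:.2f} +/- {e['low_sd']:.2f}"
            high = f"{e['high_mean']:.2f} +/- {e['high_sd']:.2f}"
        else:
            low = f"{e['low_count']} ({e['low_pct']:.1f}%)"
            high = f"{e['high_count']} ({e['high_pct']:.1f}%)"
        lines.append(f"{var:<22}{low:>22}{high:>22}{e['p_value']:>10.4f}")

    lines.append("")
    lines.append("Correlations with the score total")
    lines.append(f"{'variable':<22}{'r':>8}{'n':>6}{'p':>10}")
    for var, e in report["correlations"].items():
        if "error" in e:
            lines.append(f"{var:<22}{'--':>8}{'--':>6}  {e['error']}")
        else:
            lines.append(f"{var:<22}{e['r']:>8.3f}{e['n']:>6}{e['p_two_sided']:>10.4f}")

    lines.append("")
    lines.append(f"Diagnostic panels for outcome '{meta['outcome']}'")
    for name, e in report["diagnostic_panels"].items():
        op = ">" if e["strict_inequality"] else ">="
        c = e["confusion"]
        lines.append(
            f"  {name} {op} {e['cutoff']:g}  "
            f"(tp {c['tp']}, fp {c['fp']}, fn {c['fn']}, tn {c['tn']})"
        )
        lines.append(f"    sensitivity {_ci_str(e['sensitivity'])}")
        lines.append(f"    specificity {_ci_str(e['specificity'])}")
        lines.append(f"    PPV         {_ci_str(e['ppv'])}")
        lines.append(f"    NPV         {_ci_str(e['npv'])}")
        lines.append(
            f"    AUC (binary rule) {e['auc_binary']:.2f}   "
            f"AUC (continuous score) {e['auc_continuous']:.2f}"
        )

    lines.append("")
    lines.append("AUROC by outcome")
    for out_name, e in report["auroc"].items():
        if "error" in e:
            lines.append(f"  {out_name}: {e['error']}")
            continue
        parts = [f"{c}={e[c]:.2f}" for c in _AUROC_SCORES if c in e]
        lines.append(f"  {out_name}: " + ", ".join(parts))
        d = e["fasila_vs_abc"]
        lines.append(
            f"    fasila vs abc: dAUC={d['delta']:+.3f} "
            f"(95% CI {d['delta_ci'][0]:+.3f} to {d['delta_ci'][1]:+.3f}, "
            f"{d['n_boot']} bootstrap replicates)"
        )

    reg = report["logistic_regression"]
    lines.append("")
    lines.append(
        f"Logistic regression for {reg['outcome']} "
        f"(n={reg['n_used']}, dropped={reg['n_dropped_listwise']})"
    )
    if "error" in reg:
        lines.append(f"  {reg['error']}")
    else:
        lines.append(f"{'term':<16}{'OR':>8}{'95% CI':>20}")
        for term, t in reg["terms"].items():
            ci = f"({t['or_lo']:.2f}-{t['or_hi']:.2f})"
            lines.append(f"{term:<16}{t['odds_ratio']:>8.2f}{ci:>20}")

    pw = report["post_hoc_power"]
    if "power" in pw:
        lines.append("")
        lines.append(
            f"Post-hoc two-proportion power (transfusion, low vs high): "
            f"{100 * pw['power']:.2f}%"
        )
    return "\n".join(lines) + "\n"
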
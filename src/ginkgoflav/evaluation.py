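"""Model metrics and the preprocessing x model comparison report.

R² = 1 − Σ(y−ŷ)² / Σ(y−ȳ)² and RMSE = √(Σ(y−ŷ)²/n), both computed over
the evaluated set (so test-set R² uses the test-set mean).  Pretreatment
effects are summarized as percent changes against each family's
raw-spectra baseline, and the best run is the one with minimal test RMSE
(ties broken by higher test R²).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd


def r_squared(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Coefficient of determination, 1 − SSE/SST with SST about mean(y)."""
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.shape != y_hat.shape:
        raise ValueError("y and y_hat must have equal length")
    if y.size < 2:
        raise ValueError("need at least 2 observations for R²")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst <= 0:
        raise ValueError("y is constant; R² denominator undefined")
    return 1.0 - float(np.sum((y - y_hat) ** 2)) / sst


def rmse(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Root mean square error in the units of y (mg·g⁻¹ for TFC)."""
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.shape != y_hat.shape:
        raise ValueError("y and y_hat must have equal length")
    if y.size == 0:
        raise ValueError("RMSE of an empty set is undefined")
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


def metrics(y: np.ndarray, y_hat: np.ndarray) -> dict:
    """R², RMSE, n and the evaluated-set mean, as a plain dict."""
    y = np.asarray(y, dtype=float).ravel()
    return {
        "r2": r_squared(y, y_hat),
        "rmse": rmse(y, y_hat),
        "n": int(y.size),
        "y_mean": float(y.mean()),
    }


def percent_change(baseline: float, treated: float) -> float:
    """Signed percent change 100·(treated − baseline)/baseline."""
    if baseline == 0:
        raise ValueError("percent change undefined for a zero baseline")
    return 100.0 * (treated - baseline) / baseline


def phenotype_summary(tfc_table: pd.DataFrame) -> dict:
    """Descriptive per-phenotype TFC summary and the LL−UL mean contrast.

    Expects columns ``phenotype`` (LL/UL) and a TFC column (``tfc`` or
    ``true_tfc``).  No hypothesis test is performed; the contrast is
    reported with its standard error.
    """
    col = "tfc" if "tfc" in tfc_table.columns else "true_tfc"
    groups = {}
    for phen in ("LL", "UL"):
        vals = tfc_table.loc[tfc_table["phenotype"] == phen, col].to_numpy(
            dtype=float)
        if vals.size == 0:
            raise ValueError(f"phenotype group {phen} absent from the table")
        groups[phen] = {
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
            "n": int(vals.size),
        }
    se = float(np.sqrt(
        groups["LL"]["sd"] ** 2 / groups["LL"]["n"]
        + groups["UL"]["sd"] ** 2 / groups["UL"]["n"]))
    return {
        "groups": groups,
        "mean_difference": groups["LL"]["mean"] - groups["UL"]["mean"],
        "se_difference": se,
    }


def build_report(runs: list) -> dict:
    """Assemble the comparison report from a list of ModelRun objects.

    Rows carry both metric sets and hyperparameters; percent changes are
    computed per family against that family's raw baseline; ``best_row``
    is the (family, preprocessing) pair with minimal test RMSE, ties broken
    by higher test R².  Families with a treated run but no raw baseline get
    a warning instead of a percent change.
    """
    if not runs:
        raise ValueError("no model runs to report")
    ok = [r for r in runs if r.error is None]
    failed = [r for r in runs if r.error is not None]
    rows = []
    for r in ok:
        rows.append({
            "family": r.family,
            "preprocessing": r.preprocessing,
            "best_params": r.best_params,
            "seed": r.seed,
            "train_r2": r.metrics_train["r2"],
            "train_rmse": r.metrics_train["rmse"],
            "test_r2": r.metrics_test["r2"],
            "test_rmse": r.metrics_test["rmse"],
        })
    baselines = {r.family: r for r in ok if r.preprocessing == "raw"}
    pct, warnings = [], []
    for r in ok:
        if r.preprocessing == "raw":
            continue
        base = baselines.get(r.family)
        if base is None:
            warnings.append(
                f"no raw baseline for family {r.family}; percent change "
                f"omitted for {r.family}+{r.preprocessing}")
            continue
        pct.append({
            "family": r.family,
            "preprocessing": r.preprocessing,
            "test_r2_pct_change": percent_change(
                base.metrics_test["r2"], r.metrics_test["r2"]),
            "test_rmse_pct_change": percent_change(
                base.metrics_test["rmse"], r.metrics_test["rmse"]),
        })
    for r in failed:
        warnings.append(
            f"run {r.family}+{r.preprocessing} failed: {r.error}")
    best = None
    if ok:
        best_run = min(
            ok, key=lambda r: (r.metrics_test["rmse"], -r.metrics_test["r2"]))
        best = {"family": best_run.family,
                "preprocessing": best_run.preprocessing}
    return {
        "rows": rows,
        "percent_changes": pct,
        "best_row": best,
        "warnings": warnings,
        "runs": [r.to_dict() for r in runs],
    }


def report_to_text(report: dict) -> str:
    """Plain-text summary table of a comparison report."""
    lines = [
        f"{'family':<8} {'prep':<8} {'train R2':>9} {'train RMSE':>11} "
        f"{'test R2':>9} {'test RMSE':>10}"
    ]
    for row in report["rows"]:
        lines.append(
            f"{row['family']:<8} {row['preprocessing']:<8} "
            f"{row['train_r2']:>9.4f} {row['train_rmse']:>11.4f} "
            f"{row['test_r2']:>9.4f} {row['test_rmse']:>10.4f}")
    for c in report["percent_changes"]:
        lines.append(
            f"{c['family']}+{c['preprocessing']} vs raw: "
            f"test R2 {c['test_r2_pct_change']:+.2f}%, "
            f"test RMSE {c['test_rmse_pct_change']:+.2f}%")
    if report["best_row"]:
        lines.append(
            f"best: {report['best_row']['family']}"
            f"+{report['best_row']['preprocessing']} (min test RMSE)")
    for w in report["warnings"]:
        lines.append(f"warning: {w}")
    return "\n".join(lines) + "\n"


def write_report(report: dict, out_dir: str | Path) -> None:
    """Serialize report.json (sorted keys, deterministic) and report.txt."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True))
    (out / "report.txt").write_text(report_to_text(report))
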
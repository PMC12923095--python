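"""Result analysis: from per-condition metric tables to robustness reports.

Consumes the harness result table (task, model, ptype, level, metric,
value, n_items) including the unperturbed ``original`` rows, classifies
every perturbed cell against its baseline, and runs the statistical chain:
category proportions, Pearson chi-squared independence tests, Friedman rank
tests per dimension with Conover–Bonferroni post hocs, and one-way
repeated-measures ANOVA per dimension.

Two granularities mirror the two published summary tables: the per-metric
view (every metric of every condition is one cell) and the analysis-metric
view (one representative metric per task — accuracy for classification,
ROUGE-L for question answering — giving one cell per condition).
"""

from __future__ import annotations

import warnings
from typing import Sequence

import pandas as pd

from .errors import SchemaError
from .stats import (
    CATEGORIES,
    classify_robustness,
    conover_posthoc,
    friedman_test,
    pearson_chi_squared,
    repeated_measures_anova,
    tabulate_robustness,
    totals_row,
)

RESULT_COLUMNS = ("task", "model", "ptype", "level", "metric", "value", "n_items")

#: One representative metric per task for condition-level analyses.
ANALYSIS_METRIC = {
    "sentiment_binary": "accuracy",
    "condition_ternary": "accuracy",
    "qa": "rouge",
}

#: Ordinal level names within each perturbation type's grid.
LEVEL_NAMES = ("low", "medium", "high")


def validate_results(results: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in RESULT_COLUMNS if c not in results.columns]
    if missing:
        raise SchemaError(f"results table missing columns {missing}")
    if results.empty:
        raise SchemaError("results table is empty")
    bad = results[(results["value"] < 0) | (results["value"] > 1)]
    if len(bad):
        raise SchemaError(f"metric values outside [0,1] in rows {bad.index.tolist()[:5]}")
    return results


def robustness_cells(results: pd.DataFrame) -> pd.DataFrame:
    """Classify every perturbed (task, model, ptype, level, metric) cell.

    The baseline is the ``original`` row with the same (task, model, metric).
    Cells with no baseline are an error; zero baselines are excluded with a
    warning (relative change is undefined).
    """
    validate_results(results)
    base = results[results["ptype"] == "original"].set_index(["task", "model", "metric"])["value"]
    pert = results[results["ptype"] != "original"].copy()
    rows = []
    for _, row in pert.iterrows():
        key = (row["task"], row["model"], row["metric"])
        if key not in base.index:
            raise SchemaError(f"no original baseline for {key}")
        original = float(base.loc[key])
        if original <= 0:
            warnings.warn(f"zero baseline for {key}; cell excluded")
            continue
        rows.append(
            {
                "task": row["task"],
                "model": row["model"],
                "ptype": row["ptype"],
                "level": row["level"],
                "metric": row["metric"],
                "category": classify_robustness(original, float(row["value"])),
            }
        )
    return pd.DataFrame(rows)


def analysis_metric_slice(results: pd.DataFrame) -> pd.DataFrame:
    keep = results.apply(lambda r: ANALYSIS_METRIC.get(r["task"]) == r["metric"], axis=1)
    return results[keep]


def _level_rank(results: pd.DataFrame) -> pd.Series:
    """Map each row's level to its ordinal name within its ptype grid."""
    names = {}
    for ptype, group in results[results["ptype"] != "original"].groupby("ptype"):
        for name, lv in zip(LEVEL_NAMES, sorted(group["level"].unique())):
            names[(ptype, lv)] = name
    out = results.apply(
        lambda r: "original" if r["ptype"] == "original" else names[(r["ptype"], r["level"])],
        axis=1,
    )
    return out


def condition_matrix(results: pd.DataFrame, dimension: str) -> pd.DataFrame:
    """Blocks × treatments matrix of analysis-metric values for one dimension.

    dimension ∈ {ptype, level, model, task}. Treatments are that dimension's
    values; blocks are the complete cases over the remaining identifiers
    (incomplete blocks are dropped with a warning, e.g. a model that was
    never run on a task).
    """
    df = analysis_metric_slice(validate_results(results)).copy()
    df["level_name"] = _level_rank(df)
    if dimension == "ptype":
        df = df[df["ptype"] != "original"]
        piv = df.pivot_table(
            index=["task", "model", "level_name"], columns="ptype", values="value"
        )
    elif dimension == "level":
        # originals replicate across the three ptypes to complete the blocks
        pert = df[df["ptype"] != "original"]
        orig = df[df["ptype"] == "original"]
        frames = [pert]
        for ptype in pert["ptype"].unique():
            o = orig.copy()
            o["ptype"] = ptype
            frames.append(o)
        piv = pd.concat(frames).pivot_table(
            index=["task", "model", "ptype"], columns="level_name", values="value"
        )
        piv = piv[[c for c in ("original", "low", "medium", "high") if c in piv.columns]]
    elif dimension == "model":
        df = df[df["ptype"] != "original"]
        piv = df.pivot_table(
            index=["task", "ptype", "level_name"], columns="model", values="value"
        )
    elif dimension == "task":
        df = df[df["ptype"] != "original"]
        piv = df.pivot_table(
            index=["model", "ptype", "level_name"], columns="task", values="value"
        )
    else:
        raise ValueError(f"unknown dimension {dimension!r}")
    incomplete = piv.isna().any(axis=1)
    if incomplete.any():
        warnings.warn(f"{dimension}: dropping {int(incomplete.sum())} incomplete blocks")
        piv = piv[~incomplete]
    return piv


def analyze_results(results: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Full statistical report bundle for one results table."""
    results = validate_results(results)
    cells = robustness_cells(results)

    per_metric = cells
    by_task_model = tabulate_robustness(
        ((f"{t}/{m}", c) for t, m, c in zip(per_metric["task"], per_metric["model"], per_metric["category"])),
        index_name="task/model",
    )
    by_model = tabulate_robustness(zip(per_metric["model"], per_metric["category"]), "model")
    by_task = tabulate_robustness(zip(per_metric["task"], per_metric["category"]), "task")
    am_cells = cells.merge(
        pd.Series(ANALYSIS_METRIC, name="am").rename_axis("task").reset_index(), on="task"
    )
    am_cells = am_cells[am_cells["metric"] == am_cells["am"]]
    by_ptype = tabulate_robustness(zip(am_cells["ptype"], am_cells["category"]), "ptype")

    report: dict = {
        "tables": {
            "by_task_model": by_task_model,
            "by_model": by_model,
            "by_task": by_task,
            "by_ptype": by_ptype,
            "totals": totals_row(by_task_model, decimals=2),
            "totals_by_ptype": totals_row(by_ptype, decimals=1),
        },
        "chi_squared": {},
        "friedman": {},
        "conover": {},
        "rm_anova": {},
    }
    for name, table in (("model", by_model), ("task", by_task), ("ptype", by_ptype)):
        try:
            report["chi_squared"][name] = pearson_chi_squared(table)
        except ValueError as exc:
            warnings.warn(f"chi-squared by {name} skipped: {exc}")
    for dimension in ("ptype", "level", "model", "task"):
        try:
            matrix = condition_matrix(results, dimension)
        except (ValueError, KeyError) as exc:
            warnings.warn(f"dimension {dimension} skipped: {exc}")
            continue
        if matrix.shape[0] < 2 or matrix.shape[1] < 2:
            warnings.warn(f"dimension {dimension}: not enough complete blocks")
            continue
        report["friedman"][dimension] = friedman_test(matrix.to_numpy())
        report["conover"][dimension] = conover_posthoc(
            matrix.to_numpy(), labels=list(matrix.columns), alpha=alpha
        )
        report["rm_anova"][dimension] = repeated_measures_anova(matrix.to_numpy())
    return report


def percent_change_profile(results: pd.DataFrame) -> pd.DataFrame:
    """Percent change vs baseline per task × ptype × level (bar-chart layout)."""
    df = analysis_metric_slice(validate_results(results)).copy()
    base = df[df["ptype"] == "original"].set_index(["task", "model"])["value"]
    pert = df[df["ptype"] != "original"].copy()

    def change(row):
        b = float(base.loc[(row["task"], row["model"])])
        return 100.0 * (row["value"] - b) / b

    pert["percent_change"] = pert.apply(change, axis=1)
    return (
        pert.groupby(["task", "ptype", "level"])["percent_change"].mean().reset_index()
    )


def read_results_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "level" in df.columns:
        df["level"] = pd.to_numeric(df["level"], errors="coerce")
        df.loc[df["ptype"] == "original", "level"] = None
    return validate_results(df)


def write_results_csv(results: pd.DataFrame, path) -> None:
    validate_results(results).to_csv(path, index=False)
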
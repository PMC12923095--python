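"""Robustness classification and the statistical analysis chain.

Performance under perturbation is summarised by the relative change
Δ = (perturbed − original) / original and binned into four categories:

* increase      — Δ > 0
* stable        — −0.05 ≤ Δ ≤ 0 (drop of at most 5%)
* decrease      — −0.50 ≤ Δ < −0.05
* catastrophic  — Δ < −0.50 (perturbed value below half the original)

The boundary points are assigned so the bins partition the real line.
Category counts feed a Pearson chi-squared independence test; per-condition
metric values feed Friedman rank tests (tie-corrected), Conover post hoc
pairwise tests with Bonferroni correction, and a one-way within-subjects
(repeated-measures) ANOVA. The medical-term profile buckets examples by the
fraction of perturbed words that are medical terms and tracks the median
score per bucket.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .perturb import PerturbedExample

CATEGORIES = ("increase", "stable", "decrease", "catastrophic")


@dataclass(frozen=True)
class TestReport:
    name: str
    statistic: float
    df: int | tuple[int, int]
    pvalue: float
    extra: dict = field(default_factory=dict)


@dataclass(frozen=True)
class PairReport:
    """One Conover post hoc comparison."""

    group1: str
    group2: str
    t: float
    pvalue: float
    p_corrected: float
    effect_size_r: float


def classify_robustness(original_value: float, perturbed_value: float) -> str:
    """Bin one (original, perturbed) metric pair; baseline must be positive."""
    if original_value <= 0:
        raise ValueError(f"undefined baseline: original value must be > 0, got {original_value}")
    delta = (perturbed_value - original_value) / original_value
    eps = 1e-12  # keep exact -5% / -50% drops on their stated side of the boundary
    if delta > 0:
        return "increase"
    if delta >= -0.05 - eps:
        return "stable"
    if delta >= -0.50 - eps:
        return "decrease"
    return "catastrophic"


def tabulate_robustness(cells: Iterable[tuple], index_name: str = "group") -> pd.DataFrame:
    """Contingency table of robustness categories.

    ``cells`` yields (group key, category) pairs; an empty input gives an
    all-zero one-row table.
    """
    counts: dict[object, dict[str, int]] = {}
    for key, cat in cells:
        if cat not in CATEGORIES:
            raise ValueError(f"unknown category {cat!r}")
        row = counts.setdefault(key, {c: 0 for c in CATEGORIES})
        row[cat] += 1
    if not counts:
        counts = {"all": {c: 0 for c in CATEGORIES}}
    table = pd.DataFrame.from_dict(counts, orient="index", columns=list(CATEGORIES))
    table.index.name = index_name
    return table.sort_index()


def percentage(count: int, total: int, decimals: int = 2) -> float:
    """Percentage rounded half-up at the table's printed precision."""
    if total == 0:
        return 0.0
    q = Decimal(1).scaleb(-decimals)
    return float((Decimal(count) * 100 / Decimal(total)).quantize(q, rounding=ROUND_HALF_UP))


def totals_row(table: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Category totals with percentages, in the published-table layout."""
    tot = table.sum(axis=0)
    grand = int(tot.sum())
    return pd.DataFrame(
        {
            "count": tot.astype(int),
            "percent": [percentage(int(c), grand, decimals) for c in tot],
        }
    )


def pearson_chi_squared(table: pd.DataFrame) -> TestReport:
    """Pearson chi-squared independence test (no continuity correction).

    Zero-margin rows/columns are dropped with a warning before testing.
    """
    values = table.to_numpy(dtype=float)
    row_ok = values.sum(axis=1) > 0
    col_ok = values.sum(axis=0) > 0
    if not row_ok.all() or not col_ok.all():
        warnings.warn("dropping zero-margin rows/columns before chi-squared test")
        values = values[row_ok][:, col_ok]
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("chi-squared requires at least a 2x2 table after margin pruning")
    stat, p, df, _ = sps.chi2_contingency(values, correction=False)
    return TestReport("pearson_chi_squared", float(stat), int(df), float(p))


def _block_ranks(matrix: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(sps.rankdata, 1, matrix)


def friedman_test(matrix) -> TestReport:
    """Tie-corrected Friedman test over an n-blocks × k-treatments matrix."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need at least 2 blocks and 2 treatments")
    if np.isnan(m).any():
        raise ValueError("missing cells are not allowed")
    n, k = m.shape
    ranks = _block_ranks(m)
    col_sums = ranks.sum(axis=0)
    stat_uncorrected = 12.0 / (n * k * (k + 1)) * np.sum(col_sums**2) - 3.0 * n * (k + 1)
    ties = 0.0
    for row in m:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    correction = 1.0 - ties / (n * k * (k**2 - 1))
    if correction <= 0:  # every block constant: no information, no effect
        return TestReport("friedman", 0.0, k - 1, 1.0)
    stat = stat_uncorrected / correction
    return TestReport("friedman", float(stat), k - 1, float(sps.chi2.sf(stat, k - 1)))


def conover_posthoc(
    matrix,
    labels: Sequence[str] | None = None,
    alpha: float = 0.05,
    correction: str = "bonferroni",
) -> list[PairReport]:
    """Conover's pairwise post hoc tests after a Friedman test.

    t = |R_i − R_j| / sqrt(2n(A − B) / ((n−1)(k−1))) with A the sum of squared
    within-block ranks and B = Σ R_j² / n; df = (n−1)(k−1). Bonferroni
    multiplies each p by the number of pairs (capped at 1). The effect size
    r = |t| / sqrt(t² + df) is reported alongside.
    """
    if correction not in ("bonferroni", "none"):
        raise ValueError(f"unsupported correction {correction!r}")
    m = np.asarray(matrix, dtype=float)
    n, k = m.shape
    if k < 3:
        warnings.warn("fewer than 3 treatments: post hoc comparisons skipped")
        return []
    labels = list(labels) if labels is not None else [f"T{j}" for j in range(k)]
    ranks = _block_ranks(m)
    col_sums = ranks.sum(axis=0)
    A = float(np.sum(ranks**2))
    B = float(np.sum(col_sums**2)) / n
    df = (n - 1) * (k - 1)
    denom_sq = 2.0 * n * (A - B) / df
    n_pairs = k * (k - 1) // 2
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = abs(col_sums[i] - col_sums[j])
            if denom_sq <= 0:
                t = 0.0 if diff == 0 else np.inf
            else:
                t = float(diff / np.sqrt(denom_sq))
            p = float(2.0 * sps.t.sf(t, df)) if np.isfinite(t) else 0.0
            p_corr = min(1.0, p * n_pairs) if correction == "bonferroni" else p
            r = float(abs(t) / np.sqrt(t**2 + df)) if np.isfinite(t) else 1.0
            out.append(PairReport(labels[i], labels[j], t, p, p_corr, r))
    return out


def repeated_measures_anova(matrix) -> TestReport:
    """One-way within-subjects ANOVA over an n-subjects × k-treatments matrix."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need at least 2 subjects and 2 treatments")
    if np.isnan(m).any():
        raise ValueError("missing cells are not allowed (no imputation)")
    n, k = m.shape
    grand = m.mean()
    ss_treat = n * float(np.sum((m.mean(axis=0) - grand) ** 2))
    ss_subj = k * float(np.sum((m.mean(axis=1) - grand) ** 2))
    ss_total = float(np.sum((m - grand) ** 2))
    ss_err = max(ss_total - ss_treat - ss_subj, 0.0)
    df_treat, df_err = k - 1, (n - 1) * (k - 1)
    if ss_treat == 0:
        return TestReport("rm_anova", 0.0, (df_treat, df_err), 1.0)
    if ss_err == 0:
        return TestReport("rm_anova", float("inf"), (df_treat, df_err), 0.0)
    f = (ss_treat / df_treat) / (ss_err / df_err)
    return TestReport(
        "rm_anova",
        float(f),
        (df_treat, df_err),
        float(sps.f.sf(f, df_treat, df_err)),
        extra={"ss_treatment": ss_treat, "ss_subject": ss_subj, "ss_error": ss_err},
    )


def medical_perturbation_profile(
    examples: Sequence[PerturbedExample],
    scores: Sequence[float],
    n_buckets: int = 10,
) -> pd.DataFrame:
    """Median score per (level, medical-perturbation-ratio bucket).

    The ratio is the fraction of an example's perturbed words that are
    medical terms; examples with no perturbed words are excluded with a
    warning. Buckets are equal-width on [0, 1] (deciles by default).
    """
    if len(examples) != len(scores):
        raise ValueError("examples and scores must be aligned")
    rows = []
    for ex, score in zip(examples, scores):
        if not ex.edits:
            warnings.warn(f"example with no perturbed tokens excluded: {ex.original[:40]!r}")
            continue
        ratio = ex.medical_edit_ratio
        bucket = min(int(ratio * n_buckets), n_buckets - 1)
        rows.append({"level": ex.spec.level, "bucket": bucket, "ratio": ratio, "score": score})
    if not rows:
        return pd.DataFrame(columns=["level", "bucket", "median_score", "n"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["level", "bucket"])
        .agg(median_score=("score", "median"), n=("score", "size"))
        .reset_index()
    )
    out["ratio_low"] = out["bucket"] / n_buckets
    out["ratio_high"] = (out["bucket"] + 1) / n_buckets
    return out
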
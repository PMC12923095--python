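"""Bundled reference data: published robustness category counts.

A published evaluation of three language models (a GPT-family chat model, a
BlueBERT encoder baseline and a Llama-family model) on three health-language
tasks classified 270 perturbed-condition metric cells — and, per perturbation
type at the analysis metric, 72 condition cells — into the four robustness
categories. Those counts ship with the package as worked-example input for
the contingency analysis: they exercise the chi-squared chain on real data
without any model calls.
"""

from __future__ import annotations

import importlib.resources
from io import StringIO

import pandas as pd

from .stats import CATEGORIES


def _load(name: str, index_cols: list[str]) -> pd.DataFrame:
    text = importlib.resources.files("perturbkit.data").joinpath(name).read_text("utf-8")
    df = pd.read_csv(StringIO(text))
    return df.set_index(index_cols)[list(CATEGORIES)]


def robustness_counts_by_task_model() -> pd.DataFrame:
    """270 metric cells: category counts per (task, model); 8 rows."""
    return _load("reference_robustness_by_task_model.csv", ["task", "model"])


def robustness_counts_by_ptype() -> pd.DataFrame:
    """72 analysis-metric cells: category counts per perturbation type."""
    return _load("reference_robustness_by_ptype.csv", ["ptype"])


def aggregate_by_model(counts: pd.DataFrame | None = None) -> pd.DataFrame:
    counts = counts if counts is not None else robustness_counts_by_task_model()
    return counts.groupby(level="model").sum()


def aggregate_by_task(counts: pd.DataFrame | None = None) -> pd.DataFrame:
    counts = counts if counts is not None else robustness_counts_by_task_model()
    return counts.groupby(level="task").sum()
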
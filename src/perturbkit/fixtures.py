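"""Synthetic fixture corpora and result tables with known ground truth.

The generators emulate the structure of the three study corpora — short
labelled sentences (binary sentiment), labelled abstracts stand-ins
(ternary condition) and (note, question, answer) triples — using only
dictionary words with known coarse POS tags and known homophone
availability. Every generated record is feasible for all nine (type, level)
grid perturbations *by construction*: sentences carry enough valid words
for the 50% redaction/typo budgets and enough homophone-bearing words for
the 30% homophone budget, so fixture corpora pass the retention rule with
zero drops and no tagger or provider flakiness.

Label signal is planted in specific keyword tokens, so perturbing them
degrades the bundled keyword/extractive mock models predictably.
``generate_result_table`` instead fabricates a per-condition performance
table in the harness output shape (the full 270-cell grid: two
classification tasks × 3 models × 4 metrics plus QA × 2 models × 3 metrics,
across 9 conditions and the originals) with programmed per-dimension
effects, for recovery and null-calibration studies of the statistics chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus import DEFAULT_GRID, TaskRecord

# word banks: every word is in the bundled POS lexicon with the listed tag;
# *_H banks are also in the bundled homophone dictionary
ADJ_H = ("weak", "sore", "plain", "fair", "new", "high", "red", "vain", "bored", "coarse")
MED_NOUN_H = ("pain", "vein", "flu", "mucus", "gait", "ileum", "humerus", "callus", "palate")
PLAIN_NOUN_H = ("week", "night", "feet", "hair", "son", "sun", "time", "board", "cell",
                "scene", "sight", "way", "weight", "hole", "sea", "nose")
VERB_H = ("see", "hear", "know", "knew", "write", "wait", "weigh", "steal", "read", "sell", "heal")
NEUTRAL_ADJ = ("severe", "mild", "chronic", "acute", "stable", "tired")
PLAIN_NOUN = ("visit", "chart", "note", "tablet", "care")

SENTIMENT_KEYWORDS = {"positive": ("happy", "calm"), "negative": ("sad", "worried")}
CONDITION_KEYWORDS = {"0": ("fever",), "1": ("rash",), "2": ("cough",)}
QA_QUESTION = "What did the examination show?"
QA_CUE = "showed"

MODELS_BY_TASK = {
    "sentiment_binary": ("GPT", "BlueBERT", "Llama"),
    "condition_ternary": ("GPT", "BlueBERT", "Llama"),
    "qa": ("GPT", "Llama"),
}
METRICS_BY_TASK = {
    "sentiment_binary": ("accuracy", "precision", "recall", "f1"),
    "condition_ternary": ("accuracy", "precision", "recall", "f1"),
    "qa": ("bleu", "rouge", "bertscore"),
}


@dataclass(frozen=True)
class FixtureConfig:
    n_records: int = 100
    seed: int = 0
    medical_fraction: float = 0.4
    label_signal: float = 1.0
    noise_sd: float = 0.03
    n_items: int = 500

    def __post_init__(self):
        for name in ("medical_fraction", "label_signal"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.n_records <= 0:
            raise ValueError("n_records must be positive")


def _pick(rng: np.random.Generator, bank: Sequence[str]) -> str:
    return bank[int(rng.integers(0, len(bank)))]


def _noun_h(rng: np.random.Generator, cfg: FixtureConfig) -> str:
    bank = MED_NOUN_H if rng.random() < cfg.medical_fraction else PLAIN_NOUN_H
    return _pick(rng, bank)


def generate_classification_corpus(
    config: FixtureConfig, task: str = "sentiment_binary"
) -> list[TaskRecord]:
    """Labelled 10-word sentences with a planted keyword signal.

    Sentence frame: "The ADJ NOUN VERB the ADJ NOUN and NOUN NOUN." —
    7 valid words per sentence, 4 of them homophone-bearing, so every grid
    condition (up to 5 words at 50%, 3 homophone swaps at 30%) is feasible.
    """
    if task not in ("sentiment_binary", "condition_ternary"):
        raise ValueError(f"not a classification task: {task}")
    rng = np.random.default_rng(config.seed)
    keywords = SENTIMENT_KEYWORDS if task == "sentiment_binary" else CONDITION_KEYWORDS
    labels = sorted(keywords)
    prefix = "s" if task == "sentiment_binary" else "c"
    records = []
    for i in range(config.n_records):
        label = labels[i % len(labels)]
        signal_on = rng.random() < config.label_signal
        if task == "sentiment_binary":
            slot_adj = _pick(rng, keywords[label]) if signal_on else _pick(rng, NEUTRAL_ADJ)
            slot_noun = _pick(rng, PLAIN_NOUN)
        else:
            slot_adj = _pick(rng, NEUTRAL_ADJ)
            slot_noun = _pick(rng, keywords[label]) if signal_on else _pick(rng, PLAIN_NOUN)
        text = (
            f"The {_pick(rng, ADJ_H)} {_noun_h(rng, config)} {_pick(rng, VERB_H)} the "
            f"{slot_adj} {_noun_h(rng, config)} and {slot_noun} {_pick(rng, PLAIN_NOUN)}."
        )
        records.append(
            TaskRecord(record_id=f"{prefix}{i:05d}", task=task, text=text, gold=label)
        )
    return records


def generate_qa_corpus(config: FixtureConfig) -> list[TaskRecord]:
    """(note, question, answer) triples, one question per note by construction.

    Each note ends with "Examination showed <answer span>." so an extractive
    mock answerer keyed on the cue verb recovers the reference answer exactly
    (ROUGE-L F = 1.0) on unperturbed notes.
    """
    rng = np.random.default_rng(config.seed + 1)
    records = []
    for i in range(config.n_records):
        answer = f"{_pick(rng, NEUTRAL_ADJ)} {_pick(rng, MED_NOUN_H)} in the {_noun_h(rng, config)}"
        note = (
            f"The {_pick(rng, ADJ_H)} patient {_pick(rng, VERB_H)} {_noun_h(rng, config)} "
            f"and {_noun_h(rng, config)} daily. Examination {QA_CUE} {answer}."
        )
        records.append(
            TaskRecord(
                record_id=f"qa{i:05d}",
                task="qa",
                text=note,
                gold=answer,
                note_id=f"note{i:05d}",
                question=QA_QUESTION,
            )
        )
    return records


@dataclass(frozen=True)
class ResultEffects:
    """Programmed relative shifts applied to perturbed-condition values.

    Each mapping adds a relative delta (e.g. -0.2 for a 20% drop) for the
    matching dimension value; unlisted values shift by zero. All-zero
    effects give a null table for calibration studies.
    """

    ptype: dict = field(default_factory=dict)
    level_name: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)
    task: dict = field(default_factory=dict)


def generate_result_table(
    config: FixtureConfig,
    effects: ResultEffects | None = None,
    grid: dict | None = None,
) -> pd.DataFrame:
    """Harness-shaped result table with programmed per-dimension effects."""
    effects = effects or ResultEffects()
    grid = grid or DEFAULT_GRID
    rng = np.random.default_rng(config.seed + 2)
    level_names = ("low", "medium", "high")
    rows = []
    for task, models in MODELS_BY_TASK.items():
        for model in models:
            for metric in METRICS_BY_TASK[task]:
                base = float(rng.uniform(0.55, 0.90))
                rows.append(
                    {
                        "task": task, "model": model, "ptype": "original", "level": None,
                        "metric": metric,
                        "value": float(np.clip(base + rng.normal(0, config.noise_sd), 0.01, 0.99)),
                        "n_items": config.n_items,
                    }
                )
                for ptype, levels in grid.items():
                    for name, level in zip(level_names, levels):
                        shift = (
                            effects.ptype.get(ptype, 0.0)
                            + effects.level_name.get(name, 0.0)
                            + effects.model.get(model, 0.0)
                            + effects.task.get(task, 0.0)
                        )
                        value = base * (1.0 + shift) + rng.normal(0, config.noise_sd)
                        rows.append(
                            {
                                "task": task, "model": model, "ptype": ptype, "level": level,
                                "metric": metric,
                                "value": float(np.clip(value, 0.01, 0.99)),
                                "n_items": config.n_items,
                            }
                        )
    return pd.DataFrame(rows)
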
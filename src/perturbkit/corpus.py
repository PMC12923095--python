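"""Corpus construction: the perturbation grid, retention rule, and splits.

Each task record is expanded into 9 perturbed variants (3 perturbation
types × 3 levels) plus the original. A record is *retained* only if every
one of the nine (type, level) perturbations is feasible for it; otherwise
it is dropped with the failing condition logged. Splits follow the
prompt-tuning / test / validation scheme, with question-answer records
split over unique notes so no note leaks across splits.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import BudgetInfeasibleError, ConfigError, SchemaError
from .homophones import DictionaryProvider, HomophoneProvider
from .perturb import PerturbationSpec, PerturbedExample, perturb_example
from .tagging import Tagger

logger = logging.getLogger(__name__)

TASKS = ("sentiment_binary", "condition_ternary", "qa")

#: Level grid per perturbation type: typos and redactions at 10/30/50% of
#: words, homophones at 10/20/30% (fewer words have homophones).
DEFAULT_GRID: dict[str, tuple[float, ...]] = {
    "typographical": (0.10, 0.30, 0.50),
    "homophone": (0.10, 0.20, 0.30),
    "redaction": (0.10, 0.30, 0.50),
}


def validate_grid(grid: dict[str, Sequence[float]]) -> None:
    for ptype, levels in grid.items():
        if len(levels) != 3:
            raise ConfigError(f"{ptype}: exactly three levels required, got {levels}")
        if list(levels) != sorted(levels) or len(set(levels)) != 3:
            raise ConfigError(f"{ptype}: levels must be strictly increasing, got {levels}")


@dataclass(frozen=True)
class TaskRecord:
    """One evaluation item: text plus gold label or reference answer."""

    record_id: str
    task: str
    text: str
    gold: str
    note_id: str | None = None
    question: str | None = None

    def __post_init__(self):
        if self.task not in TASKS:
            raise SchemaError(f"unknown task {self.task!r} (record {self.record_id})")
        if self.task == "qa":
            if not (self.text and self.question and self.gold and self.note_id):
                raise SchemaError(
                    f"qa record {self.record_id} needs non-empty note, question, answer, note_id"
                )
        elif not (self.text and self.gold is not None):
            raise SchemaError(f"record {self.record_id} needs non-empty text and label")


@dataclass
class CorpusEntry:
    """One retained record with its original and nine perturbed variants."""

    record: TaskRecord
    variants: dict[tuple[str, float], PerturbedExample] = field(default_factory=dict)


@dataclass
class DroppedRecord:
    record_id: str
    ptype: str
    level: float
    reason: str


def spec_for(ptype: str, level: float, seed: int, **kwargs) -> PerturbationSpec:
    return PerturbationSpec(ptype=ptype, level=level, seed=seed, **kwargs)


def build_perturbed_corpus(
    records: Iterable[TaskRecord],
    grid: dict[str, Sequence[float]] | None = None,
    seed: int = 0,
    provider: HomophoneProvider | None = None,
    lexicon: Iterable[str] = (),
    tagger: Tagger | None = None,
    spec_factory=spec_for,
) -> tuple[list[CorpusEntry], list[DroppedRecord]]:
    """Expand records across the grid, applying the all-nine retention rule."""
    grid = dict(grid or DEFAULT_GRID)
    validate_grid(grid)
    provider = provider or DictionaryProvider()
    corpus: list[CorpusEntry] = []
    dropped: list[DroppedRecord] = []
    for rec in records:
        entry = CorpusEntry(record=rec)
        failure: DroppedRecord | None = None
        for ptype, levels in grid.items():
            for level in levels:
                spec = spec_factory(ptype, level, seed)
                try:
                    ex = perturb_example(
                        rec.text,
                        spec,
                        provider=provider,
                        lexicon=lexicon,
                        tagger=tagger,
                        example_id=rec.record_id,
                    )
                except BudgetInfeasibleError as exc:
                    failure = DroppedRecord(rec.record_id, ptype, level, str(exc))
                    break
                entry.variants[(ptype, level)] = ex
            if failure:
                break
        if failure:
            logger.info(
                "dropped record %s: %s@%s infeasible (%s)",
                failure.record_id, failure.ptype, failure.level, failure.reason,
            )
            dropped.append(failure)
        else:
            corpus.append(entry)
    return corpus, dropped


def select_one_question_per_note(records: Sequence[TaskRecord]) -> list[TaskRecord]:
    """Keep exactly one question per medical note (lowest record id, for
    reproducibility)."""
    by_note: dict[str, TaskRecord] = {}
    for rec in records:
        if rec.task != "qa":
            raise SchemaError(f"record {rec.record_id} is not a qa record")
        cur = by_note.get(rec.note_id)
        if cur is None or rec.record_id < cur.record_id:
            by_note[rec.note_id] = rec
    return [by_note[k] for k in sorted(by_note)]


@dataclass
class SplitAssignment:
    """record id -> split name; splits are disjoint and exhaustive."""

    assignment: dict[str, str]

    def ids(self, split: str) -> list[str]:
        return sorted(rid for rid, s in self.assignment.items() if s == split)


def assign_splits(
    records: Sequence[TaskRecord],
    n_test: int = 1000,
    fraction_prompt_tuning: float = 0.20,
    seed: int = 0,
) -> SplitAssignment:
    """Carve prompt-tuning (20%) then a random test set (1000) from the rest;
    the remainder is validation. QA records are split over unique notes.
    """
    if not 0 < fraction_prompt_tuning < 1:
        raise ConfigError(f"fraction_prompt_tuning must be in (0,1), got {fraction_prompt_tuning}")
    is_qa = records and records[0].task == "qa"
    if is_qa:
        units = sorted({r.note_id for r in records})
    else:
        units = sorted({r.record_id for r in records})
    rng = np.random.default_rng(seed)
    order = [units[int(i)] for i in rng.permutation(len(units))]
    n_tuning = round(fraction_prompt_tuning * len(units))
    if n_tuning < 1:
        raise ConfigError("prompt-tuning carve-out is empty; dataset too small")
    remainder = len(units) - n_tuning
    if n_test >= remainder:
        raise ConfigError(
            f"test carve-out infeasible: need {n_test} of {remainder} records "
            "remaining after prompt tuning"
        )
    unit_split: dict[str, str] = {}
    for u in order[:n_tuning]:
        unit_split[u] = "prompt_tuning"
    for u in order[n_tuning : n_tuning + n_test]:
        unit_split[u] = "test"
    for u in order[n_tuning + n_test :]:
        unit_split[u] = "validation"
    if is_qa:
        assignment = {r.record_id: unit_split[r.note_id] for r in records}
    else:
        assignment = {r.record_id: unit_split[r.record_id] for r in records}
    return SplitAssignment(assignment)


# ---------------------------------------------------------------------------
# I/O: CSV / JSONL records in, JSONL corpus + manifest out


def read_records_csv(path: str | Path, task: str) -> list[TaskRecord]:
    """CSV with columns id, text, label."""
    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for i, row in enumerate(reader):
            try:
                out.append(
                    TaskRecord(record_id=row["id"], task=task, text=row["text"], gold=row["label"])
                )
            except KeyError as exc:
                raise SchemaError(f"{path}: row {i} missing column {exc}") from exc
    return out


def read_records_jsonl(path: str | Path, task: str) -> list[TaskRecord]:
    """JSONL records; QA rows carry note_id, note, question, answer."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            try:
                row = json.loads(line)
            except json.JSONDecodeError as exc:
                raise SchemaError(f"{path}:{lineno}: invalid JSON") from exc
            try:
                if task == "qa":
                    out.append(
                        TaskRecord(
                            record_id=str(row["id"]),
                            task=task,
                            text=row["note"],
                            gold=row["answer"],
                            note_id=str(row["note_id"]),
                            question=row["question"],
                        )
                    )
                else:
                    out.append(
                        TaskRecord(
                            record_id=str(row["id"]), task=task, text=row["text"],
                            gold=str(row["label"]),
                        )
                    )
            except KeyError as exc:
                raise SchemaError(f"{path}:{lineno}: missing field {exc}") from exc
    return out


def write_corpus_jsonl(corpus: Sequence[CorpusEntry], path: str | Path) -> None:
    """One JSON object per variant: (record id, ptype|original, level, text, gold)."""
    with open(path, "w", encoding="utf-8") as fh:
        for entry in corpus:
            rec = entry.record
            base = {"id": rec.record_id, "task": rec.task, "gold": rec.gold}
            if rec.task == "qa":
                base["note_id"] = rec.note_id
                base["question"] = rec.question
            fh.write(
                json.dumps({**base, "ptype": "original", "level": None, "text": rec.text}) + "\n"
            )
            for (ptype, level), ex in sorted(entry.variants.items()):
                fh.write(
                    json.dumps({**base, "ptype": ptype, "level": level, "text": ex.perturbed})
                    + "\n"
                )


def write_manifest(
    path: str | Path,
    grid: dict[str, Sequence[float]],
    seed: int,
    n_retained: int,
    dropped: Sequence[DroppedRecord],
    provider_version: str,
    extra: dict | None = None,
) -> None:
    manifest = {
        "grid": {k: list(v) for k, v in grid.items()},
        "seed": seed,
        "n_retained": n_retained,
        "n_dropped": len(dropped),
        "dropped": [
            {"id": d.record_id, "ptype": d.ptype, "level": d.level, "reason": d.reason}
            for d in dropped
        ],
        "homophone_provider": provider_version,
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2), encoding="utf-8")
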
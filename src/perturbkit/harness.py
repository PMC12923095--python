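"""Evaluation harness: 5-shot prompts, model adapters, per-condition scoring.

Every item is evaluated in its own session: one self-contained prompt, one
stateless adapter call, no conversational carry-over. The prompt carries a
role statement, five worked examples, task instructions, the input, an
isolation instruction (so a hosted model does not answer from short-term
memory of neighbouring cases) and a request for a short justification.

Adapters are pluggable. The bundled mocks — oracle, adversarial, keyword
classifier, extractive answerer and a noisy channel with configurable
per-condition degradation — let the whole pipeline run and be tested
without any hosted model. A generic HTTP chat-completion client covers
real endpoints.
"""

from __future__ import annotations

import json
import os
import urllib.error
import urllib.request
import re
from dataclasses import dataclass, field
from statistics import fmean
from typing import Callable, Iterable, Sequence

import pandas as pd

from .errors import AdapterError, ConfigError
from .corpus import CorpusEntry, TaskRecord
from .metrics import score_classification, score_qa
from .perturb import round_half_up

TASK_LABELS = {"sentiment_binary": ("negative", "positive"), "condition_ternary": ("0", "1", "2")}
CLASSIFICATION_METRICS = ("accuracy", "precision", "recall", "f1")
QA_METRICS = ("bleu", "rouge")

DEFAULT_ISOLATION = (
    "Treat this case in isolation: do not use information from any previous "
    "case or conversation."
)
DEFAULT_JUSTIFICATION = (
    "Provide a short justification for your answer; if none can be given, say so."
)
DEFAULT_QA_GROUNDING = "Give an answer based only on the medical note provided."


@dataclass(frozen=True)
class EvalItem:
    """One unit of evaluation: a (possibly perturbed) input plus its gold."""

    record_id: str
    task: str
    text: str
    gold: str
    question: str | None = None
    ptype: str = "original"
    level: float | None = None


@dataclass
class PromptTemplate:
    task: str
    role_statement: str
    shots: list[tuple[str, str]]
    task_instructions: str
    isolation_instruction: str = DEFAULT_ISOLATION
    justification_instruction: str = DEFAULT_JUSTIFICATION
    qa_grounding_instruction: str = DEFAULT_QA_GROUNDING
    k: int = 5

    def __post_init__(self):
        if len(self.shots) != self.k:
            raise ConfigError(f"template requires exactly {self.k} shots, got {len(self.shots)}")
        if self.task == "qa" and not self.qa_grounding_instruction:
            raise ConfigError("qa templates must carry a grounding instruction")


def default_template(task: str, shots: list[tuple[str, str]]) -> PromptTemplate:
    roles = {
        "sentiment_binary": "You are an assistant that labels the sentiment of health-related sentences.",
        "condition_ternary": "You are a clinical assistant that classifies medical abstracts by disease condition.",
        "qa": "You are a clinical assistant that answers questions about medical notes.",
    }
    instructions = {
        "sentiment_binary": "Label the sentiment of the input as positive or negative.",
        "condition_ternary": "Classify the abstract's condition as 0, 1, or 2.",
        "qa": "Answer the question about the medical note.",
    }
    return PromptTemplate(
        task=task, role_statement=roles[task], shots=shots, task_instructions=instructions[task]
    )


def build_prompt(template: PromptTemplate, item: EvalItem) -> str:
    """Assemble the full 5-shot prompt for one item."""
    if item.task != template.task:
        raise ConfigError(f"item task {item.task!r} does not match template {template.task!r}")
    parts = [template.role_statement, ""]
    for i, (shot_in, shot_out) in enumerate(template.shots, 1):
        parts += [f"Example {i}:", f"Input: {shot_in}", f"Answer: {shot_out}", ""]
    parts.append(template.task_instructions)
    if item.task == "qa":
        parts.append(template.qa_grounding_instruction)
        parts += [f"Medical note: {item.text}", f"Question: {item.question}"]
    else:
        parts.append(f"Input: {item.text}")
    parts += [template.isolation_instruction, template.justification_instruction]
    return "\n".join(parts)


def select_shots(
    records: Sequence[TaskRecord], k: int = 5, seed: int = 0
) -> list[tuple[str, str]]:
    """Seeded shot sample; classification shots label-balanced as evenly as k allows."""
    import numpy as np

    if k <= 0:
        raise ConfigError("k must be positive")
    if len(records) < k:
        raise ConfigError(f"need at least {k} records for shots, have {len(records)}")
    rng = np.random.default_rng(seed)
    task = records[0].task
    if task == "qa":
        idx = rng.choice(len(records), size=k, replace=False)
        return [
            (f"{records[int(i)].text}\nQuestion: {records[int(i)].question}", records[int(i)].gold)
            for i in idx
        ]
    by_label: dict[str, list[TaskRecord]] = {}
    for r in records:
        by_label.setdefault(r.gold, []).append(r)
    labels = sorted(by_label)
    base, extra = divmod(k, len(labels))
    extra_labels = {labels[int(i)] for i in rng.choice(len(labels), size=extra, replace=False)}
    shots: list[tuple[str, str]] = []
    for lab in labels:
        need = base + (lab in extra_labels)
        pool = by_label[lab]
        if len(pool) < need:
            raise ConfigError(f"label {lab!r} has {len(pool)} records, need {need} for shots")
        for i in rng.choice(len(pool), size=need, replace=False):
            shots.append((pool[int(i)].text, pool[int(i)].gold))
    order = rng.permutation(len(shots))
    return [shots[int(i)] for i in order]


def parse_classification_response(response: str, label_set: Sequence[str]) -> str | None:
    """First label (case-insensitive, word-boundary) mentioned in the response.

    Responses naming no label are unparseable (None) and score as incorrect.
    """
    if not label_set:
        raise ConfigError("label_set must be non-empty")
    best: tuple[int, str] | None = None
    for label in label_set:
        m = re.search(rf"(?<![\w]){re.escape(str(label))}(?![\w])", response, re.IGNORECASE)
        if m and (best is None or m.start() < best[0]):
            best = (m.start(), str(label))
    return best[1] if best else None


# ---------------------------------------------------------------------------
# Adapters


class ModelAdapter:
    """Contract: one stateless call per item.

    Real adapters use only the prompt. The bundled mocks also receive the
    item and active condition out of band, which a prompt string cannot
    carry without fragile re-parsing; session isolation is preserved since
    nothing persists between calls.
    """

    name = "adapter"

    def complete(self, prompt: str, *, item: EvalItem | None = None, condition=None) -> str:
        raise NotImplementedError


class OracleAdapter(ModelAdapter):
    """Always answers the gold label/answer (upper performance bound)."""

    name = "oracle"

    def complete(self, prompt, *, item=None, condition=None):
        if item.task == "qa":  # free-text answers are scored verbatim
            return item.gold
        return f"{item.gold}. Justification: matches the reference."


class AdversarialAdapter(ModelAdapter):
    """Never answers correctly (lower performance bound)."""

    name = "adversarial"

    def complete(self, prompt, *, item=None, condition=None):
        labels = TASK_LABELS.get(item.task)
        if labels:
            wrong = next(l for l in labels if l != item.gold)
            return f"{wrong}. Justification: none."
        return "qqz wrx vvk"  # tokens disjoint from any fixture answer


class NoisyChannelAdapter(ModelAdapter):
    """Degrades a base accuracy by a programmed relative amount per condition.

    For a condition with target accuracy a, the adapter answers the i-th item
    of that condition correctly iff the running number of correct answers is
    below round(a * i): after n items exactly round(a * n) are correct, so the
    realised relative change matches the programmed one up to rounding rather
    than fluctuating binomially.
    """

    name = "noisy-channel"

    def __init__(
        self,
        base_accuracy: float = 0.80,
        degradation: dict | None = None,
        seed: int = 0,
    ):
        if not 0 < base_accuracy <= 1:
            raise ConfigError("base_accuracy must be in (0, 1]")
        self.base_accuracy = base_accuracy
        self.degradation = degradation or {}
        self.seed = seed
        self._seen: dict = {}
        self._correct: dict = {}

    def _target_accuracy(self, condition) -> float:
        delta = 0.0
        if condition is not None:
            ptype, level = condition
            if ptype != "original":
                delta = self.degradation.get((ptype, level), self.degradation.get(ptype, 0.0))
        return min(1.0, max(0.0, self.base_accuracy * (1.0 + delta)))

    def complete(self, prompt, *, item=None, condition=None):
        acc = self._target_accuracy(condition)
        key = (item.task, condition)
        n = self._seen.get(key, 0) + 1
        self._seen[key] = n
        want = round_half_up(acc * n)
        if self._correct.get(key, 0) < want:
            self._correct[key] = self._correct.get(key, 0) + 1
            if item.task == "qa":
                return item.gold
            return f"{item.gold}. Justification: consistent with the input."
        labels = TASK_LABELS.get(item.task)
        if labels:
            wrong = next(l for l in labels if l != item.gold)
            return f"{wrong}. Justification: uncertain."
        return "qqz wrx vvk"


class KeywordClassifierAdapter(ModelAdapter):
    """Labels by keyword lookup in the (possibly perturbed) input text."""

    name = "keyword"

    def __init__(self, label_keywords: dict[str, Iterable[str]], fallback: str):
        self.label_keywords = {lab: frozenset(w.lower() for w in ws) for lab, ws in label_keywords.items()}
        self.fallback = fallback

    def complete(self, prompt, *, item=None, condition=None):
        tokens = set(re.findall(r"[a-z’']+", item.text.lower()))
        for lab in sorted(self.label_keywords):
            if tokens & self.label_keywords[lab]:
                return f"{lab}. Justification: keyword match."
        return f"{self.fallback}. Justification: no keyword found."


class ExtractiveAnswerAdapter(ModelAdapter):
    """Extracts the clause after a cue verb from the note (QA fixtures)."""

    name = "extractive"

    def __init__(self, cue: str = "showed"):
        self.cue = cue

    def complete(self, prompt, *, item=None, condition=None):
        m = re.search(rf"\b{re.escape(self.cue)}\b\s+(.+?)(?:[.?!]|$)", item.text, re.IGNORECASE)
        return m.group(1).strip() if m else ""


class HTTPChatAdapter(ModelAdapter):
    """Generic chat-completion client (OpenAI-compatible JSON shape).

    Credentials come from an environment variable, never from config files.
    """

    def __init__(
        self,
        endpoint: str,
        model: str,
        api_key_env: str = "PERTURBKIT_API_KEY",
        temperature: float = 0.0,
        timeout: float = 60.0,
    ):
        self.endpoint = endpoint
        self.model = model
        self.name = model
        self.api_key_env = api_key_env
        self.temperature = temperature
        self.timeout = timeout

    def complete(self, prompt, *, item=None, condition=None):
        payload = {
            "model": self.model,
            "messages": [{"role": "user", "content": prompt}],
            "temperature": self.temperature,
        }
        headers = {"Content-Type": "application/json"}
        key = os.environ.get(self.api_key_env)
        if key:
            headers["Authorization"] = f"Bearer {key}"
        req = urllib.request.Request(
            self.endpoint, data=json.dumps(payload).encode(), headers=headers
        )
        try:
            with urllib.request.urlopen(req, timeout=self.timeout) as resp:
                body = json.load(resp)
            return body["choices"][0]["message"]["content"]
        except (urllib.error.URLError, OSError, KeyError, ValueError) as exc:
            raise AdapterError(f"chat completion failed: {exc}") from exc


ADAPTERS = {
    "oracle": OracleAdapter,
    "adversarial": AdversarialAdapter,
    "noisy-channel": NoisyChannelAdapter,
    "keyword": KeywordClassifierAdapter,
    "extractive": ExtractiveAnswerAdapter,
    "http-chat": HTTPChatAdapter,
}


def make_adapter(name: str, **settings) -> ModelAdapter:
    if name not in ADAPTERS:
        raise ConfigError(f"unknown adapter {name!r}; built-ins: {sorted(ADAPTERS)}")
    return ADAPTERS[name](**settings)


# ---------------------------------------------------------------------------
# Condition execution


@dataclass(frozen=True)
class ConditionResult:
    task: str
    model: str
    ptype: str
    level: float | None
    metric: str
    value: float
    n_items: int

    def __post_init__(self):
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(f"metric value out of [0,1]: {self.value}")
        if self.n_items <= 0:
            raise ValueError("n_items must be positive")


def run_condition(
    items: Sequence[EvalItem],
    adapter: ModelAdapter,
    template: PromptTemplate,
    model_name: str | None = None,
    embedding_scorer: Callable[[str, str], float] | None = None,
) -> tuple[list[ConditionResult], list[dict]]:
    """Evaluate one homogeneous (task, ptype, level) slice, one call per item.

    Per-item adapter failures are recorded; the condition itself fails only
    when every item fails. Raw responses are returned for audit.
    """
    if not items:
        raise ConfigError("empty condition slice")
    task, ptype, level = items[0].task, items[0].ptype, items[0].level
    if any((it.task, it.ptype, it.level) != (task, ptype, level) for it in items):
        raise ConfigError("condition slice must be homogeneous in (task, ptype, level)")
    model_name = model_name or adapter.name
    raw: list[dict] = []
    ok_items: list[tuple[EvalItem, str]] = []
    for it in items:
        prompt = build_prompt(template, it)
        try:
            response = adapter.complete(prompt, item=it, condition=(ptype, level))
        except AdapterError as exc:
            raw.append({"id": it.record_id, "error": str(exc)})
            continue
        raw.append({"id": it.record_id, "response": response})
        ok_items.append((it, response))
    if not ok_items:
        raise AdapterError(f"all {len(items)} items failed for condition {(task, ptype, level)}")

    results: list[ConditionResult] = []
    n = len(ok_items)
    if task == "qa":
        per_metric: dict[str, list[float]] = {}
        for it, resp in ok_items:
            scores = score_qa(resp, it.gold, embedding_scorer=embedding_scorer)
            for m, v in scores.items():
                per_metric.setdefault(m, []).append(v)
        for m, vals in per_metric.items():
            results.append(ConditionResult(task, model_name, ptype, level, m, fmean(vals), n))
    else:
        labels = TASK_LABELS[task]
        preds = [parse_classification_response(resp, labels) for _, resp in ok_items]
        golds = [it.gold for it, _ in ok_items]
        scores = score_classification(preds, golds, labels)
        for m in CLASSIFICATION_METRICS:
            results.append(ConditionResult(task, model_name, ptype, level, m, scores[m], n))
    return results, raw


def corpus_conditions(entries: Sequence[CorpusEntry]) -> dict[tuple[str, float | None], list[EvalItem]]:
    """Group a perturbed corpus into homogeneous condition slices (incl. original)."""
    slices: dict[tuple[str, float | None], list[EvalItem]] = {}
    for entry in entries:
        rec = entry.record
        slices.setdefault(("original", None), []).append(
            EvalItem(rec.record_id, rec.task, rec.text, rec.gold, rec.question)
        )
        for (ptype, level), ex in sorted(entry.variants.items()):
            slices.setdefault((ptype, level), []).append(
                EvalItem(rec.record_id, rec.task, ex.perturbed, rec.gold, rec.question, ptype, level)
            )
    return slices


def evaluate_corpus(
    entries: Sequence[CorpusEntry],
    adapter: ModelAdapter,
    template: PromptTemplate,
    model_name: str | None = None,
    embedding_scorer: Callable[[str, str], float] | None = None,
) -> pd.DataFrame:
    """Run every condition of a single-task corpus; results in long form.

    Columns: task, model, ptype, level, metric, value, n_items.
    """
    rows = []
    for (ptype, level), items in corpus_conditions(entries).items():
        results, _ = run_condition(
            items, adapter, template, model_name=model_name, embedding_scorer=embedding_scorer
        )
        rows.extend(r.__dict__ for r in results)
    return pd.DataFrame(rows)
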
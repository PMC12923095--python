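"""Evaluation metrics: classification scores, ROUGE-L, BLEU.

Classification tasks get accuracy plus macro-averaged precision/recall/F1
(computed with scikit-learn). Question answering gets n-gram overlap
measures computed over lowercased whitespace tokens:

* ROUGE-L — F-measure of the longest common subsequence between candidate
  and reference (the analysis metric for QA conditions).
* BLEU — up to 4-gram modified precision with brevity penalty; higher-order
  precisions are add-one smoothed so short clinical answers do not
  degenerate to zero.

A semantic-similarity scorer (e.g. an embedding-based one) can be injected
into :func:`score_qa`; the core has no neural dependency.
"""

from __future__ import annotations

import math
from collections import Counter
from typing import Callable, Sequence

from sklearn.metrics import accuracy_score, precision_recall_fscore_support


def _tokens(text: str) -> list[str]:
    return text.lower().split()


def lcs_length(a: Sequence[str], b: Sequence[str]) -> int:
    """Length of the longest common subsequence (dynamic programming)."""
    if not a or not b:
        return 0
    prev = [0] * (len(b) + 1)
    for x in a:
        cur = [0]
        for j, y in enumerate(b, 1):
            cur.append(prev[j - 1] + 1 if x == y else max(prev[j], cur[j - 1]))
        prev = cur
    return prev[-1]


def rouge_l(candidate: str, reference: str) -> dict[str, float]:
    """ROUGE-L precision, recall and F1 over lowercased word tokens."""
    c, r = _tokens(candidate), _tokens(reference)
    if not c or not r:
        return {"precision": 0.0, "recall": 0.0, "f1": 0.0}
    lcs = lcs_length(c, r)
    p, rec = lcs / len(c), lcs / len(r)
    f1 = 0.0 if p + rec == 0 else 2 * p * rec / (p + rec)
    return {"precision": p, "recall": rec, "f1": f1}


def bleu(candidate: str, reference: str, max_n: int = 4) -> float:
    """Sentence BLEU with add-one smoothing on higher-order precisions."""
    c, r = _tokens(candidate), _tokens(reference)
    if not c:
        return 0.0
    log_precisions = []
    for n in range(1, max_n + 1):
        cand_ngrams = Counter(tuple(c[i : i + n]) for i in range(len(c) - n + 1))
        ref_ngrams = Counter(tuple(r[i : i + n]) for i in range(len(r) - n + 1))
        overlap = sum(min(cnt, ref_ngrams[g]) for g, cnt in cand_ngrams.items())
        total = max(sum(cand_ngrams.values()), 0)
        if n == 1:
            if overlap == 0 or total == 0:
                return 0.0
            p = overlap / total
        else:
            # add-one smoothing keeps short answers off the zero floor
            p = (overlap + 1) / (total + 1)
        log_precisions.append(math.log(p))
    bp = 1.0 if len(c) >= len(r) else math.exp(1 - len(r) / max(len(c), 1))
    return bp * math.exp(sum(log_precisions) / max_n)


def score_classification(
    predictions: Sequence[str | None],
    golds: Sequence[str],
    label_set: Sequence[str],
) -> dict[str, float]:
    """Accuracy plus macro precision/recall/F1; per-class F1 under ``f1_<label>``.

    Unparseable predictions (None) count as a dedicated wrong class, so they
    hurt accuracy and recall but never silently drop out of the denominator.
    """
    if len(predictions) != len(golds):
        raise ValueError("predictions and golds must be aligned")
    if not golds:
        raise ValueError("cannot score an empty batch")
    labels = [str(l) for l in label_set]
    preds = [p if p is not None else "<unparseable>" for p in predictions]
    acc = accuracy_score(golds, preds)
    prec, rec, f1, _ = precision_recall_fscore_support(
        golds, preds, labels=labels, average="macro", zero_division=0
    )
    out = {"accuracy": float(acc), "precision": float(prec), "recall": float(rec), "f1": float(f1)}
    p_c, r_c, f_c, _ = precision_recall_fscore_support(
        golds, preds, labels=labels, average=None, zero_division=0
    )
    for lab, f in zip(labels, f_c):
        out[f"f1_{lab}"] = float(f)
    return out


def score_qa(
    candidate: str,
    reference: str,
    embedding_scorer: Callable[[str, str], float] | None = None,
) -> dict[str, float]:
    """BLEU and ROUGE-L F for one answer; semantic score only when injected."""
    if not reference.strip():
        raise ValueError("reference answer must be non-empty")
    out = {"bleu": bleu(candidate, reference), "rouge": rouge_l(candidate, reference)["f1"]}
    if embedding_scorer is not None:
        out["bertscore"] = float(embedding_scorer(candidate, reference))
    return out
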
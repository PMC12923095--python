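"""Word-level perturbation engine: typos, homophone swaps, redaction.

The engine mimics how humans degrade health-related text. A perturbation is
budgeted in *words*: a level of 0.10 on a 10-word sentence perturbs
``round(0.10 * 10) = 1`` word, drawn only from "valid" words — adjectives,
adverbs, verbs and nouns. A sentence of 10 words with 5 valid words at the
10% level therefore has 1 of its 5 valid words (20% of them) perturbed.
Typo intensity inside a chosen word is separately governed by
``letter_fraction_range``: 20–50% of the word's letters (at least one) are
hit by a single operator — insertion, deletion, substitution or adjacent
transposition.

Everything is reproducible: one seeded generator per example, derived from
(global seed, example id), so corpus-level runs are order-independent.
"""

from __future__ import annotations

import re
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import BudgetInfeasibleError, DegenerateInputError
from .homophones import HomophoneProvider
from .tagging import DEFAULT_VALID_POS, RuleBasedTagger, Tagger, default_tagger, is_medical

PTYPES = ("typographical", "homophone", "redaction")
TYPO_OPS = ("typo_insert", "typo_delete", "typo_substitute", "typo_transpose")
_ALPHABET = "abcdefghijklmnopqrstuvwxyz"
_WORD_CHARS = re.compile(r"[0-9A-Za-z]")


def round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5 + 1e-9))


def derive_seed(global_seed: int, example_id: object | None) -> int:
    """Stable per-example seed below 2**31, order-independent across a corpus."""
    if example_id is None:
        return int(global_seed) % (2**31)
    key = f"{global_seed}:{example_id}".encode("utf-8")
    return zlib.crc32(key) & 0x7FFFFFFF


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(int(seed_or_rng))


@dataclass(frozen=True)
class PerturbationSpec:
    """Parameters governing one perturbation run.

    level is the fraction of *total* words to perturb (the 10/20/30/50%
    grids); letter_fraction_range bounds the per-word typo intensity.
    """

    ptype: str
    level: float
    seed: int = 0
    letter_fraction_range: tuple[float, float] = (0.20, 0.50)
    valid_pos: frozenset[str] = DEFAULT_VALID_POS

    def __post_init__(self):
        if self.ptype not in PTYPES:
            raise ValueError(f"unknown perturbation type {self.ptype!r}")
        if not (0.0 < self.level <= 1.0):
            raise ValueError(f"level must be in (0, 1], got {self.level}")
        lo, hi = self.letter_fraction_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"letter_fraction_range must be ordered within [0,1], got {lo, hi}")
        if not self.valid_pos:
            raise ValueError("valid_pos must be non-empty")
        object.__setattr__(self, "valid_pos", frozenset(self.valid_pos))


@dataclass(frozen=True)
class TokenAnnotation:
    """One word token: text, half-open character span, POS, eligibility flags."""

    text: str
    start: int
    end: int
    pos: str
    is_valid: bool
    is_medical: bool


@dataclass(frozen=True)
class Edit:
    """One recorded perturbation of one token."""

    token_index: int
    operation: str
    before: str
    after: str
    is_medical: bool = False


@dataclass
class PerturbedExample:
    original: str
    perturbed: str
    spec: PerturbationSpec
    edits: list[Edit] = field(default_factory=list)
    target_count: int = 0

    @property
    def medical_edit_ratio(self) -> float:
        """Fraction of perturbed words that are medical terms."""
        if not self.edits:
            raise ZeroDivisionError("example has no perturbed tokens")
        return sum(e.is_medical for e in self.edits) / len(self.edits)


def tokenize(text: str) -> list[tuple[str, int, int]]:
    """Word tokens with 0-based half-open spans.

    Whitespace-delimited chunks with leading/trailing punctuation peeled off;
    internal apostrophes and hyphens stay inside the word ("patient’s").
    """
    tokens = []
    for m in re.finditer(r"\S+", text):
        chunk, start = m.group(), m.start()
        lo, hi = 0, len(chunk)
        while lo < hi and not _WORD_CHARS.match(chunk[lo]):
            lo += 1
        while hi > lo and not _WORD_CHARS.match(chunk[hi - 1]):
            hi -= 1
        if hi > lo:
            tokens.append((chunk[lo:hi], start + lo, start + hi))
    return tokens


def annotate_tokens(
    text: str,
    lexicon: Iterable[str] = (),
    tagger: Tagger | None = None,
    valid_pos: Iterable[str] = DEFAULT_VALID_POS,
) -> list[TokenAnnotation]:
    """Tokenize and annotate every word token with POS and eligibility flags."""
    if not text or not text.strip():
        raise DegenerateInputError("cannot annotate empty or whitespace-only text")
    tagger = tagger or default_tagger()
    valid = frozenset(valid_pos)
    lex = frozenset(w.lower() for w in lexicon)
    out = []
    for tok, start, end in tokenize(text):
        pos = tagger(tok)
        out.append(
            TokenAnnotation(
                text=tok,
                start=start,
                end=end,
                pos=pos,
                is_valid=pos in valid,
                is_medical=is_medical(tok, lex),
            )
        )
    return out


def compute_target_count(n_total_words: int, n_valid_words: int, level: float) -> int:
    """Number of words to perturb: round-half-up of level × total words, floor 1.

    Raises :class:`BudgetInfeasibleError` when the budget exceeds the number
    of valid words — the signal the corpus retention rule consumes.
    """
    if level <= 0:
        raise ValueError(f"level must be positive, got {level}")
    if n_valid_words > n_total_words:
        raise ValueError("n_valid_words cannot exceed n_total_words")
    target = max(1, round_half_up(level * n_total_words))
    if target > n_valid_words:
        raise BudgetInfeasibleError(required=target, available=n_valid_words)
    return target


def select_words(
    annotations: Sequence[TokenAnnotation], target_count: int, seed
) -> list[int]:
    """Uniform sample without replacement among valid-token indices (sorted)."""
    valid_idx = [i for i, a in enumerate(annotations) if a.is_valid]
    if target_count > len(valid_idx):
        raise BudgetInfeasibleError(required=target_count, available=len(valid_idx))
    rng = _rng(seed)
    chosen = rng.choice(len(valid_idx), size=target_count, replace=False)
    return sorted(valid_idx[i] for i in chosen)


def _random_letter(rng: np.random.Generator, exclude: str = "") -> str:
    pool = [c for c in _ALPHABET if c != exclude.lower()]
    return pool[int(rng.integers(0, len(pool)))]


def apply_typo_detail(word: str, letter_fraction_range=(0.20, 0.50), seed=0) -> tuple[str, str]:
    """Typo a word; returns (perturbed word, operator name).

    One operator, drawn uniformly, is applied at k letter positions where
    k = round(u · len(word)) with u uniform in letter_fraction_range (k ≥ 1).
    The output always differs from the input; untouched letters keep case.
    """
    if len(word) < 1:
        raise ValueError("word must have length >= 1")
    rng = _rng(seed)
    ops = list(TYPO_OPS)
    if len(word) == 1:
        # deletion would empty the word and transposition is impossible
        ops = ["typo_insert", "typo_substitute"]
    op = ops[int(rng.integers(0, len(ops)))]
    lo, hi = letter_fraction_range
    u = float(rng.uniform(lo, hi))
    k = max(1, round_half_up(u * len(word)))
    chars = list(word)
    if op == "typo_insert":
        for _ in range(k):
            pos = int(rng.integers(0, len(chars) + 1))
            chars.insert(pos, _random_letter(rng))
    elif op == "typo_delete":
        k = min(k, len(chars) - 1)
        for pos in sorted(rng.choice(len(chars), size=k, replace=False), reverse=True):
            del chars[int(pos)]
    elif op == "typo_substitute":
        k = min(k, len(chars))
        for pos in rng.choice(len(chars), size=k, replace=False):
            chars[int(pos)] = _random_letter(rng, exclude=chars[int(pos)])
    else:  # typo_transpose: adjacent swaps
        k = min(k, len(chars) - 1)
        for pos in sorted(rng.choice(len(chars) - 1, size=k, replace=False)):
            p = int(pos)
            chars[p], chars[p + 1] = chars[p + 1], chars[p]
    out = "".join(chars)
    if out == word:  # e.g. transposing equal letters; force a visible change
        pos = int(rng.integers(0, len(word)))
        chars = list(word)
        chars[pos] = _random_letter(rng, exclude=chars[pos])
        out = "".join(chars)
        op = "typo_substitute"
    return out, op


def apply_typo(word: str, letter_fraction_range=(0.20, 0.50), seed=0) -> str:
    return apply_typo_detail(word, letter_fraction_range, seed)[0]


def apply_homophone(word: str, provider: HomophoneProvider) -> str | None:
    """First homophone of ``word`` that differs in spelling, case-adapted.

    Returns None when the provider knows no homophone; the caller reselects
    another valid word or marks the budget infeasible.
    """
    for cand in provider.lookup(word):
        if cand.lower() != word.lower():
            if word[:1].isupper():
                cand = cand[:1].upper() + cand[1:]
            return cand
    return None


def apply_redaction(
    text: str, annotations: Sequence[TokenAnnotation], indices: Iterable[int]
) -> str:
    """Remove the word tokens at ``indices``; collapse whitespace, keep punctuation."""
    drop = sorted(set(indices), reverse=True)
    s = text
    for i in drop:
        a = annotations[i]
        s = s[: a.start] + s[a.end :]
    s = re.sub(r"\s+", " ", s).strip()
    s = re.sub(r"\s+([,.;:!?)\]])", r"\1", s)
    return s


def _splice(text: str, replacements: list[tuple[int, int, str]]) -> str:
    """Replace (start, end) spans with strings; spans must be disjoint."""
    out, cursor = [], 0
    for start, end, repl in sorted(replacements):
        out.append(text[cursor:start])
        out.append(repl)
        cursor = end
    out.append(text[cursor:])
    return "".join(out)


def apply_edits(
    text: str, annotations: Sequence[TokenAnnotation], edits: Sequence[Edit], ptype: str
) -> str:
    """Deterministically re-apply recorded edits to the original text."""
    if ptype == "redaction":
        return apply_redaction(text, annotations, [e.token_index for e in edits])
    repl = []
    for e in edits:
        a = annotations[e.token_index]
        repl.append((a.start, a.end, e.after))
    return _splice(text, repl)


def perturb_example(
    text: str,
    spec: PerturbationSpec,
    provider: HomophoneProvider | None = None,
    lexicon: Iterable[str] = (),
    tagger: Tagger | None = None,
    example_id: object | None = None,
) -> PerturbedExample:
    """Perturb one text under ``spec``; fully determined by (text, spec, provider).

    Raises :class:`BudgetInfeasibleError` when the level's word budget cannot
    be met (too few valid words, or too few homophone-bearing valid words).
    """
    annotations = annotate_tokens(text, lexicon=lexicon, tagger=tagger, valid_pos=spec.valid_pos)
    n_total = len(annotations)
    n_valid = sum(a.is_valid for a in annotations)
    target = compute_target_count(n_total, n_valid, spec.level)
    rng = _rng(derive_seed(spec.seed, example_id))

    edits: list[Edit] = []
    if spec.ptype == "homophone":
        if provider is None:
            raise ValueError("homophone perturbation requires a provider")
        valid_idx = [i for i, a in enumerate(annotations) if a.is_valid]
        order = [valid_idx[int(j)] for j in rng.permutation(len(valid_idx))]
        swaps: list[tuple[int, str]] = []
        for i in order:  # reselect past words with no homophone
            after = apply_homophone(annotations[i].text, provider)
            if after is not None:
                swaps.append((i, after))
            if len(swaps) == target:
                break
        if len(swaps) < target:
            raise BudgetInfeasibleError(
                required=target, available=len(swaps), detail="valid words with homophones"
            )
        for i, after in sorted(swaps):
            a = annotations[i]
            edits.append(Edit(i, "homophone_swap", a.text, after, a.is_medical))
    else:
        chosen = select_words(annotations, target, rng)
        for i in chosen:
            a = annotations[i]
            if spec.ptype == "typographical":
                after, op = apply_typo_detail(a.text, spec.letter_fraction_range, rng)
                edits.append(Edit(i, op, a.text, after, a.is_medical))
            else:
                edits.append(Edit(i, "redact", a.text, "", a.is_medical))

    perturbed = apply_edits(text, annotations, edits, spec.ptype)
    return PerturbedExample(
        original=text, perturbed=perturbed, spec=spec, edits=edits, target_count=target
    )
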
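"""Homophone providers.

A homophone provider answers "what sounds like this word?" with an ordered
candidate list. Two implementations share the contract:

* :class:`DictionaryProvider` — a versioned static two-column TSV bundled
  with the package (word, pipe-separated homophones). Fully offline and
  deterministic; the one used in tests.
* :class:`DatamuseProvider` — a sounds-like HTTP lookup against a
  Datamuse-style endpoint. Network failures raise :class:`ProviderError`;
  there is no silent fallback.
"""

from __future__ import annotations

import importlib.resources
import json
import urllib.error
import urllib.parse
import urllib.request
from typing import Protocol, Sequence

from .errors import ProviderError


class HomophoneProvider(Protocol):
    """word -> ordered homophone candidates (possibly empty)."""

    version: str

    def lookup(self, word: str) -> Sequence[str]: ...


class DictionaryProvider:
    """Static homophone dictionary read from a two-column TSV."""

    def __init__(self, path: str | None = None, version: str | None = None):
        if path is None:
            text = (
                importlib.resources.files("perturbkit.data")
                .joinpath("homophones.tsv")
                .read_text("utf-8")
            )
            self.version = version or "bundled-1"
        else:
            with open(path, encoding="utf-8") as fh:
                text = fh.read()
            self.version = version or f"file:{path}"
        self._table: dict[str, tuple[str, ...]] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            word, cands = line.split("\t")
            self._table[word.lower()] = tuple(c for c in cands.split("|") if c)

    def lookup(self, word: str) -> Sequence[str]:
        return self._table.get(word.lower(), ())

    def words_with_homophones(self) -> frozenset[str]:
        return frozenset(self._table)


class DatamuseProvider:
    """Sounds-like lookup against a Datamuse-style REST endpoint.

    Results are perfect-score sound matches only, ordered as returned by the
    service. Requires network access; use :class:`DictionaryProvider` for
    reproducible offline runs.
    """

    def __init__(self, endpoint: str = "https://api.datamuse.com/words", timeout: float = 10.0):
        self.endpoint = endpoint
        self.timeout = timeout
        self.version = f"datamuse:{endpoint}"

    def lookup(self, word: str) -> Sequence[str]:
        query = urllib.parse.urlencode({"sl": word, "max": 20})
        url = f"{self.endpoint}?{query}"
        try:
            with urllib.request.urlopen(url, timeout=self.timeout) as resp:
                payload = json.load(resp)
        except (urllib.error.URLError, OSError, ValueError) as exc:
            raise ProviderError(f"homophone lookup failed for {word!r}: {exc}") from exc
        out = []
        for entry in payload:
            cand = entry.get("word", "")
            # perfect sounds-like matches score 100 on Datamuse
            if cand and entry.get("score", 0) >= 100 and cand.lower() != word.lower():
                out.append(cand)
        return tuple(out)
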
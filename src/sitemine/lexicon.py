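"""Keyword dictionaries, lemma spotting, and semantic-similarity filtering.

Two keyword families drive the rule-based filters.  *PPI+ive* lemmas (stem
words such as ``bind``, ``interfac``, ``pocket``) signal that a sentence
talks about the protein-protein binding site; *PPI-ive* lemmas
(``phosphory``, ``epitope``, ``IgG1`` ...) signal interaction-adjacent but
site-irrelevant content.  The packaged default dictionary has 16 positive
and 36 negative lemmas.

The semantic-similarity route compares every word of a residue-containing
sentence against generic concept words (default ``touch`` and ``site``)
with one of three measures — gloss overlap (Lesk), information content
(Lin), or inverse path length (Path) — and keeps the sentence's residues
when any score strictly exceeds the measure's threshold (20, 0.2 and 0.11
respectively).  A small deterministic synset forest ships with the package
so all three measures run offline; any provider implementing
``score(word, concept, measure)`` can be substituted.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Protocol, Sequence

from .textcorpus import Sentence

__all__ = [
    "KeywordDictionary",
    "SimilarityThresholds",
    "SimilarityProvider",
    "FixtureSimilarityProvider",
    "load_dictionary",
    "default_dictionary",
    "default_provider",
    "lemma_matches",
    "spot_keywords",
    "dictionary_filter",
    "similarity_filter",
    "DEFAULT_CONCEPT_WORDS",
]

#: Generic concept words standing in for the notion "binding site".
DEFAULT_CONCEPT_WORDS = ("touch", "site")


@dataclass(frozen=True)
class SimilarityThresholds:
    """Strict lower bounds for the three similarity measures."""

    lesk: float = 20.0
    lin: float = 0.2
    path: float = 0.11

    def __post_init__(self):
        if min(self.lesk, self.lin, self.path) <= 0:
            raise ValueError("thresholds must be positive")

    def for_measure(self, measure: str) -> float:
        try:
            return getattr(self, measure)
        except AttributeError:
            raise ValueError(f"unknown measure: {measure!r}") from None


@dataclass(frozen=True)
class KeywordDictionary:
    """PPI+ive / PPI-ive lemma lists.

    Lemmas are stems: lower-case lemmas of length >= 4 match any token that
    starts with them (case-insensitively), while short (<= 3 characters) or
    mixed-case lemmas (``Fc``, ``IgG1``, ``dCTP``) require an exact,
    case-sensitive whole-token match.
    """

    ppi_positive: tuple[str, ...]
    ppi_negative: tuple[str, ...]
    name: str = "custom"

    def __post_init__(self):
        overlap = set(self.ppi_positive) & set(self.ppi_negative)
        if overlap:
            raise ValueError(f"lemmas in both sections: {sorted(overlap)}")

    def with_positive(self, lemma: str) -> "KeywordDictionary":
        return KeywordDictionary(self.ppi_positive + (lemma,),
                                 self.ppi_negative, self.name)


def lemma_matches(lemma: str, token: str) -> bool:
    """The lemma-matching rule shared by every keyword-based filter.

    Stems (all-lowercase, length >= 4) match as case-insensitive prefixes
    anchored at the token start; everything else (short forms, mixed-case
    forms) must match the whole token case-sensitively.
    """
    if len(lemma) >= 4 and lemma == lemma.lower():
        return token.lower().startswith(lemma)
    return token == lemma


def spot_keywords(
    sentence: Sentence | Sequence[str], lemmas: Iterable[str]
) -> list[tuple[int, str]]:
    """All (token_index, lemma) matches in token order."""
    tokens = sentence.tokens if isinstance(sentence, Sentence) else list(sentence)
    hits = []
    for i, tok in enumerate(tokens):
        for lemma in lemmas:
            if lemma_matches(lemma, tok):
                hits.append((i, lemma))
    hits.sort(key=lambda h: h[0])
    return hits


def dictionary_filter(sentence: Sentence, dictionary: KeywordDictionary) -> bool:
    """Keep (True) iff at least one PPI+ive lemma is spotted in the sentence.

    Negative lemmas play no role in this method; they matter only for
    parse-tree scoring.
    """
    return bool(spot_keywords(sentence, dictionary.ppi_positive))


# ---------------------------------------------------------------------------
# Dictionary file I/O
# ---------------------------------------------------------------------------

def load_dictionary(stream, name: str = "custom") -> KeywordDictionary:
    """Read a two-section ``[positive]`` / ``[negative]`` dictionary file."""
    section = None
    pos: list[str] = []
    neg: list[str] = []
    for raw in stream:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.lower() == "[positive]":
            section = pos
        elif line.lower() == "[negative]":
            section = neg
        elif section is None:
            raise ValueError(f"lemma before any section header: {line!r}")
        else:
            section.append(line)
    return KeywordDictionary(tuple(pos), tuple(neg), name=name)


def default_dictionary() -> KeywordDictionary:
    """The packaged binding-site dictionary (16 PPI+ive, 36 PPI-ive lemmas)."""
    text = resources.files("sitemine.data").joinpath("ppi_dictionary.txt").read_text()
    return load_dictionary(text.splitlines(), name="binding-site")


# ---------------------------------------------------------------------------
# Semantic similarity
# ---------------------------------------------------------------------------

class SimilarityProvider(Protocol):
    def score(self, word: str, concept_word: str, measure: str) -> float | None:
        """Similarity between two words, or None when undefined/out-of-lexicon."""


class FixtureSimilarityProvider:
    """Deterministic similarity scorer over a small packaged synset forest.

    The lexicon is a forest of hypernym trees; each synset carries words, a
    gloss and a corpus count.  Measures:

    ``path``
        ``1 / (1 + d)`` with ``d`` the edge count of the shortest path
        through a common ancestor; undefined across different trees.
    ``lin``
        ``2*IC(lcs) / (IC(a) + IC(b))`` with information content
        ``IC = -ln(cumulative_count / total)``; undefined without a common
        subsumer.
    ``lesk``
        Gloss-overlap: sum of squared lengths of maximal shared token
        phrases between the two synsets' expanded glosses (own gloss plus
        hypernym and direct-hyponym glosses).

    Word-level scores maximize over all synset pairs containing the words.
    """

    def __init__(self, lexicon: dict | None = None):
        if lexicon is None:
            raw = resources.files("sitemine.data").joinpath(
                "fixture_lexicon.json").read_text()
            lexicon = json.loads(raw)
        self._synsets = {s["id"]: s for s in lexicon["synsets"]}
        self._word_index: dict[str, list[str]] = {}
        for s in lexicon["synsets"]:
            for w in s["words"]:
                self._word_index.setdefault(w.lower(), []).append(s["id"])
        self._children: dict[str, list[str]] = {sid: [] for sid in self._synsets}
        for s in lexicon["synsets"]:
            if s["hypernym"] is not None:
                self._children[s["hypernym"]].append(s["id"])
        self._cum = {sid: self._cumulative_count(sid) for sid in self._synsets}
        self._total = sum(s["count"] for s in self._synsets.values())

    # -- graph helpers ------------------------------------------------------

    def _ancestors(self, sid: str) -> dict[str, int]:
        """Ancestor id -> upward edge distance (self included at 0)."""
        out, d = {}, 0
        node: str | None = sid
        while node is not None:
            out[node] = d
            node = self._synsets[node]["hypernym"]
            d += 1
        return out

    def _cumulative_count(self, sid: str) -> int:
        total = self._synsets[sid]["count"]
        for child in self._children[sid]:
            total += self._cumulative_count(child)
        return total

    def _ic(self, sid: str) -> float:
        return -math.log(self._cum[sid] / self._total)

    def _expanded_gloss(self, sid: str) -> list[str]:
        parts = [self._synsets[sid]["gloss"]]
        hyper = self._synsets[sid]["hypernym"]
        if hyper is not None:
            parts.append(self._synsets[hyper]["gloss"])
        parts.extend(self._synsets[c]["gloss"] for c in self._children[sid])
        tokens: list[str] = []
        for i, p in enumerate(parts):
            if i:
                tokens.append(f"<sep{i}>")  # phrases never span gloss boundaries
            tokens.extend(re.findall(r"[a-z]+", p.lower()))
        return tokens

    # -- synset-pair scores -------------------------------------------------

    def _path(self, a: str, b: str) -> float | None:
        anc_a, anc_b = self._ancestors(a), self._ancestors(b)
        common = anc_a.keys() & anc_b.keys()
        if not common:
            return None
        d = min(anc_a[c] + anc_b[c] for c in common)
        return 1.0 / (1.0 + d)

    def _lin(self, a: str, b: str) -> float | None:
        anc_a, anc_b = self._ancestors(a), self._ancestors(b)
        common = anc_a.keys() & anc_b.keys()
        if not common:
            return None
        lcs = min(common, key=lambda c: anc_a[c] + anc_b[c])
        denom = self._ic(a) + self._ic(b)
        if denom == 0:
            return None
        return 2.0 * self._ic(lcs) / denom

    def _lesk(self, a: str, b: str) -> float:
        ga, gb = self._expanded_gloss(a), self._expanded_gloss(b)
        return float(_phrase_overlap(ga, gb))

    def score(self, word: str, concept_word: str, measure: str) -> float | None:
        syn_a = self._word_index.get(word.lower())
        syn_b = self._word_index.get(concept_word.lower())
        if not syn_a or not syn_b:
            return None
        fn = {"path": self._path, "lin": self._lin, "lesk": self._lesk}.get(measure)
        if fn is None:
            raise ValueError(f"unknown measure: {measure!r}")
        scores = [s for a in syn_a for b in syn_b if (s := fn(a, b)) is not None]
        return max(scores) if scores else None

    @property
    def words(self) -> frozenset[str]:
        return frozenset(self._word_index)


def _phrase_overlap(a: list[str], b: list[str]) -> int:
    """Greedy maximal-shared-phrase score: repeatedly remove the longest
    common contiguous token run, adding length**2 each time."""
    a, b = list(a), list(b)
    score = 0
    while True:
        best_len, best = 0, None
        # O(n*m) longest-common-substring by dynamic programming
        prev = [0] * (len(b) + 1)
        for i in range(1, len(a) + 1):
            cur = [0] * (len(b) + 1)
            for j in range(1, len(b) + 1):
                if a[i - 1] == b[j - 1] and a[i - 1] is not None:
                    cur[j] = prev[j - 1] + 1
                    if cur[j] > best_len:
                        best_len, best = cur[j], (i - cur[j], j - cur[j])
            prev = cur
        if best_len == 0:
            break
        score += best_len * best_len
        ia, ib = best
        for k in range(best_len):  # mask so runs are consumed once
            a[ia + k] = None
            b[ib + k] = None
    return score


_default_provider: FixtureSimilarityProvider | None = None


def default_provider() -> FixtureSimilarityProvider:
    global _default_provider
    if _default_provider is None:
        _default_provider = FixtureSimilarityProvider()
    return _default_provider


def similarity_filter(
    sentence: Sentence,
    concept_words: Sequence[str] = DEFAULT_CONCEPT_WORDS,
    provider: SimilarityProvider | None = None,
    measure: str = "path",
    thresholds: SimilarityThresholds = SimilarityThresholds(),
) -> bool:
    """Keep the sentence's residues iff any (sentence word, concept word)
    similarity strictly exceeds the measure's threshold.

    Words undefined in the provider's lexicon contribute nothing; a sentence
    of only out-of-lexicon words is dropped (vacuous maximum).
    """
    if not concept_words:
        raise ValueError("concept_words must be non-empty")
    provider = provider or default_provider()
    bound = thresholds.for_measure(measure)
    for tok in sentence.tokens:
        for concept in concept_words:
            try:
                s = provider.score(tok, concept, measure)
            except ValueError:
                raise
            except Exception:  # provider hiccup on a word: treat as undefined
                s = None
            if s is not None and s > bound:
                return True
    return False
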
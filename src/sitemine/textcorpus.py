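"""Abstract ingestion, sentence segmentation, and residue-mention recognition.

An abstract is a short block of prose retrieved for one protein-protein
complex by either an AND-query (both partner names required) or an OR-query
(either name).  The unit of downstream analysis is the *residue-containing
sentence*: a sentence mentioning at least one amino-acid residue such as
"Glu67" or "glutamate 67".  This module turns raw text into
:class:`AbstractRecord` objects with tokenized sentences and canonicalized
:class:`ResidueMention` annotations; everything later in the pipeline
(keyword spotting, parse-tree scoring, SVM features, docking constraints)
operates on these objects.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, TextIO

__all__ = [
    "QueryType",
    "ResidueMention",
    "Sentence",
    "AbstractRecord",
    "CorpusFormatError",
    "segment_and_tokenize",
    "extract_residue_mentions",
    "read_abstracts",
    "write_abstracts",
]


class QueryType(str, Enum):
    """Provenance of an abstract: retrieved by AND-query or OR-query."""

    AND = "AND"
    OR = "OR"


#: Canonical three-letter codes of the 20 standard amino acids.
AMINO3 = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET "
    "PHE PRO SER THR TRP TYR VAL"
).split()

#: One-letter -> three-letter.
AMINO1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

AMINO3TO1 = {v: k for k, v in AMINO1TO3.items()}

#: Full residue names (lowercased) -> three-letter code.  Common synonyms
#: (aspartate/aspartic, glutamate/glutamic) are included.
FULLNAME_TO3 = {
    "alanine": "ALA", "arginine": "ARG", "asparagine": "ASN",
    "aspartate": "ASP", "aspartic": "ASP", "cysteine": "CYS",
    "glutamine": "GLN", "glutamate": "GLU", "glutamic": "GLU",
    "glycine": "GLY", "histidine": "HIS", "isoleucine": "ILE",
    "leucine": "LEU", "lysine": "LYS", "methionine": "MET",
    "phenylalanine": "PHE", "proline": "PRO", "serine": "SER",
    "threonine": "THR", "tryptophan": "TRP", "tyrosine": "TYR",
    "valine": "VAL",
}


class CorpusFormatError(ValueError):
    """A corpus record could not be parsed.

    Carries the offending record id (when known) and the line number of the
    record start so other records can still be processed.
    """

    def __init__(self, message: str, abstract_id: str | None = None,
                 line: int | None = None):
        self.abstract_id = abstract_id
        self.line = line
        where = []
        if abstract_id is not None:
            where.append(f"record {abstract_id!r}")
        if line is not None:
            where.append(f"line {line}")
        suffix = f" ({', '.join(where)})" if where else ""
        super().__init__(message + suffix)


@dataclass(frozen=True)
class ResidueMention:
    """One amino-acid residue mentioned in a sentence.

    ``residue_name`` is the canonical upper-case 3-letter code and
    ``residue_number`` the author numbering exactly as printed (no
    renumbering happens at extraction time; mapping onto a structure is the
    structure module's job).  ``chain_hint`` is a single upper-case letter
    captured only when directly appended to the number ("Glu67B" -> "B").
    """

    residue_name: str
    residue_number: int
    chain_hint: str | None = None
    token_index: int = 0
    source_form: str = ""

    def __post_init__(self):
        if self.residue_name not in AMINO3:
            raise ValueError(f"not a standard residue name: {self.residue_name!r}")
        if self.residue_number < 1:
            raise ValueError("residue number must be >= 1")

    @property
    def key(self) -> tuple[str, int]:
        return (self.residue_name, self.residue_number)


@dataclass
class Sentence:
    """A tokenized sentence with its residue mentions.

    ``tree`` optionally holds the constituency parse (a
    :class:`sitemine.deepparse.ParseTree`) whose leaves coincide with
    ``tokens``.
    """

    index: int
    text: str
    tokens: list[str] = field(default_factory=list)
    mentions: list[ResidueMention] = field(default_factory=list)
    tree: object | None = None


@dataclass
class AbstractRecord:
    """One retrieved abstract: query provenance plus its sentences."""

    abstract_id: str
    query_type: QueryType
    complex_id: str
    sentences: list[Sentence] = field(default_factory=list)

    def residue_sentences(self) -> list[Sentence]:
        return [s for s in self.sentences if s.mentions]


# ---------------------------------------------------------------------------
# Segmentation and tokenization (rule-based, deterministic)
# ---------------------------------------------------------------------------

#: Abbreviations after which a period never ends a sentence.
PROTECTED_ABBREVIATIONS = frozenset({
    "i.e", "e.g", "cf", "al", "et", "vs", "fig", "figs", "eq", "eqs",
    "ref", "refs", "no", "ca", "approx", "resp", "dr", "mr", "mrs", "ms",
    "prof", "inc", "e.g", "i.e",
})

_SENT_BOUNDARY = re.compile(r"([.!?])(\s+)(?=[A-Z0-9(\"'])")

_TOKEN_RE = re.compile(
    r"[A-Za-z0-9]+(?:[-'][A-Za-z0-9]+)*"  # words, keeping internal hyphens
)


def _is_protected(prefix: str) -> bool:
    """Whether the word immediately before a '.' protects it from splitting."""
    m = re.search(r"([A-Za-z.]+)$", prefix)
    if not m:
        return False
    word = m.group(1).rstrip(".").lower()
    return word in PROTECTED_ABBREVIATIONS


def tokenize(text: str) -> list[str]:
    """Split into word tokens; internal hyphens and apostrophes are kept."""
    return _TOKEN_RE.findall(text)


def segment_and_tokenize(text: str) -> list[Sentence]:
    """Deterministic rule-based sentence segmentation + tokenization.

    Splits at ``.!?`` followed by whitespace and an upper-case letter, digit,
    bracket or quote, except after protected abbreviations ("i.e.",
    "et al.", "Fig." ...) and single letters.  Degenerate text (no
    terminator) yields exactly one sentence.
    """
    text = text.strip()
    pieces: list[str] = []
    start = 0
    for m in _SENT_BOUNDARY.finditer(text):
        if _is_protected(text[: m.end(1)]):
            continue
        pieces.append(text[start : m.end(1)])
        start = m.end()
    tail = text[start:].strip()
    if tail:
        pieces.append(tail)
    if not pieces:
        pieces = [text]
    sentences = []
    for i, piece in enumerate(pieces):
        s = Sentence(index=i, text=piece, tokens=tokenize(piece))
        s.mentions = extract_residue_mentions(s)
        sentences.append(s)
    return sentences


# ---------------------------------------------------------------------------
# Residue-mention grammar
# ---------------------------------------------------------------------------

_NAME3_ALT = "|".join(AMINO3)
_FULL_ALT = "|".join(sorted(FULLNAME_TO3, key=len, reverse=True))

# "Glu67", "glu-67", "GLU67B", "Glu67Ala", "glutamate-67"
_NAMED_NUM = re.compile(
    rf"^(?P<name>{_NAME3_ALT}|{_FULL_ALT})-?(?P<num>\d+)(?P<tail>[A-Za-z]{{1,3}})?$",
    re.IGNORECASE,
)
# bare residue name token ("Glu", "glutamate") possibly followed by a number token
_NAME_ONLY = re.compile(rf"^(?P<name>{_NAME3_ALT}|{_FULL_ALT})$", re.IGNORECASE)
# number token, optionally with trailing chain letter ("67", "67B")
_NUM_TOKEN = re.compile(r"^(?P<num>\d+)(?P<chain>[A-Z])?$")
# one-letter code: "E67", "E67A" (mutation), "E67B" (chain hint)
_ONE_LETTER = re.compile(r"^(?P<code>[ACDEFGHIKLMNPQRSTVWY])(?P<num>\d+)(?P<tail>[A-Z])?$")


def _canonical_name(raw: str) -> str | None:
    low = raw.lower()
    if low in FULLNAME_TO3:
        return FULLNAME_TO3[low]
    up = raw.upper()
    if up in AMINO3:
        return up
    return None


def _classify_tail(tail: str | None) -> tuple[str | None, bool]:
    """Return (chain_hint, is_mutation) for text trailing the number.

    A 3-letter amino-acid code or a single 1-letter code denotes mutation
    notation (wild-type residue is the mention); any other single upper-case
    letter is a chain hint.
    """
    if not tail:
        return None, False
    if len(tail) == 3 and tail.upper() in AMINO3:
        return None, True
    if len(tail) == 1:
        if tail in AMINO1TO3:
            return None, True
        if tail.isupper():
            return tail, False
    return None, False  # unrecognized tail: ignore


def extract_residue_mentions(
    sentence: Sentence, one_letter: bool = True
) -> list[ResidueMention]:
    """Recognize residue mentions in a tokenized sentence.

    The grammar accepts case-insensitive 3-letter codes or full amino-acid
    names, fused to the number or separated by a space/hyphen ("Glu67",
    "Glu 67", "Glu-67", "glutamate 67"); upper-case 1-letter codes fused to
    the number ("E67", disable via ``one_letter=False``); mutation notation
    ("E67A", "Glu67Ala") yields the wild-type residue only.  A bare number
    without a residue name is never a mention.  Extraction is idempotent and
    looks at this sentence only.
    """
    mentions: list[ResidueMention] = []
    tokens = sentence.tokens
    i = 0
    while i < len(tokens):
        tok = tokens[i]
        m = _NAMED_NUM.match(tok)
        if m:
            name = _canonical_name(m.group("name"))
            chain, _is_mut = _classify_tail(m.group("tail"))
            if name is not None:
                mentions.append(ResidueMention(
                    residue_name=name, residue_number=int(m.group("num")),
                    chain_hint=chain, token_index=i, source_form=tok))
                i += 1
                continue
        m = _NAME_ONLY.match(tok)
        if m and i + 1 < len(tokens):
            nm = _NUM_TOKEN.match(tokens[i + 1])
            name = _canonical_name(m.group("name"))
            if nm and name is not None:
                mentions.append(ResidueMention(
                    residue_name=name, residue_number=int(nm.group("num")),
                    chain_hint=nm.group("chain"), token_index=i,
                    source_form=f"{tok} {tokens[i + 1]}"))
                i += 2
                continue
        if one_letter:
            m = _ONE_LETTER.match(tok)
            if m:
                chain, _is_mut = _classify_tail(m.group("tail"))
                mentions.append(ResidueMention(
                    residue_name=AMINO1TO3[m.group("code")],
                    residue_number=int(m.group("num")),
                    chain_hint=chain, token_index=i, source_form=tok))
                i += 1
                continue
        i += 1
    return mentions


# ---------------------------------------------------------------------------
# Corpus I/O
# ---------------------------------------------------------------------------
# Plain corpus format: blank-line separated blocks, each starting with
#   #ID <abstract_id> <AND|OR> <complex_id>
# followed by the abstract text.  MEDLINE field format (PMID/AB) is accepted
# read-only via Bio.Medline; such records default to OR provenance.

def _iter_blocks(lines: list[str]) -> Iterator[tuple[int, list[str]]]:
    block: list[str] = []
    start = 1
    for lineno, line in enumerate(lines, 1):
        if line.strip():
            if not block:
                start = lineno
            block.append(line)
        elif block:
            yield start, block
            block = []
    if block:
        yield start, block


def read_abstracts(
    stream: TextIO | Iterable[str],
    format: str = "plain",
    errors: str = "raise",
    one_letter: bool = True,
) -> list[AbstractRecord]:
    """Read a corpus of abstracts from ``stream``.

    ``format`` is ``"plain"`` (the native block format) or ``"medline"``.
    With ``errors="collect"`` malformed records are skipped and reported on
    the returned list's ``.errors`` attribute instead of raising, leaving
    other records unaffected.
    """
    if format == "medline":
        return _read_medline(stream, one_letter=one_letter)
    if format != "plain":
        raise ValueError(f"unknown corpus format: {format!r}")

    lines = list(stream)
    records: list[AbstractRecord] = []
    problems: list[CorpusFormatError] = []
    for start, block in _iter_blocks(lines):
        try:
            records.append(_parse_plain_block(block, start, one_letter))
        except CorpusFormatError as exc:
            if errors == "raise":
                raise
            problems.append(exc)
    out = _RecordList(records)
    out.errors = problems
    return out


class _RecordList(list):
    """A list of AbstractRecords with an ``errors`` side channel."""

    errors: list[CorpusFormatError]


def _parse_plain_block(block: list[str], start: int, one_letter: bool) -> AbstractRecord:
    header = block[0].strip()
    if not header.startswith("#ID"):
        raise CorpusFormatError("missing '#ID' header", line=start)
    parts = header.split()
    if len(parts) < 4:
        raise CorpusFormatError(
            "header must be '#ID <abstract_id> <AND|OR> <complex_id>'", line=start)
    _, abstract_id, qt, complex_id = parts[0], parts[1], parts[2], " ".join(parts[3:])
    if qt not in (QueryType.AND.value, QueryType.OR.value):
        raise CorpusFormatError(
            f"query type must be AND or OR, got {qt!r}", abstract_id, start)
    body = " ".join(line.strip() for line in block[1:]).strip()
    if not body:
        raise CorpusFormatError("empty abstract", abstract_id, start)
    sentences = segment_and_tokenize(body)
    if not one_letter:
        for s in sentences:
            s.mentions = extract_residue_mentions(s, one_letter=False)
    return AbstractRecord(abstract_id=abstract_id, query_type=QueryType(qt),
                          complex_id=complex_id, sentences=sentences)


def _read_medline(stream, one_letter: bool = True) -> list[AbstractRecord]:
    from Bio import Medline

    records = []
    for rec in Medline.parse(stream):
        pmid = rec.get("PMID")
        body = rec.get("AB", "")
        if not pmid or not body.strip():
            continue
        sentences = segment_and_tokenize(body)
        if not one_letter:
            for s in sentences:
                s.mentions = extract_residue_mentions(s, one_letter=False)
        records.append(AbstractRecord(abstract_id=pmid, query_type=QueryType.OR,
                                      complex_id="", sentences=sentences))
    out = _RecordList(records)
    out.errors = []
    return out


def write_abstracts(records: Iterable[AbstractRecord], stream: TextIO) -> None:
    """Write records in the plain corpus format (round-trips with
    :func:`read_abstracts`)."""
    first = True
    for rec in records:
        if not first:
            stream.write("\n")
        first = False
        stream.write(f"#ID {rec.abstract_id} {rec.query_type.value} {rec.complex_id}\n")
        stream.write(" ".join(s.text for s in rec.sentences) + "\n")
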
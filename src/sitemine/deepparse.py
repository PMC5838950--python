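"""Constituency parse trees and the keyword-proximity residue score.

Two words adjacent in a sentence may be grammatically distant and vice
versa; the parse tree normalizes for writing style.  A mined residue X is
scored by its tree proximity to binding-site-relevant (PPI+ive) and
-irrelevant (PPI-ive) keywords::

    S_X = sum_i 1/d+_Xi  -  sum_j 1/d-_Xj

where d+ / d- are edge-count distances between the residue's leaf and each
occurrence of a positive / negative keyword leaf.  Interface residues tend
to score above 0.25, which is the default decision threshold (strict
inequality).

Method 1 keeps a mention iff S_X > threshold.  Method 2 additionally
requires a PPI+ive keyword in a *context sentence* (the sentence
immediately before or after), so its keep-set is always a subset of
Method 1's.  The context-root score used by the SVM features is the same
sum taken from the tree root instead of a residue leaf.

Trees are supplied as Penn-Treebank-style bracketed S-expressions — either
produced by an external parser behind the ``ParserProvider`` contract or
read from a sidecar file — so the whole pipeline runs deterministically
offline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence, TextIO

from .lexicon import KeywordDictionary, lemma_matches
from .textcorpus import AbstractRecord, ResidueMention, Sentence

__all__ = [
    "ParseTree",
    "TreeNode",
    "ResidueScore",
    "SX_THRESHOLD",
    "ParseError",
    "read_bracketed_tree",
    "tree_distance",
    "score_residue",
    "context_root_score",
    "method1_filter",
    "context_spot",
    "method2_filter",
    "read_tree_sidecar",
    "write_tree_sidecar",
]

#: Default S_X decision threshold; strict (keep iff S_X > threshold).
SX_THRESHOLD = 0.25


class ParseError(ValueError):
    def __init__(self, message: str, position: int):
        self.position = position
        super().__init__(f"{message} (at character {position})")


@dataclass
class TreeNode:
    label: str
    children: list["TreeNode"] = field(default_factory=list)
    parent: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return not self.children


class ParseTree:
    """Rooted ordered tree over a sentence's tokens.

    Leaves, in order, are the sentence tokens; internal nodes carry
    constituent labels.  Distances are edge counts on the unique path
    between nodes.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        self.leaves: list[TreeNode] = []
        self._depth: dict[int, int] = {}
        self._index_leaves(root, 0)
        self._leaf_pos = {id(leaf): i for i, leaf in enumerate(self.leaves)}

    def _index_leaves(self, node: TreeNode, depth: int) -> None:
        self._depth[id(node)] = depth
        if node.is_leaf:
            self.leaves.append(node)
        for child in node.children:
            child.parent = node
            self._index_leaves(child, depth + 1)

    @property
    def tokens(self) -> list[str]:
        return [leaf.label for leaf in self.leaves]

    def depth(self, node: TreeNode) -> int:
        return self._depth[id(node)]

    def leaf(self, index: int) -> TreeNode:
        return self.leaves[index]

    def leaf_index(self, node: TreeNode) -> int:
        try:
            return self._leaf_pos[id(node)]
        except KeyError:
            raise ValueError("node is not a leaf of this tree") from None

    def __len__(self) -> int:
        return len(self.leaves)


def read_bracketed_tree(s_expression: str) -> ParseTree:
    """Parse a bracketed (S-expression) constituency tree.

    ``(S (NP (NN Glu67)) (VP (VBZ binds)))`` — the first symbol after ``(``
    is the node label; bare symbols are token leaves.  Raises
    :class:`ParseError` with a character position on malformed input.
    """
    s = s_expression
    pos = 0
    n = len(s)

    def skip_ws():
        nonlocal pos
        while pos < n and s[pos].isspace():
            pos += 1

    def parse_node() -> TreeNode:
        nonlocal pos
        skip_ws()
        if pos >= n:
            raise ParseError("unexpected end of input", pos)
        if s[pos] != "(":
            # bare token leaf
            start = pos
            while pos < n and not s[pos].isspace() and s[pos] not in "()":
                pos += 1
            if start == pos:
                raise ParseError(f"unexpected character {s[pos]!r}", pos)
            return TreeNode(label=s[start:pos])
        pos += 1  # consume '('
        skip_ws()
        start = pos
        while pos < n and not s[pos].isspace() and s[pos] not in "()":
            pos += 1
        if start == pos:
            raise ParseError("missing node label", pos)
        node = TreeNode(label=s[start:pos])
        while True:
            skip_ws()
            if pos >= n:
                raise ParseError("unbalanced parentheses", pos)
            if s[pos] == ")":
                pos += 1
                return node
            node.children.append(parse_node())

    skip_ws()
    if pos >= n:
        raise ParseError("empty input", 0)
    root = parse_node()
    skip_ws()
    if pos != n:
        raise ParseError("trailing content after tree", pos)
    return ParseTree(root)


def write_bracketed_tree(tree: ParseTree) -> str:
    def emit(node: TreeNode) -> str:
        if node.is_leaf:
            return node.label
        inner = " ".join(emit(c) for c in node.children)
        return f"({node.label} {inner})"
    return emit(tree.root)


def tree_distance(tree: ParseTree, leaf_a: TreeNode | int, leaf_b: TreeNode | int) -> int:
    """Edge count on the unique path between two leaves:
    ``depth(a) + depth(b) - 2*depth(lca)``."""
    a = tree.leaf(leaf_a) if isinstance(leaf_a, int) else leaf_a
    b = tree.leaf(leaf_b) if isinstance(leaf_b, int) else leaf_b
    for node in (a, b):
        if id(node) not in tree._depth:
            raise ValueError("leaf not in tree")
    if a is b:
        return 0
    ancestors = {}
    node, d = a, tree.depth(a)
    while node is not None:
        ancestors[id(node)] = d
        node = node.parent
        d -= 1
    node, d = b, tree.depth(b)
    while node is not None:
        if id(node) in ancestors:
            return (tree.depth(a) - ancestors[id(node)]) + (tree.depth(b) - d)
        node = node.parent
        d -= 1
    raise ValueError("leaves are not in the same tree")


@dataclass(frozen=True)
class ResidueScore:
    """The S_X value plus the per-keyword terms that produced it."""

    s_x: float
    positive_terms: tuple[tuple[str, int], ...] = ()
    negative_terms: tuple[tuple[str, int], ...] = ()


def _keyword_leaves(
    tree: ParseTree, lemmas: Sequence[str], exclude: set[int]
) -> list[tuple[str, TreeNode]]:
    out = []
    for i, leaf in enumerate(tree.leaves):
        if i in exclude:
            continue
        for lemma in lemmas:
            if lemma_matches(lemma, leaf.label):
                out.append((lemma, leaf))
                break  # one term per leaf occurrence
    return out


def score_residue(
    tree: ParseTree, mention: ResidueMention, dictionary: KeywordDictionary
) -> ResidueScore:
    """Compute S_X for a mention whose head token is a tree leaf.

    Every *occurrence* of a positive/negative keyword among the leaves
    contributes one term 1/d; the residue's own leaf never counts as a
    keyword.  No keywords at all gives a score of 0.
    """
    if mention.token_index >= len(tree.leaves):
        raise ValueError("mention head token is not a leaf of the tree")
    res_leaf = tree.leaf(mention.token_index)
    exclude = {mention.token_index}
    pos_terms = []
    for lemma, leaf in _keyword_leaves(tree, dictionary.ppi_positive, exclude):
        pos_terms.append((lemma, tree_distance(tree, res_leaf, leaf)))
    neg_terms = []
    for lemma, leaf in _keyword_leaves(tree, dictionary.ppi_negative, exclude):
        neg_terms.append((lemma, tree_distance(tree, res_leaf, leaf)))
    s = sum(1.0 / d for _, d in pos_terms) - sum(1.0 / d for _, d in neg_terms)
    return ResidueScore(s, tuple(pos_terms), tuple(neg_terms))


def context_root_score(tree: ParseTree | None, dictionary: KeywordDictionary) -> float:
    """S_X-like score measured from the tree root instead of a residue leaf.

    Used for context sentences, which usually contain no residues.  A
    missing tree or absence of keywords gives 0.
    """
    if tree is None:
        return 0.0
    total = 0.0
    for _lemma, leaf in _keyword_leaves(tree, dictionary.ppi_positive, set()):
        d = tree.depth(leaf)
        if d > 0:
            total += 1.0 / d
    for _lemma, leaf in _keyword_leaves(tree, dictionary.ppi_negative, set()):
        d = tree.depth(leaf)
        if d > 0:
            total -= 1.0 / d
    return total


# ---------------------------------------------------------------------------
# Method 1 and Method 2 filters
# ---------------------------------------------------------------------------

def method1_filter(
    sentence: Sentence,
    mention: ResidueMention,
    dictionary: KeywordDictionary,
    threshold: float = SX_THRESHOLD,
    strict_trees: bool = False,
) -> bool:
    """Keep iff the mention's S_X strictly exceeds the threshold.

    When the sentence has no parse tree the filter abstains and the mention
    passes through (``strict_trees=True`` drops instead).
    """
    tree = sentence.tree
    if tree is None:
        return not strict_trees
    return score_residue(tree, mention, dictionary).s_x > threshold


def context_spot(
    abstract: AbstractRecord, sentence_index: int, dictionary: KeywordDictionary
) -> bool:
    """Whether a PPI+ive keyword occurs in the immediately preceding or
    following sentence.  Missing neighbors contribute False."""
    from .lexicon import spot_keywords

    for j in (sentence_index - 1, sentence_index + 1):
        if 0 <= j < len(abstract.sentences):
            if spot_keywords(abstract.sentences[j], dictionary.ppi_positive):
                return True
    return False


def method2_filter(
    abstract: AbstractRecord,
    sentence_index: int,
    mention: ResidueMention,
    dictionary: KeywordDictionary,
    threshold: float = SX_THRESHOLD,
    strict_trees: bool = False,
) -> bool:
    """Method 1 AND a PPI+ive keyword spotted in a context sentence."""
    sentence = abstract.sentences[sentence_index]
    return method1_filter(sentence, mention, dictionary, threshold,
                          strict_trees) and context_spot(abstract, sentence_index,
                                                         dictionary)


# ---------------------------------------------------------------------------
# Sidecar tree files: one tree per line, aligned to (abstract_id, sentence_index)
# ---------------------------------------------------------------------------

def read_tree_sidecar(stream: TextIO | Iterable[str]) -> dict[tuple[str, int], ParseTree]:
    """Read a tab-separated sidecar of bracketed trees:
    ``abstract_id <TAB> sentence_index <TAB> s-expression``."""
    out: dict[tuple[str, int], ParseTree] = {}
    for lineno, raw in enumerate(stream, 1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t", 2)
        if len(parts) != 3:
            raise ValueError(f"sidecar line {lineno}: expected 3 tab-separated fields")
        abstract_id, idx, sexpr = parts
        out[(abstract_id, int(idx))] = read_bracketed_tree(sexpr)
    return out


def write_tree_sidecar(
    trees: dict[tuple[str, int], ParseTree], stream: TextIO
) -> None:
    for (abstract_id, idx), tree in trees.items():
        stream.write(f"{abstract_id}\t{idx}\t{write_bracketed_tree(tree)}\n")


def attach_trees(
    abstracts: Iterable[AbstractRecord],
    trees: dict[tuple[str, int], ParseTree],
    parser: Callable[[str], str] | None = None,
) -> list[tuple[str, int]]:
    """Attach sidecar (or parser-provided) trees to sentences in place.

    ``parser`` maps sentence text to an S-expression and is consulted for
    sentences absent from ``trees``.  Returns the (abstract_id, index) pairs
    still missing a tree afterwards.
    """
    missing = []
    for rec in abstracts:
        for sent in rec.sentences:
            key = (rec.abstract_id, sent.index)
            if key in trees:
                sent.tree = trees[key]
            elif parser is not None:
                sent.tree = read_bracketed_tree(parser(sent.text))
            if sent.tree is None:
                missing.append(key)
    return missing
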
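import random

import pytest

from sitemine.deepparse import ParseTree, TreeNode
from sitemine.lexicon import default_dictionary, default_provider


@pytest.fixture(scope="session")
def dictionary():
    return default_dictionary()


@pytest.fixture(scope="session")
def provider():
    return default_provider()


def random_tree(rng: random.Random, n_leaves: int, vocab=None) -> ParseTree:
    """A random rooted ordered tree whose leaves are tokens.

    Built by recursively partitioning the token sequence, so arbitrary
    branching factors and depths occur.
    """
    vocab = vocab or [f"w{i}" for i in range(n_leaves)]
    tokens = [vocab[i % len(vocab)] for i in range(n_leaves)]

    counter = [0]

    def build(seq):
        if len(seq) == 1 and rng.random() < 0.5:
            return TreeNode(label=seq[0])
        counter[0] += 1
        node = TreeNode(label=f"N{counter[0]}")
        if len(seq) == 1:
            node.children = [TreeNode(label=seq[0])]
            return node
        n_parts = rng.randint(2, min(4, len(seq)))
        cuts = sorted(rng.sample(range(1, len(seq)), n_parts - 1))
        parts = []
        prev = 0
        for c in cuts + [len(seq)]:
            parts.append(seq[prev:c])
            prev = c
        node.children = [build(p) for p in parts]
        return node

    root = TreeNode(label="ROOT")
    root.children = [build(tokens)]
    return ParseTree(root)


def bfs_distance(tree: ParseTree, a: TreeNode, b: TreeNode) -> int:
    """Independent oracle: breadth-first search over the undirected tree."""
    adjacency = {id(tree.root): []}

    def walk(node):
        for child in node.children:
            adjacency.setdefault(id(node), []).append(child)
            adjacency.setdefault(id(child), []).append(node)
            walk(child)

    walk(tree.root)
    frontier = [a]
    seen = {id(a)}
    d = 0
    while frontier:
        if any(n is b for n in frontier):
            return d
        nxt = []
        for n in frontier:
            for m in adjacency[id(n)]:
                if id(m) not in seen:
                    seen.add(id(m))
                    nxt.append(m)
        frontier = nxt
        d += 1
    raise AssertionError("leaves not connected")
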
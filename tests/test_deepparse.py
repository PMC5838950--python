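import random

import pytest

from sitemine import deepparse as dp
from sitemine.lexicon import KeywordDictionary, lemma_matches
from sitemine.textcorpus import AbstractRecord, QueryType, ResidueMention, Sentence, tokenize

from conftest import bfs_distance, random_tree


def make_sentence(sexpr, index=0):
    tree = dp.read_bracketed_tree(sexpr)
    text = " ".join(tree.tokens)
    s = Sentence(index=index, text=text, tokens=tree.tokens, tree=tree)
    return s


def mention_at(tree, token):
    idx = tree.tokens.index(token)
    return ResidueMention("GLU", 67, token_index=idx, source_form=token)


SMALL_DICT = KeywordDictionary(("bind", "dock"), ("phosphory", "epitope"))


class TestBracketReader:
    def test_two_leaves(self):
        tree = dp.read_bracketed_tree("(S (NP (NN Glu67)) (VP (VBZ binds)))")
        assert tree.tokens == ["Glu67", "binds"]

    def test_single_leaf(self):
        tree = dp.read_bracketed_tree("(X a)")
        assert tree.tokens == ["a"]
        assert tree.root.label == "X"

    def test_unbalanced_raises_with_position(self):
        with pytest.raises(dp.ParseError) as exc:
            dp.read_bracketed_tree("((")
        assert exc.value.position >= 0

    @pytest.mark.parametrize("bad", ["", "   ", "(S a) trailing", "(S a))"])
    def test_malformed(self, bad):
        with pytest.raises(dp.ParseError):
            dp.read_bracketed_tree(bad)

    def test_round_trip(self):
        sexpr = "(S (NP the (JJ binding) site) (VP (VBZ opens)))"
        tree = dp.read_bracketed_tree(sexpr)
        assert dp.write_bracketed_tree(tree) == sexpr


class TestTreeDistance:
    def test_leaf_to_itself_is_zero(self):
        tree = dp.read_bracketed_tree("(S a b)")
        assert dp.tree_distance(tree, 0, 0) == 0

    def test_siblings_at_distance_two(self):
        tree = dp.read_bracketed_tree("(S a b)")
        assert dp.tree_distance(tree, 0, 1) == 2

    def test_matches_bfs_oracle_on_random_trees(self):
        rng = random.Random(7)
        for _ in range(40):
            tree = random_tree(rng, rng.randint(2, 15))
            for i in range(len(tree)):
                for j in range(len(tree)):
                    want = bfs_distance(tree, tree.leaf(i), tree.leaf(j))
                    assert dp.tree_distance(tree, i, j) == want

    def test_metric_properties(self):
        rng = random.Random(11)
        for _ in range(20):
            tree = random_tree(rng, rng.randint(3, 12))
            n = len(tree)
            idx = [rng.randrange(n) for _ in range(3)]
            a, b, c = idx
            dab = dp.tree_distance(tree, a, b)
            assert dab == dp.tree_distance(tree, b, a)       # symmetry
            assert (dab == 0) == (a == b)                    # identity
            assert dab <= dp.tree_distance(tree, a, c) + \
                dp.tree_distance(tree, c, b)                 # triangle

    def test_foreign_leaf_rejected(self):
        t1 = dp.read_bracketed_tree("(S a b)")
        t2 = dp.read_bracketed_tree("(S c d)")
        with pytest.raises(ValueError):
            dp.tree_distance(t1, t1.leaf(0), t2.leaf(0))


def brute_force_score(tree, mention, dictionary):
    """Independent oracle: enumerate every (keyword leaf, sign) pair."""
    total = 0.0
    for i, leaf in enumerate(tree.leaves):
        if i == mention.token_index:
            continue
        d = bfs_distance(tree, tree.leaf(mention.token_index), leaf)
        if any(lemma_matches(l, leaf.label) for l in dictionary.ppi_positive):
            total += 1.0 / d
        elif any(lemma_matches(l, leaf.label) for l in dictionary.ppi_negative):
            total -= 1.0 / d
    return total


class TestScoreResidue:
    def test_single_positive_at_distance_four(self):
        # Glu67 and binding both at depth 2 in different branches: path 4
        s = make_sentence("(S (NP Glu67) (VP shows binding))")
        score = dp.score_residue(s.tree, mention_at(s.tree, "Glu67"), SMALL_DICT)
        assert score.s_x == pytest.approx(0.25)
        assert score.positive_terms == (("bind", 4),)

    def test_mixed_terms_sum(self):
        # positives at distances 2 and 5, negative at 4: 0.5 + 0.2 - 0.25
        tree = dp.read_bracketed_tree(
            "(S (NP Glu67 binding) (VP phosphorylation (PP of docking)))")
        d = {t: dp.tree_distance(tree, tree.tokens.index("Glu67"),
                                 tree.tokens.index(t))
             for t in ("binding", "docking", "phosphorylation")}
        assert d == {"binding": 2, "docking": 5, "phosphorylation": 4}
        score = dp.score_residue(tree, mention_at(tree, "Glu67"), SMALL_DICT)
        assert score.s_x == pytest.approx(0.5 + 0.2 - 0.25)

    def test_no_keywords_scores_zero(self):
        s = make_sentence("(S (NP Glu67) (VP was measured))")
        assert dp.score_residue(s.tree, mention_at(s.tree, "Glu67"),
                                SMALL_DICT).s_x == 0.0

    def test_residue_leaf_never_counts_as_keyword(self):
        # token "binds67"? use a mention whose own token matches a lemma
        tree = dp.read_bracketed_tree("(S (NP binding) (VP binding))")
        m = ResidueMention("GLU", 67, token_index=0)
        score = dp.score_residue(tree, m, SMALL_DICT)
        assert len(score.positive_terms) == 1  # only the other occurrence

    def test_each_occurrence_contributes(self):
        tree = dp.read_bracketed_tree("(S Glu67 binding binding)")
        score = dp.score_residue(tree, mention_at(tree, "Glu67"), SMALL_DICT)
        assert score.s_x == pytest.approx(1.0)  # two terms at distance 2

    def test_matches_brute_force_on_random_trees(self):
        rng = random.Random(3)
        vocab = ["binding", "docked", "phosphorylated", "epitope", "the",
                 "site", "was", "of", "shown", "residue"]
        for _ in range(60):
            tree = random_tree(rng, rng.randint(2, 20), vocab=vocab)
            m = ResidueMention("GLU", 67, token_index=rng.randrange(len(tree)))
            got = dp.score_residue(tree, m, SMALL_DICT).s_x
            assert got == pytest.approx(brute_force_score(tree, m, SMALL_DICT),
                                        abs=1e-12)

    def test_additivity_adding_positive_leaf_never_decreases(self):
        rng = random.Random(5)
        for _ in range(20):
            tree = random_tree(rng, rng.randint(2, 10),
                               vocab=["plain", "words", "only"])
            m = ResidueMention("GLU", 67, token_index=0)
            base = dp.score_residue(tree, m, SMALL_DICT).s_x
            # relabel a non-mention leaf into a positive keyword
            for leaf in tree.leaves[1:]:
                leaf.label = "binding"
                break
            grown = dp.score_residue(tree, m, SMALL_DICT).s_x
            assert grown >= base

    def test_term_bound(self):
        # min distance between distinct leaves is 2, so every term <= 0.5
        rng = random.Random(9)
        for _ in range(20):
            tree = random_tree(rng, rng.randint(2, 15), vocab=["binding", "x"])
            m = ResidueMention("GLU", 67, token_index=0)
            score = dp.score_residue(tree, m, SMALL_DICT)
            n_pos = len(score.positive_terms)
            assert all(d >= 2 for _, d in score.positive_terms)
            assert score.s_x <= 0.5 * n_pos + 1e-12


class TestContextRootScore:
    def test_positive_leaf_at_depth_three(self):
        tree = dp.read_bracketed_tree("(S (NP (X binding)) (VP other))")
        assert dp.context_root_score(tree, SMALL_DICT) == pytest.approx(1 / 3)

    def test_no_keywords_zero(self):
        tree = dp.read_bracketed_tree("(S (NP plain) (VP words))")
        assert dp.context_root_score(tree, SMALL_DICT) == 0.0

    def test_missing_tree_zero(self):
        assert dp.context_root_score(None, SMALL_DICT) == 0.0

    def test_matches_depth_enumeration(self):
        rng = random.Random(13)
        vocab = ["binding", "epitope", "site", "the", "dock"]
        for _ in range(30):
            tree = random_tree(rng, rng.randint(2, 15), vocab=vocab)
            want = 0.0
            for leaf in tree.leaves:
                d = bfs_distance(tree, tree.root, leaf)
                if any(lemma_matches(l, leaf.label)
                       for l in SMALL_DICT.ppi_positive):
                    want += 1 / d
                elif any(lemma_matches(l, leaf.label)
                         for l in SMALL_DICT.ppi_negative):
                    want -= 1 / d
            assert dp.context_root_score(tree, SMALL_DICT) == pytest.approx(
                want, abs=1e-12)


def abstract_with(sentences):
    return AbstractRecord("a1", QueryType.OR, "cpx", sentences)


class TestMethodFilters:
    def test_method1_threshold_is_strict(self):
        keep = make_sentence("(S Glu67 binding binding)")      # s_x = 1.0
        at_threshold = make_sentence("(S (NP Glu67) (VP shows binding))")  # 0.25
        neg = make_sentence("(S Glu67 phosphorylation)")        # -0.5
        for s, expected in ((keep, True), (at_threshold, False), (neg, False)):
            m = mention_at(s.tree, "Glu67")
            assert dp.method1_filter(s, m, SMALL_DICT) is expected

    def test_missing_tree_abstains_by_default(self):
        s = Sentence(0, "Glu67", tokens=["Glu67"])
        m = ResidueMention("GLU", 67, token_index=0)
        assert dp.method1_filter(s, m, SMALL_DICT) is True
        assert dp.method1_filter(s, m, SMALL_DICT, strict_trees=True) is False

    def test_context_spot(self):
        prev = Sentence(0, "docking was performed",
                        tokens=tokenize("docking was performed"))
        res = make_sentence("(S Glu67 binding binding)", index=1)
        nxt = Sentence(2, "nothing here", tokens=tokenize("nothing here"))
        rec = abstract_with([prev, res, nxt])
        assert dp.context_spot(rec, 1, SMALL_DICT) is True
        rec2 = abstract_with([Sentence(0, "nothing", tokens=["nothing"]),
                              res, nxt])
        assert dp.context_spot(rec2, 1, SMALL_DICT) is False

    def test_only_sentence_has_no_context(self):
        res = make_sentence("(S Glu67 binding binding)")
        rec = abstract_with([res])
        assert dp.context_spot(rec, 0, SMALL_DICT) is False

    def test_method2_is_conjunction(self):
        ctx = Sentence(0, "docking was performed",
                       tokens=tokenize("docking was performed"))
        plain = Sentence(0, "nothing here", tokens=tokenize("nothing here"))
        high = "(S Glu67 binding binding)"
        low = "(S (NP Glu67) (VP was measured))"
        cases = [
            (ctx, high, True),    # s_x high + context keyword
            (plain, high, False),  # no context keyword
            (ctx, low, False),     # s_x below threshold
        ]
        for first, sexpr, expected in cases:
            res = make_sentence(sexpr, index=1)
            m = mention_at(res.tree, "Glu67")
            rec = abstract_with([first, res])
            assert dp.method2_filter(rec, 1, m, SMALL_DICT) is expected

    def test_method2_subset_of_method1(self):
        rng = random.Random(17)
        vocab = ["binding", "epitope", "plain", "dock", "words"]
        for _ in range(25):
            tree = random_tree(rng, rng.randint(2, 10), vocab=vocab)
            res = Sentence(0, " ".join(tree.tokens), tokens=tree.tokens,
                           tree=tree)
            rec = abstract_with([res])
            m = ResidueMention("GLU", 67,
                               token_index=rng.randrange(len(tree)))
            if dp.method2_filter(rec, 0, m, SMALL_DICT):
                assert dp.method1_filter(res, m, SMALL_DICT)


class TestSidecar:
    def test_round_trip(self, tmp_path):
        trees = {("a1", 0): dp.read_bracketed_tree("(S x y)"),
                 ("a1", 1): dp.read_bracketed_tree("(S (NP z))")}
        p = tmp_path / "trees.tsv"
        with open(p, "w") as fh:
            dp.write_tree_sidecar(trees, fh)
        with open(p) as fh:
            again = dp.read_tree_sidecar(fh)
        assert set(again) == set(trees)
        assert again[("a1", 0)].tokens == ["x", "y"]

    def test_attach_trees_reports_missing(self):
        s0 = Sentence(0, "x y", tokens=["x", "y"])
        s1 = Sentence(1, "z", tokens=["z"])
        rec = abstract_with([s0, s1])
        missing = dp.attach_trees([rec], {("a1", 0):
                                          dp.read_bracketed_tree("(S x y)")})
        assert missing == [("a1", 1)]
        assert rec.sentences[0].tree is not None
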
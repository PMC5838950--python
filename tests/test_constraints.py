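import itertools

import numpy as np
import pytest

from sitemine import constraints as cn
from sitemine import structure as st
from sitemine.synthdata import _random_rotation, generate_pose_set, generate_toy_complex
from sitemine.textcorpus import QueryType


def ev(qt, nlp=False, aid=None):
    return cn.Evidence(abstract_id=aid or f"a{id(object()) % 1000}",
                       query_type=qt, nlp_pass=nlp)


AND, OR = QueryType.AND, QueryType.OR


class TestConfidenceBasic:
    def test_or_abstracts_sum(self):
        assert cn.confidence_basic([ev(OR, aid=f"a{i}") for i in range(3)]) == 3

    def test_and_abstracts_capped(self):
        assert cn.confidence_basic([ev(AND, aid=f"a{i}") for i in range(6)]) == 10

    def test_mixed(self):
        assert cn.confidence_basic([ev(AND, aid="a"), ev(OR, aid="b")]) == 3

    def test_empty_evidence_error(self):
        with pytest.raises(ValueError):
            cn.confidence_basic([])

    def test_monotone_in_evidence(self):
        base = [ev(OR, aid="a")]
        assert cn.confidence_basic(base + [ev(OR, aid="b")]) >= \
            cn.confidence_basic(base)


class TestConfidenceNlp:
    def test_and_passing_nlp(self):
        assert cn.confidence_nlp([ev(AND, nlp=True, aid="a")]) == 10

    def test_and_without_nlp(self):
        assert cn.confidence_nlp([ev(AND, aid="a")]) == 8

    def test_or_passing_nlp(self):
        assert cn.confidence_nlp([ev(OR, nlp=True, aid="a")]) == 6

    def test_fallback_max_of_five_and_count(self):
        assert cn.confidence_nlp([ev(OR, aid="a"), ev(OR, aid="b")]) == 5
        many = [ev(OR, aid=f"a{i}") for i in range(7)]
        assert cn.confidence_nlp(many) == 7

    def test_exhaustive_patterns_match_enumeration(self):
        """All AND/OR x NLP evidence multisets up to six abstracts agree
        with a direct clause-by-clause enumeration, and stay in [1, 10]."""
        kinds = [(AND, True), (AND, False), (OR, True), (OR, False)]

        def oracle(pattern):
            if any(q is AND and p for q, p in pattern):
                return 10
            if any(q is AND for q, p in pattern):
                return 8
            if any(q is OR and p for q, p in pattern):
                return 6
            return min(10, max(5, len(pattern)))

        def oracle_basic(pattern):
            return min(10, sum(2 if q is AND else 1 for q, _ in pattern))

        n_checked = 0
        for size in range(1, 7):
            for pattern in itertools.combinations_with_replacement(kinds, size):
                evidence = [ev(q, nlp=p, aid=f"a{i}")
                            for i, (q, p) in enumerate(pattern)]
                f_nlp = cn.confidence_nlp(evidence)
                f_basic = cn.confidence_basic(evidence)
                assert f_nlp == oracle(pattern)
                assert f_basic == oracle_basic(pattern)
                assert 1 <= f_nlp <= 10 and 1 <= f_basic <= 10
                # AND evidence outranks any OR-only pattern of the same size
                if any(q is AND for q, _ in pattern):
                    assert f_nlp >= 8
                n_checked += 1
        assert n_checked > 200


def scored(role, num, f, n_evidence=1, and_derived=False):
    evidence = tuple(
        ev(AND if (and_derived and i == 0) else OR, aid=f"r{num}-a{i}")
        for i in range(n_evidence))
    return cn.ScoredResidue(role, "A", num, float(f), evidence=evidence)


class TestSelectConstraints:
    def test_top_five_of_seven(self):
        residues = [scored("receptor", i, f) for i, f in
                    enumerate([3, 9, 5, 7, 2, 8, 6])]
        out = cn.select_constraints(residues)
        assert len(out) == 5
        assert [c.f for c in out] == [9, 8, 7, 6, 5]

    def test_fewer_than_k_returns_all(self):
        out = cn.select_constraints([scored("receptor", 1, 4),
                                     scored("receptor", 2, 6)])
        assert len(out) == 2

    def test_tie_break_and_before_or_then_count_then_number(self):
        residues = [
            scored("receptor", 30, 6, n_evidence=2),
            scored("receptor", 10, 6, n_evidence=1),
            scored("receptor", 20, 6, n_evidence=1, and_derived=True),
        ]
        out = cn.select_constraints(residues, k=3)
        assert [c.residue_number for c in out] == [20, 30, 10]

    def test_confidence_range_enforced(self):
        with pytest.raises(ValueError):
            cn.Constraint("receptor", "A", 1, 0.5)
        with pytest.raises(ValueError):
            cn.Constraint("sidechain", "A", 1, 5.0)


class TestReferenceConstraints:
    def test_three_smallest_ca_distances(self):
        cpx = generate_toy_complex(n_contacts=5, seed=8)
        pairs, constraints = cn.reference_constraints(cpx.bound_receptor,
                                                      cpx.bound_ligand)
        assert len(pairs) == 3
        # generator stacks contacts at increasing Ca-Ca distance
        assert [p.ca_distance for p in pairs] == sorted(p.ca_distance
                                                        for p in pairs)
        assert all(c.f == 10.0 for c in constraints)
        all_pairs = st.interface_pairs(cpx.bound_receptor, cpx.bound_ligand)
        dists = sorted(
            float(np.linalg.norm(r.atom("CA").xyz - l.atom("CA").xyz))
            for (_, r), (_, l) in all_pairs)
        assert [p.ca_distance for p in pairs] == pytest.approx(dists[:3])

    def test_fewer_pairs_than_requested_warns(self):
        cpx = generate_toy_complex(n_contacts=3, seed=9)
        with pytest.warns(UserWarning, match="interface pairs"):
            pairs, _ = cn.reference_constraints(cpx.bound_receptor,
                                                cpx.bound_ligand, k=5)
        assert len(pairs) == 3

    def test_no_interface_returns_empty(self):
        a = st.StructureModel(chains={"A": [st.Residue(
            "ALA", 1, atoms=[st.Atom("CA", "C", (0, 0, 0))])]})
        b = st.StructureModel(chains={"B": [st.Residue(
            "GLY", 1, atoms=[st.Atom("CA", "C", (50, 0, 0))])]})
        with pytest.warns(UserWarning):
            pairs, constraints = cn.reference_constraints(a, b)
        assert pairs == [] and constraints == []


def ligand_constraints_in_unbound_numbering(cpx, constraints):
    inv = {b: u for u, b in cpx.ligand_mapping().items()}
    out = []
    for c in constraints:
        if c.protein_role == "ligand":
            num, _ = inv[(c.residue_number, "")]
            out.append(cn.Constraint("ligand", "L", num, c.f))
        else:
            out.append(c)
    return out


class TestRescoring:
    def test_scores_sum_constraint_confidences(self):
        cpx = generate_toy_complex(seed=10, noise_sigma=0.0)
        ps = generate_pose_set(cpx, n_poses=1, fraction_near_native=1.0,
                               seed=0)
        native = ps.poses[0]
        receptor_c = cn.Constraint("receptor", "A", 1, 10.0)
        inv = {b: u for u, b in cpx.ligand_mapping().items()}
        lig_num, _ = inv[(1, "")]
        ligand_c = cn.Constraint("ligand", "L", lig_num, 6.0)
        ranked = cn.rescore_poses([native], [receptor_c, ligand_c],
                                  cpx.bound_receptor, cpx.unbound_ligand)
        assert ranked[0][1] == pytest.approx(16.0)

    def test_no_constraints_keeps_order(self):
        cpx = generate_toy_complex(seed=11)
        ps = generate_pose_set(cpx, n_poses=20, seed=1)
        ranked = cn.rescore_poses(ps.poses, [], cpx.bound_receptor,
                                  cpx.unbound_ligand)
        assert [p.pose_id for p, s in ranked] == [p.pose_id for p in ps.poses]
        assert all(s == 0.0 for _, s in ranked)

    def test_equal_scores_preserve_raw_order(self):
        cpx = generate_toy_complex(seed=12)
        # constraint on a residue no pose can reach (number absent)
        ghost = cn.Constraint("receptor", "A", 999, 10.0)
        ps = generate_pose_set(cpx, n_poses=10, fraction_near_native=0.0,
                               seed=2)
        far = [p for p in ps.poses if ps.gold_irmsd[p.pose_id] > 30]
        ranked = cn.rescore_poses(far, [ghost], cpx.bound_receptor,
                                  cpx.unbound_ligand)
        assert [p.pose_id for p, _ in ranked] == [p.pose_id for p in far]


class TestIrmsd:
    def setup_method(self):
        self.cpx = generate_toy_complex(seed=13)
        self.ps = generate_pose_set(self.cpx, n_poses=5, seed=3)
        self.mapping = self.cpx.ligand_mapping()

    def reference_pose(self):
        return cn.DockPose("ref", self.ps.reference_rotation,
                           self.ps.reference_translation)

    def test_identity_pose_zero(self):
        v = cn.irmsd(self.reference_pose(), self.cpx.bound_receptor,
                     self.cpx.bound_ligand, self.cpx.unbound_ligand,
                     mapping=self.mapping)
        assert v == pytest.approx(0.0, abs=1e-9)

    def test_pure_translation_adds_uniformly(self):
        ref = self.reference_pose()
        shift = np.array([3.0, 0.0, 0.0])
        moved = cn.DockPose("t", ref.rotation, ref.translation + shift)
        v = cn.irmsd(moved, self.cpx.bound_receptor, self.cpx.bound_ligand,
                     self.cpx.unbound_ligand, mapping=self.mapping)
        assert v == pytest.approx(3.0, abs=1e-9)

    def test_invariant_to_global_rotation(self):
        rng = np.random.default_rng(5)
        ref = self.reference_pose()
        base = cn.irmsd(ref, self.cpx.bound_receptor, self.cpx.bound_ligand,
                        self.cpx.unbound_ligand, mapping=self.mapping)
        for _ in range(5):
            G = _random_rotation(rng)

            def rotate(model):
                out = st.StructureModel(name=model.name)
                for cid, residues in model.chains.items():
                    out.chains[cid] = [
                        st.Residue(r.name, r.number, r.icode, [
                            st.Atom(a.name, a.element,
                                    tuple(G @ a.xyz))
                            for a in r.atoms]) for r in residues]
                return out

            rotated_pose = cn.DockPose("g", G @ ref.rotation,
                                       G @ ref.translation)
            v = cn.irmsd(rotated_pose, rotate(self.cpx.bound_receptor),
                         rotate(self.cpx.bound_ligand),
                         self.cpx.unbound_ligand, mapping=self.mapping)
            assert v == pytest.approx(base, abs=1e-8)

    def test_too_few_interface_correspondences(self):
        cpx = generate_toy_complex(n_contacts=3, seed=14)
        mapping = dict(list(cpx.ligand_mapping().items())[:2])
        pose = cn.DockPose("x", np.eye(3), np.zeros(3))
        with pytest.raises(ValueError, match="interface"):
            cn.irmsd(pose, cpx.bound_receptor, cpx.bound_ligand,
                     cpx.unbound_ligand, mapping=mapping)


class TestSuccessRate:
    def test_half_of_complexes_succeed(self):
        assert cn.success_rate([[1.0, 8.0], [9.0, 9.0]]) == 0.5

    def test_hit_at_rank_eleven_fails(self):
        irmsds = [10.0] * 10 + [1.0]
        assert cn.success_rate([irmsds]) == 0.0

    def test_threshold_is_non_strict(self):
        assert cn.success_rate([[5.0]]) == 1.0

    def test_empty_input_error(self):
        with pytest.raises(ValueError):
            cn.success_rate([])


def test_constraint_file_round_trip(tmp_path):
    constraints = [cn.Constraint("receptor", "A", 42, 10.0, "GLU", ("a1", "a2")),
                   cn.Constraint("ligand", "B", 7, 6.0)]
    p = tmp_path / "c.tsv"
    with open(p, "w") as fh:
        cn.write_constraints(constraints, fh)
    with open(p) as fh:
        again = cn.read_constraints(fh)
    assert again == constraints
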
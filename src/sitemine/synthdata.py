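"""Seeded generators of labeled corpora, parse trees, toy structures and
pose sets.

The corpus generator emulates the statistical regularity the filters
exploit: residues that really sit at a protein-protein interface tend to
be mentioned grammatically close to binding-site (PPI+ive) keywords, in
sentences naming the interaction partners, with more binding-site talk in
the surrounding sentences; non-interface residues co-occur with PPI-ive
keywords (modifications, immunoglobulin chemistry, nucleotides).  It does
not attempt realistic English prose or PubMed retrieval statistics -
sentences come from a fixed catalogue of template skeletons whose
bracketed parses are emitted alongside, so every parse-tree distance is
known by construction (near-keyword skeletons place the keyword at edge
distance 2-3 from the residue leaf, i.e. S_X of 1/2 or 1/3).

The structure generator builds Ca-trace-plus-pseudo-side-chain chains with
an exactly controlled number of interface contacts, plus noisy renumbered
"unbound" monomers; the pose generator produces seeded rigid-body match
sets with a planted near-native fraction and records each pose's true
i-RMSD.  All generators are pure functions of (recipe, seed).
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import numpy as np

from .deepparse import ParseTree, read_bracketed_tree
from .structure import Atom, Residue, StructureModel, superpose
from .textcorpus import (
    AMINO3,
    AbstractRecord,
    QueryType,
    Sentence,
    extract_residue_mentions,
    tokenize,
)

__all__ = [
    "CorpusRecipe",
    "SyntheticCorpus",
    "generate_corpus",
    "ToyComplex",
    "generate_toy_complex",
    "PoseSet",
    "generate_pose_set",
]


# ---------------------------------------------------------------------------
# Corpus generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorpusRecipe:
    """Knobs of the synthetic-corpus generator.

    The defaults describe a corpus with a strong but imperfect planted
    signal: 9 of 10 interface mentions sit grammatically near a PPI+ive
    keyword, 8 of 10 non-interface mentions near a PPI-ive keyword, and
    context/protein-name cues follow the same asymmetry.
    """

    n_complexes: int = 200
    abstracts_per_complex: int = 3
    interface_mention_rate: float = 0.5
    p_keyword_near_interface: float = 0.9
    p_negword_near_noninterface: float = 0.8
    p_and_query: float = 0.3
    p_both_names_interface: float = 0.8
    p_single_name_noninterface: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for name in ("interface_mention_rate", "p_keyword_near_interface",
                     "p_negword_near_noninterface", "p_and_query",
                     "p_both_names_interface", "p_single_name_noninterface"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_complexes < 1 or self.abstracts_per_complex < 1:
            raise ValueError("counts must be >= 1")


@dataclass
class MentionLabel:
    complex_id: str
    abstract_id: str
    sentence_index: int
    residue_name: str
    residue_number: int
    interface: bool


@dataclass
class SyntheticCorpus:
    recipe: CorpusRecipe
    abstracts: list[AbstractRecord]
    trees: dict[tuple[str, int], ParseTree]
    labels: list[MentionLabel]
    protein_names: dict[str, tuple[str, str]]   # complex_id -> (name1, name2)

    def label_index(self) -> dict[tuple[str, int, str, int], bool]:
        return {(l.abstract_id, l.sentence_index, l.residue_name,
                 l.residue_number): l.interface for l in self.labels}


# Surface word forms whose stems are in the packaged dictionary.
POSITIVE_FORMS = ("binding", "interface", "docking", "pocket", "contact",
                  "interaction", "groove", "recognition")
NEGATIVE_FORMS = ("phosphorylation", "epitope", "ubiquitin", "allosteric",
                  "polar", "dissociation", "antibody", "nucleotide")

# -- template skeletons -----------------------------------------------------
# Trees are nested tuples: (label, child, ...); a str child is a token leaf.
# Near-keyword skeletons put {K} at edge distance 2 or 3 from {R}.

def _near_skeletons():
    # keyword and residue leaves hang directly under a shared constituent
    # (no intervening part-of-speech nodes), fixing d(R, K) exactly
    return [
        # d(R, K) = 2
        lambda R, K, P: ("S", ("NP", "The", K, "residue", R),
                         ("VP", "is", ("ADJP", "critical"))),
        lambda R, K, P: ("S", ("NP", ("NP", "Mutation"),
                               ("PP", "of", ("NP", "the", K, "residue", R))),
                         ("VP", "reduced", ("NP", "activity"))),
        # d(R, K) = 2, both partner names available
        lambda R, K, P: ("S", ("NP", "The", K, "residue", R),
                         ("VP", "links", ("NP", P[0], "and", P[1]))),
        lambda R, K, P: ("S", ("NP", P[0]),
                         ("VP", "positions", ("NP", "residue", R, K))),
        # d(R, K) = 3
        lambda R, K, P: ("S", ("NP", P[0]),
                         ("VP", "anchors",
                          ("NP", "residue", R, ("NP", "its", K, "surface")))),
        lambda R, K, P: ("S", ("NP", "Residue", R, ("NP", "a", K, "element")),
                         ("VP", "stabilizes", ("NP", P[1]))),
    ]


def _plain_skeletons():
    return [
        lambda R, P: ("S", ("NP", ("NN", "Residue"), ("NN", R)),
                      ("VP", ("VBD", "was"),
                       ("VP", ("VBN", "examined"),
                        ("PP", ("IN", "in"), ("NP", ("NN", "detail")))))),
        lambda R, P: ("S", ("NP", ("DT", "The"), ("NNS", "authors")),
                      ("VP", ("VBD", "measured"),
                       ("NP", ("NN", "residue"), ("NN", R)))),
        lambda R, P: ("S", ("NP", ("NN", "Residue"), ("NN", R)),
                      ("VP", ("VBZ", "links"),
                       ("NP", ("NN", P[0]), ("CC", "and"), ("NN", P[1])))),
        lambda R, P: ("S", ("NP", ("NN", P[0])),
                      ("VP", ("VBZ", "retains"),
                       ("NP", ("NN", "residue"), ("NN", R)))),
    ]


def _context_skeletons():
    return [
        lambda K, P: ("S", ("NP", ("DT", "The"), ("NN", K)),
                      ("VP", ("VBD", "was"),
                       ("VP", ("VBN", "analyzed"),
                        ("PP", ("IN", "for"),
                         ("NP", ("NN", P[0]), ("CC", "and"), ("NN", P[1])))))),
        lambda K, P: ("S", ("NP", ("NNS", "Experiments")),
                      ("VP", ("VBD", "revealed"),
                       ("NP", ("DT", "a"), ("JJ", "clear"), ("NN", K)))),
    ]


def _neutral_context_skeletons():
    return [
        lambda P: ("S", ("NP", ("DT", "The"), ("NNS", "authors")),
                   ("VP", ("VBD", "performed"),
                    ("NP", ("JJ", "many"), ("NNS", "measurements")))),
        lambda P: ("S", ("NP", ("NNS", "Samples")),
                   ("VP", ("VBD", "were"),
                    ("VP", ("VBN", "purified"),
                     ("PP", ("IN", "before"), ("NP", ("NN", "analysis")))))),
    ]


def _emit(node) -> str:
    if isinstance(node, str):
        return node
    label, rest = node[0], node[1:]
    return "(" + label + " " + " ".join(_emit(c) for c in rest) + ")"


def _leaves(node) -> list[str]:
    if isinstance(node, str):
        return [node]
    out = []
    for c in node[1:]:
        out.extend(_leaves(c))
    return out


def _make_sentence(index: int, skeleton) -> tuple[Sentence, str]:
    tokens = _leaves(skeleton)
    text = " ".join(tokens) + "."
    sexpr = _emit(skeleton)
    sent = Sentence(index=index, text=text, tokens=tokenize(text))
    assert sent.tokens == tokens, (sent.tokens, tokens)
    sent.mentions = extract_residue_mentions(sent)
    return sent, sexpr


def generate_corpus(recipe: CorpusRecipe) -> SyntheticCorpus:
    """Generate a labeled corpus with bracketed parse trees.

    Every abstract contains 1-3 residue-containing sentences, each
    sandwiched between optional context sentences.  The gold interface/
    non-interface label of each planted mention is returned alongside.
    """
    rng = random.Random(recipe.seed)
    near = _near_skeletons()
    plain = _plain_skeletons()
    ctx_kw = _context_skeletons()
    ctx_neutral = _neutral_context_skeletons()

    abstracts: list[AbstractRecord] = []
    trees: dict[tuple[str, int], ParseTree] = {}
    labels: list[MentionLabel] = []
    protein_names: dict[str, tuple[str, str]] = {}

    for c in range(recipe.n_complexes):
        complex_id = f"CPX{c:04d}"
        names = (f"Zyma{c:04d}", f"Zymb{c:04d}")
        protein_names[complex_id] = names
        used_numbers: set[int] = set()
        for a in range(recipe.abstracts_per_complex):
            abstract_id = f"{complex_id}-A{a}"
            qt = QueryType.AND if rng.random() < recipe.p_and_query else QueryType.OR
            sentences: list[Sentence] = []
            sexprs: list[str] = []

            n_mentions = rng.randint(1, 3)
            for _ in range(n_mentions):
                resname = rng.choice(AMINO3).title()
                resnum = rng.randint(5, 400)
                while resnum in used_numbers:
                    resnum = rng.randint(5, 400)
                used_numbers.add(resnum)
                rtok = f"{resname}{resnum}"
                is_interface = rng.random() < recipe.interface_mention_rate

                # residue-containing sentence
                if is_interface:
                    use_names = rng.random() < recipe.p_both_names_interface
                    pnames = names if use_names else ("Factor", "Partner")
                    if rng.random() < recipe.p_keyword_near_interface:
                        skel = rng.choice(near)(rtok, rng.choice(POSITIVE_FORMS),
                                                pnames)
                    else:
                        skel = rng.choice(plain)(rtok, pnames)
                else:
                    use_name = rng.random() < recipe.p_single_name_noninterface
                    pnames = ((names[rng.randrange(2)], "partner") if use_name
                              else ("Factor", "Partner"))
                    if rng.random() < recipe.p_negword_near_noninterface:
                        skel = rng.choice(near)(rtok, rng.choice(NEGATIVE_FORMS),
                                                pnames)
                    else:
                        skel = rng.choice(plain)(rtok, pnames)

                # context sentence (before or after, seeded)
                if is_interface:
                    if rng.random() < recipe.p_keyword_near_interface:
                        ctx = rng.choice(ctx_kw)(rng.choice(POSITIVE_FORMS), names)
                    else:
                        ctx = rng.choice(ctx_neutral)(names)
                else:
                    if rng.random() < recipe.p_negword_near_noninterface:
                        ctx = rng.choice(ctx_kw)(rng.choice(NEGATIVE_FORMS),
                                                 ("Factor", "Partner"))
                    else:
                        ctx = rng.choice(ctx_neutral)(names)

                group = [ctx, skel] if rng.random() < 0.5 else [skel, ctx]
                for sk in group:
                    idx = len(sentences)
                    sent, sexpr = _make_sentence(idx, sk)
                    sentences.append(sent)
                    sexprs.append(sexpr)
                    for m in sent.mentions:
                        labels.append(MentionLabel(
                            complex_id, abstract_id, idx,
                            m.residue_name, m.residue_number, is_interface))

            rec = AbstractRecord(abstract_id=abstract_id, query_type=qt,
                                 complex_id=complex_id, sentences=sentences)
            for sent, sexpr in zip(sentences, sexprs):
                tree = read_bracketed_tree(sexpr)
                sent.tree = tree
                trees[(abstract_id, sent.index)] = tree
            abstracts.append(rec)

    return SyntheticCorpus(recipe=recipe, abstracts=abstracts, trees=trees,
                           labels=labels, protein_names=protein_names)


# ---------------------------------------------------------------------------
# Toy structures
# ---------------------------------------------------------------------------

@dataclass
class ToyComplex:
    bound_receptor: StructureModel
    bound_ligand: StructureModel
    unbound_receptor: StructureModel
    unbound_ligand: StructureModel
    n_contacts: int
    receptor_offset: int
    ligand_offset: int

    def ligand_mapping(self) -> dict[tuple[int, str], tuple[int, str]]:
        """Unbound -> bound residue-key map for the ligand (known by
        construction: a pure numbering offset)."""
        bcid = next(iter(self.bound_ligand.chains))
        ucid = next(iter(self.unbound_ligand.chains))
        return {u.key: b.key for u, b in zip(self.unbound_ligand.chains[ucid],
                                             self.bound_ligand.chains[bcid])}


def _chain(names: list[str], ca: np.ndarray, cb: np.ndarray,
           start_number: int) -> list[Residue]:
    out = []
    for i, name in enumerate(names):
        atoms = [Atom("CA", "C", tuple(float(v) for v in ca[i])),
                 Atom("CB", "C", tuple(float(v) for v in cb[i]))]
        out.append(Residue(name=name, number=start_number + i, atoms=atoms))
    return out


def generate_toy_complex(
    n_res_receptor: int = 30,
    n_res_ligand: int = 20,
    n_contacts: int = 4,
    seed: int = 0,
    noise_sigma: float = 0.5,
    receptor_offset: int = 0,
    ligand_offset: int = 5,
) -> ToyComplex:
    """A bound receptor/ligand pair with exactly ``n_contacts`` residue
    pairs within 6 A, plus unbound monomers (isotropic Gaussian coordinate
    noise, renumbered, different chain IDs).

    Geometry: both chains are Ca traces along x at 3.8 A spacing; the
    first ``n_contacts`` ligand residues sit 5.0-5.2 A above their
    receptor counterparts, the rest 20 A away.  Pseudo side-chain CB atoms
    point away from the interface so they never add contacts.
    """
    if min(n_res_receptor, n_res_ligand) < 3:
        raise ValueError("chains need >= 3 residues")
    if n_contacts > min(n_res_receptor, n_res_ligand):
        raise ValueError("infeasible geometry: more contacts than residues")
    rng = np.random.default_rng(seed)
    rec_names = [AMINO3[i] for i in rng.integers(0, 20, n_res_receptor)]
    lig_names = [AMINO3[i] for i in rng.integers(0, 20, n_res_ligand)]

    x_rec = np.arange(n_res_receptor) * 3.8
    rec_ca = np.stack([x_rec, np.zeros_like(x_rec), np.zeros_like(x_rec)], 1)
    rec_cb = rec_ca + np.array([0.0, -1.5, 0.4])

    x_lig = np.arange(n_res_ligand) * 3.8
    y_lig = np.full(n_res_ligand, 20.0)
    y_lig[:n_contacts] = 5.0 + 0.05 * np.arange(n_contacts)  # distinct Ca-Ca
    lig_ca = np.stack([x_lig, y_lig, np.zeros(n_res_ligand)], 1)
    lig_cb = lig_ca + np.array([0.0, 1.5, 0.4])

    bound_receptor = StructureModel(
        chains={"A": _chain(rec_names, rec_ca, rec_cb, 1)}, name="bound_receptor")
    bound_ligand = StructureModel(
        chains={"B": _chain(lig_names, lig_ca, lig_cb, 1)}, name="bound_ligand")

    def noisy(ca, cb):
        return (ca + rng.normal(0, noise_sigma, ca.shape),
                cb + rng.normal(0, noise_sigma, cb.shape))

    u_rec_ca, u_rec_cb = noisy(rec_ca, rec_cb)
    u_lig_ca, u_lig_cb = noisy(lig_ca, lig_cb)
    unbound_receptor = StructureModel(
        chains={"R": _chain(rec_names, u_rec_ca, u_rec_cb, 1 + receptor_offset)},
        name="unbound_receptor")
    unbound_ligand = StructureModel(
        chains={"L": _chain(lig_names, u_lig_ca, u_lig_cb, 1 + ligand_offset)},
        name="unbound_ligand")

    return ToyComplex(bound_receptor, bound_ligand, unbound_receptor,
                      unbound_ligand, n_contacts, receptor_offset, ligand_offset)


# ---------------------------------------------------------------------------
# Pose sets
# ---------------------------------------------------------------------------

@dataclass
class PoseSet:
    poses: list          # list[DockPose] in raw rank order
    gold_irmsd: dict[str, float]
    reference_rotation: np.ndarray
    reference_translation: np.ndarray


def _random_rotation(rng: np.random.Generator, max_angle: float = np.pi) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0, max_angle)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def generate_pose_set(
    complex_: ToyComplex,
    n_poses: int = 500,
    fraction_near_native: float = 0.01,
    rmsd_spread: float = 2.0,
    seed: int = 0,
) -> PoseSet:
    """Seeded rigid-body matches of the unbound ligand against the bound
    receptor frame.

    ``fraction_near_native`` of the poses are small perturbations of the
    reference placement (rotations/translations sized by ``rmsd_spread``);
    the rest are large random transforms scattered around the receptor.
    The true i-RMSD of every pose, computed directly on the generated
    interface Ca coordinates, is recorded.
    """
    from .constraints import DockPose

    if n_poses < 1:
        raise ValueError("n_poses must be >= 1")
    rng = np.random.default_rng(seed)
    mapping = complex_.ligand_mapping()
    ucid = next(iter(complex_.unbound_ligand.chains))
    bcid = next(iter(complex_.bound_ligand.chains))
    u_res = complex_.unbound_ligand.chains[ucid]
    b_res = complex_.bound_ligand.chains[bcid]
    u_ca = np.array([r.atom("CA").xyz for r in u_res])
    b_ca = np.array([r.atom("CA").xyz for r in b_res])
    R0, t0, _ = superpose(u_ca, b_ca)
    reference = u_ca @ R0.T + t0
    iface_idx = np.arange(complex_.n_contacts)  # contacts are the first residues
    centroid = u_ca.mean(axis=0)
    rec_center = complex_.bound_receptor.heavy_coords().mean(axis=0)

    n_native = max(0, round(n_poses * fraction_near_native))
    poses, gold = [], {}
    specs = []
    for i in range(n_poses):
        if i < n_native:
            if i == 0:
                dR, dt = np.eye(3), np.zeros(3)  # one exact-reference pose
            else:
                dR = _random_rotation(rng, max_angle=rmsd_spread * 0.05)
                dt = rng.normal(0, rmsd_spread / np.sqrt(3.0), 3)
            R = dR @ R0
            t = dR @ (t0 - (R0 @ centroid + t0)) + (R0 @ centroid + t0) + dt
            # rotate about the placed ligand centroid, then translate
            specs.append((R, t))
        else:
            R = _random_rotation(rng) @ R0
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            target = rec_center + direction * rng.uniform(15.0, 45.0)
            t = target - R @ centroid
            specs.append((R, t))

    order = rng.permutation(n_poses)
    for rank, idx in enumerate(order):
        R, t = specs[idx]
        pose = DockPose(pose_id=f"pose{idx:04d}", rotation=R, translation=t,
                        raw_score=float(rng.uniform(0, 100)), rank=rank)
        docked = u_ca[iface_idx] @ R.T + t
        gold[pose.pose_id] = float(np.sqrt(
            ((docked - reference[iface_idx]) ** 2).sum(axis=1).mean()))
        poses.append(pose)
    return PoseSet(poses=poses, gold_irmsd=gold,
                   reference_rotation=R0, reference_translation=t0)
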
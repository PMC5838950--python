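"""Docking constraints from mined residues, pose rescoring, and i-RMSD.

Each retained residue becomes a docking constraint with a confidence
``f`` between 1 (low) and 10 (high).  The basic scheme sums abstract
provenance weights::

    f(R) = min(10, sum_i a_i),   a_i = 2 (AND-query) or 1 (OR-query only)

The NLP scheme re-ranks within provenance categories, keeping the [1, 10]
range and AND precedence over OR::

    f(R) = 10  if some AND-retrieved abstract passes the NLP filter
           8   if R appears in an AND-retrieved abstract
           6   if some OR-retrieved abstract passes the NLP filter
           max(5, number of abstracts mentioning R)  otherwise (capped at 10)

The top five residues per protein are used as constraints.  *Reference*
constraints — the ceiling for any text-derived scheme — are the three
interface residue pairs of the co-crystallized complex with the smallest
Ca-Ca distances, each at f = 10.

Docking matches are rescored by the sum of the f values of constrained
residues found at the match's predicted interface (6 A heavy-atom rule);
with no constraints every score is zero and the original order stands.
Match quality is the ligand interface Ca RMSD (i-RMSD) against the
reference placement obtained by superimposing the unbound ligand onto the
bound ligand; success means at least one match with i-RMSD <= 5 A among
the top 10.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, TextIO

import numpy as np

from .structure import (
    INTERFACE_CUTOFF,
    StructureModel,
    interface_pairs,
    interface_residues,
    map_unbound_to_bound,
    superpose,
)
from .textcorpus import QueryType

__all__ = [
    "Evidence",
    "Constraint",
    "DockPose",
    "ReferencePair",
    "confidence_basic",
    "confidence_nlp",
    "select_constraints",
    "reference_constraints",
    "pose_interface",
    "rescore_poses",
    "irmsd",
    "success_rate",
    "write_constraints",
    "read_constraints",
    "SUCCESS_IRMSD",
    "SUCCESS_TOP_N",
]

SUCCESS_IRMSD = 5.0
SUCCESS_TOP_N = 10
TOP_K_CONSTRAINTS = 5
REFERENCE_PAIRS = 3


@dataclass(frozen=True)
class Evidence:
    """One abstract mentioning a residue: its provenance and whether it
    survived the configured NLP filter."""

    abstract_id: str
    query_type: QueryType
    nlp_pass: bool = False


@dataclass(frozen=True)
class Constraint:
    protein_role: str          # "receptor" | "ligand"
    chain_id: str
    residue_number: int
    f: float
    residue_name: str = ""
    evidence_ids: tuple[str, ...] = ()

    def __post_init__(self):
        if self.protein_role not in ("receptor", "ligand"):
            raise ValueError("protein_role must be 'receptor' or 'ligand'")
        if not (1.0 <= self.f <= 10.0):
            raise ValueError(f"confidence f={self.f} outside [1, 10]")


@dataclass(frozen=True)
class ReferencePair:
    receptor_chain: str
    receptor_residue: int
    ligand_chain: str
    ligand_residue: int
    ca_distance: float


@dataclass
class DockPose:
    """One rigid-body docking match: a rotation/translation applied to the
    unbound ligand, with the raw docking score and rank."""

    pose_id: str
    rotation: np.ndarray       # 3x3
    translation: np.ndarray    # 3
    raw_score: float = 0.0
    rank: int = 0

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ np.asarray(self.rotation, float).T \
            + np.asarray(self.translation, float)


# ---------------------------------------------------------------------------
# Confidence schemes
# ---------------------------------------------------------------------------

def confidence_basic(evidence: Sequence[Evidence]) -> float:
    """Capped provenance sum: AND-query abstracts weigh 2, OR-only weigh 1."""
    if not evidence:
        raise ValueError("residue has no abstract evidence")
    total = sum(2 if e.query_type == QueryType.AND else 1 for e in evidence)
    return float(min(10, total))


def confidence_nlp(evidence: Sequence[Evidence]) -> float:
    """Category re-ranking: AND+NLP (10) > AND (8) > OR+NLP (6) >
    max(5, abstract count), the fallback capped at 10 to preserve the
    [1, 10] range and AND precedence."""
    if not evidence:
        raise ValueError("residue has no abstract evidence")
    has_and_pass = any(e.query_type == QueryType.AND and e.nlp_pass for e in evidence)
    has_and = any(e.query_type == QueryType.AND for e in evidence)
    has_or_pass = any(e.query_type == QueryType.OR and e.nlp_pass for e in evidence)
    if has_and_pass:
        return 10.0
    if has_and:
        return 8.0
    if has_or_pass:
        return 6.0
    return float(min(10, max(5, len(evidence))))


@dataclass(frozen=True)
class ScoredResidue:
    protein_role: str
    chain_id: str
    residue_number: int
    f: float
    residue_name: str = ""
    evidence: tuple[Evidence, ...] = ()

    @property
    def and_derived(self) -> bool:
        return any(e.query_type == QueryType.AND for e in self.evidence)


def select_constraints(
    scored: Sequence[ScoredResidue], k: int = TOP_K_CONSTRAINTS
) -> list[Constraint]:
    """Top-k residues by confidence.  Ties break deterministically:
    AND-derived before OR-derived, then more supporting abstracts, then
    lower residue number."""
    ranked = sorted(
        scored,
        key=lambda r: (-r.f, not r.and_derived, -len(r.evidence), r.residue_number))
    return [
        Constraint(protein_role=r.protein_role, chain_id=r.chain_id,
                   residue_number=r.residue_number, f=r.f,
                   residue_name=r.residue_name,
                   evidence_ids=tuple(e.abstract_id for e in r.evidence))
        for r in ranked[:k]
    ]


# ---------------------------------------------------------------------------
# Reference constraints from the bound complex
# ---------------------------------------------------------------------------

def reference_constraints(
    receptor: StructureModel,
    ligand: StructureModel,
    k: int = REFERENCE_PAIRS,
    cutoff: float = INTERFACE_CUTOFF,
) -> tuple[list[ReferencePair], list[Constraint]]:
    """The k interface residue pairs with the smallest Ca-Ca distances,
    emitted as f=10 constraints on both sides.

    Fewer than k available pairs returns what exists with a warning.
    """
    import warnings

    pairs = []
    for (rcid, rres), (lcid, lres) in interface_pairs(receptor, ligand, cutoff):
        ca_r, ca_l = rres.atom("CA"), lres.atom("CA")
        if ca_r is None or ca_l is None:
            continue
        d = float(np.linalg.norm(ca_r.xyz - ca_l.xyz))
        pairs.append(ReferencePair(rcid, rres.number, lcid, lres.number, d))
    pairs.sort(key=lambda p: (p.ca_distance, p.receptor_residue, p.ligand_residue))
    top = pairs[:k]
    if len(top) < k:
        warnings.warn(f"only {len(top)} interface pairs available (wanted {k})")
    constraints: list[Constraint] = []
    seen = set()
    for p in top:
        for role, cid, num in (("receptor", p.receptor_chain, p.receptor_residue),
                               ("ligand", p.ligand_chain, p.ligand_residue)):
            if (role, cid, num) not in seen:
                seen.add((role, cid, num))
                constraints.append(Constraint(role, cid, num, 10.0))
    return top, constraints


# ---------------------------------------------------------------------------
# Pose rescoring
# ---------------------------------------------------------------------------

def pose_interface(
    pose: DockPose,
    receptor: StructureModel,
    ligand: StructureModel,
    cutoff: float = INTERFACE_CUTOFF,
) -> set[tuple[str, str, int]]:
    """Residues at the match's predicted interface, as
    (role, chain_id, residue_number) on both sides, using the same 6 A
    heavy-atom rule as the bound-interface definition."""
    from scipy.spatial import cKDTree

    rec_coords = receptor.heavy_coords()
    if not len(rec_coords):
        return set()
    rec_tree = cKDTree(rec_coords)

    out: set[tuple[str, str, int]] = set()
    lig_pts, lig_keys = [], []
    for cid, res in ligand.residues():
        pts = pose.transform(res.heavy_coords())
        if len(pts):
            lig_pts.append(pts)
            lig_keys.extend([("ligand", cid, res.number)] * len(pts))
    if not lig_pts:
        return set()
    lig_all = np.vstack(lig_pts)
    lig_tree = cKDTree(lig_all)

    for i, neighbors in enumerate(rec_tree.query_ball_tree(lig_tree, cutoff)):
        for j in neighbors:
            out.add(lig_keys[j])
    # receptor side
    offset = 0
    rec_keys = []
    for cid, res in receptor.residues():
        n = len(res.heavy_coords())
        rec_keys.extend([("receptor", cid, res.number)] * n)
    for i, neighbors in enumerate(lig_tree.query_ball_tree(rec_tree, cutoff)):
        for j in neighbors:
            out.add(rec_keys[j])
    return out


def rescore_poses(
    poses: Sequence[DockPose],
    constraints: Sequence[Constraint],
    receptor: StructureModel,
    ligand: StructureModel,
    cutoff: float = INTERFACE_CUTOFF,
) -> list[tuple[DockPose, float]]:
    """Score each match by the sum of f over constrained residues at its
    predicted interface, then sort descending with the raw order as stable
    tie-break.  No constraints -> all scores zero, order unchanged."""
    scored = []
    cset = {(c.protein_role, c.chain_id, c.residue_number): c.f for c in constraints}
    for pose in poses:
        if cset:
            iface = pose_interface(pose, receptor, ligand, cutoff)
            s = sum(f for key, f in cset.items() if key in iface)
        else:
            s = 0.0
        scored.append((pose, float(s)))
    scored.sort(key=lambda ps: -ps[1])  # stable: raw order preserved on ties
    return scored


# ---------------------------------------------------------------------------
# i-RMSD and success rate
# ---------------------------------------------------------------------------

def irmsd(
    pose: DockPose,
    bound_receptor: StructureModel,
    bound_ligand: StructureModel,
    unbound_ligand: StructureModel,
    mapping: dict | None = None,
    cutoff: float = INTERFACE_CUTOFF,
) -> float:
    """Ligand interface Ca RMSD of a docking match.

    The unbound ligand is least-squares superimposed (all mapped Ca atoms)
    onto the bound ligand of the co-crystallized complex; that placement is
    the reference.  The i-RMSD is then the RMSD over interface Ca atoms
    between the posed unbound ligand and the reference placement, with no
    further fitting.  Interface residues are those of the bound ligand
    within ``cutoff`` of the bound receptor, carried to the unbound chain
    through the residue ``mapping`` (computed by sequence alignment when
    not supplied).
    """
    lig_cid_u = _single_chain(unbound_ligand)
    lig_cid_b = _single_chain(bound_ligand)
    if mapping is None:
        mapping = map_unbound_to_bound(unbound_ligand, bound_ligand,
                                       lig_cid_u, lig_cid_b)
    bound_by_key = {r.key: r for r in bound_ligand.chains[lig_cid_b]}
    _, lig_iface = interface_residues(bound_receptor, bound_ligand, cutoff)
    iface_numbers = {num for (cid, num) in lig_iface.interface_residues
                     if cid == lig_cid_b}

    unb_all, bnd_all = [], []
    unb_iface = []
    for res in unbound_ligand.chains[lig_cid_u]:
        bkey = mapping.get(res.key)
        if bkey is None:
            continue
        bres = bound_by_key.get(bkey)
        ca_u = res.atom("CA")
        ca_b = bres.atom("CA") if bres is not None else None
        if ca_u is None or ca_b is None:
            continue
        unb_all.append(ca_u.xyz)
        bnd_all.append(ca_b.xyz)
        if bres.number in iface_numbers:
            unb_iface.append(ca_u.xyz)
    if len(unb_iface) < 3:
        raise ValueError(
            f"only {len(unb_iface)} interface Ca correspondences (need >= 3)")
    R0, t0, _ = superpose(np.array(unb_all), np.array(bnd_all))
    unb_iface = np.array(unb_iface)
    reference = unb_iface @ R0.T + t0
    docked = pose.transform(unb_iface)
    return float(np.sqrt(((docked - reference) ** 2).sum(axis=1).mean()))


def _single_chain(model: StructureModel) -> str:
    if len(model.chains) != 1:
        raise ValueError("expected a single-chain model")
    return next(iter(model.chains))


def success_rate(
    ranked_irmsds_per_complex: Sequence[Sequence[float]],
    threshold: float = SUCCESS_IRMSD,
    top_n: int = SUCCESS_TOP_N,
) -> float:
    """Fraction of complexes with >= 1 match at i-RMSD <= ``threshold``
    (non-strict) within the ``top_n`` best-ranked matches."""
    if not ranked_irmsds_per_complex:
        raise ValueError("no complexes supplied")
    hits = sum(
        1 for irmsds in ranked_irmsds_per_complex
        if any(v <= threshold for v in list(irmsds)[:top_n]))
    return hits / len(ranked_irmsds_per_complex)


# ---------------------------------------------------------------------------
# Constraint file I/O
# ---------------------------------------------------------------------------

def write_constraints(constraints: Iterable[Constraint], stream: TextIO) -> None:
    stream.write("role\tchain\tresnum\tresname\tf\tevidence\n")
    for c in constraints:
        ev = ",".join(c.evidence_ids)
        stream.write(f"{c.protein_role}\t{c.chain_id}\t{c.residue_number}"
                     f"\t{c.residue_name}\t{c.f:g}\t{ev}\n")


def read_constraints(stream: TextIO) -> list[Constraint]:
    out = []
    for i, raw in enumerate(stream):
        line = raw.rstrip("\n")
        if not line or (i == 0 and line.startswith("role\t")):
            continue
        role, chain, num, name, f, ev = (line.split("\t") + [""])[:6]
        out.append(Constraint(role, chain, int(num), float(f), name,
                              tuple(e for e in ev.split(",") if e)))
    return out
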
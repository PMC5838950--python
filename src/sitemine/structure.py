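"""Protein-structure support for validating mined residues.

A mined residue survives the basic structural filter only if (i) its name
and author number correspond to a residue in the PDB file and (ii) that
residue sits on the protein surface.  Interface residues of the
co-crystallized complex — any residue with a heavy atom within 6 A of the
partner — provide the ground truth for evaluating the text-mining output
and the reference docking constraints.  Because unbound and bound
structures frequently disagree in residue numbering and chain IDs,
residues are matched to the bound protein through a global sequence
alignment.

Parsing goes through Bio.PDB; solvent accessibility uses the
Shrake-Rupley algorithm (probe 1.4 A) normalized by extended-state
reference areas.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, TextIO

import numpy as np

from .textcorpus import AMINO3, AMINO3TO1, ResidueMention

__all__ = [
    "Atom",
    "Residue",
    "StructureModel",
    "InterfaceAnnotation",
    "read_structure",
    "write_structure",
    "match_mention",
    "is_surface",
    "interface_residues",
    "map_unbound_to_bound",
    "superpose",
    "INTERFACE_CUTOFF",
    "RSASA_THRESHOLD",
]

#: Atom-atom distance (A) defining interface residues across the complex.
INTERFACE_CUTOFF = 6.0

#: Relative SASA at or above which a residue counts as surface-exposed.
RSASA_THRESHOLD = 0.05

#: Reference (extended-state) per-residue solvent-accessible areas in A^2,
#: theoretical maxima of Tien et al. (2013), used to normalize SASA.
MAX_ASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coord: tuple[float, float, float]

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coord, dtype=float)

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


@dataclass
class Residue:
    name: str          # canonical 3-letter code
    number: int        # author numbering, as printed in the PDB file
    icode: str = ""    # insertion code
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[int, str]:
        return (self.number, self.icode)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_coords(self) -> np.ndarray:
        pts = [a.coord for a in self.atoms if a.is_heavy]
        return np.asarray(pts, dtype=float).reshape(-1, 3)


@dataclass
class StructureModel:
    """Chains of standard amino-acid residues with atom coordinates."""

    chains: dict[str, list[Residue]] = field(default_factory=dict)
    name: str = ""

    def residues(self) -> Iterable[tuple[str, Residue]]:
        for cid, res_list in self.chains.items():
            for res in res_list:
                yield cid, res

    def n_residues(self) -> int:
        return sum(len(v) for v in self.chains.values())

    def chain(self, cid: str) -> list[Residue]:
        return self.chains[cid]

    def find(self, chain_id: str, number: int, icode: str = "") -> Residue | None:
        for res in self.chains.get(chain_id, ()):
            if res.number == number and res.icode == icode:
                return res
        return None

    def sequence(self, chain_id: str) -> str:
        return "".join(AMINO3TO1.get(r.name, "X") for r in self.chains[chain_id])

    def heavy_coords(self, chain_id: str | None = None) -> np.ndarray:
        chains = [chain_id] if chain_id else list(self.chains)
        pts = []
        for cid in chains:
            for res in self.chains[cid]:
                pts.append(res.heavy_coords())
        return np.vstack(pts) if pts else np.empty((0, 3))


@dataclass
class InterfaceAnnotation:
    """Interface membership for one partner of a complex."""

    interface_residues: frozenset[tuple[str, int]]  # (chain_id, residue_number)
    cutoff: float = INTERFACE_CUTOFF

    def __contains__(self, item: tuple[str, int]) -> bool:
        return item in self.interface_residues

    def __len__(self) -> int:
        return len(self.interface_residues)


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def read_structure(stream: TextIO | str, name: str = "") -> StructureModel:
    """Parse PDB-format text into a :class:`StructureModel`.

    Only the first model of multi-model files is used; only the 20 standard
    amino acids are retained; alternate locations are resolved to the
    highest-occupancy conformer (ties -> first encountered).
    """
    from Bio.PDB import PDBParser

    if isinstance(stream, str):
        stream = io.StringIO(stream)
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bio_structure = parser.get_structure(name or "model", stream)
    models = list(bio_structure)
    if not models:
        raise ValueError("no ATOM records found")
    model = StructureModel(name=name)
    for chain in models[0]:
        residues = []
        for res in chain:
            resname = res.get_resname().strip().upper()
            if resname not in AMINO3:
                continue
            _, number, icode = res.get_id()
            atoms = _resolve_altlocs(res)
            if atoms:
                residues.append(Residue(name=resname, number=number,
                                        icode=icode.strip(), atoms=atoms))
        if residues:
            model.chains[chain.id] = residues
    if model.n_residues() == 0:
        raise ValueError("no standard amino-acid ATOM records found")
    return model


def _resolve_altlocs(bio_res) -> list[Atom]:
    groups: dict[str, list] = {}
    for atom in bio_res.get_unpacked_list():
        groups.setdefault(atom.get_name(), []).append(atom)
    atoms = []
    for name, alts in groups.items():
        best = max(alts, key=lambda a: (a.get_occupancy() or 0.0))
        # max() keeps the first of equal-occupancy conformers
        x, y, z = best.get_coord()
        element = (best.element or name[0]).strip() or name[0]
        atoms.append(Atom(name=name, element=element,
                          coord=(float(x), float(y), float(z))))
    return atoms


def write_structure(model: StructureModel, stream: TextIO) -> None:
    """Write minimal PDB-format ATOM/TER records (round-trips with
    :func:`read_structure`)."""
    serial = 1
    for cid, residues in model.chains.items():
        for res in residues:
            for atom in res.atoms:
                stream.write(
                    "ATOM  {serial:>5} {name:<4}{alt}{res:<3} {chain}{num:>4}"
                    "{icode}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
                    "          {el:>2}\n".format(
                        serial=serial, name=_pad_atom_name(atom.name), alt=" ",
                        res=res.name, chain=cid, num=res.number,
                        icode=res.icode or " ", x=atom.coord[0], y=atom.coord[1],
                        z=atom.coord[2], occ=1.0, b=0.0, el=atom.element))
                serial += 1
        stream.write(f"TER   {serial:>5}      {residues[-1].name:<3} {cid}"
                     f"{residues[-1].number:>4}\n")
        serial += 1
    stream.write("END\n")


def _pad_atom_name(name: str) -> str:
    # PDB columns 13-16: 1-letter elements start at column 14
    return f" {name:<3}" if len(name) < 4 else name


# ---------------------------------------------------------------------------
# Mention <-> structure correspondence and surface filter
# ---------------------------------------------------------------------------

def match_mention(mention: ResidueMention, model: StructureModel) -> tuple[str, Residue] | None:
    """Find the structure residue matching a mention by author number and
    3-letter name; a chain hint restricts the search to that chain."""
    chains = [mention.chain_hint] if mention.chain_hint else list(model.chains)
    for cid in chains:
        for res in model.chains.get(cid, ()):
            if res.number == mention.residue_number and res.name == mention.residue_name:
                return (cid, res)
    return None


def _compute_sasa(model: StructureModel, n_points: int = 960) -> dict[tuple[str, int, str], float]:
    """Per-residue Shrake-Rupley SASA (A^2) of the model in isolation."""
    from Bio.PDB.SASA import ShrakeRupley
    from Bio.PDB.StructureBuilder import StructureBuilder

    builder = StructureBuilder()
    builder.init_structure("m")
    builder.init_model(0)
    builder.init_seg(" ")
    serial = 1
    for cid, residues in model.chains.items():
        builder.init_chain(cid)
        for res in residues:
            builder.init_residue(res.name, " ", res.number, res.icode or " ")
            for atom in res.atoms:
                builder.init_atom(atom.name, np.asarray(atom.coord, float), 0.0,
                                  1.0, " ", _pad_atom_name(atom.name), serial,
                                  element=atom.element.upper())
                serial += 1
    struct = builder.get_structure()
    ShrakeRupley(probe_radius=1.4, n_points=n_points).compute(struct, level="R")
    out = {}
    for chain in struct[0]:
        for bio_res in chain:
            _, num, icode = bio_res.get_id()
            out[(chain.id, num, icode.strip())] = float(bio_res.sasa)
    return out


class SurfaceCalculator:
    """Caches one SASA computation per model for repeated surface queries."""

    def __init__(self, model: StructureModel, n_points: int = 960):
        self.model = model
        self._sasa = _compute_sasa(model, n_points=n_points)

    def rsasa(self, chain_id: str, residue: Residue) -> float:
        sasa = self._sasa[(chain_id, residue.number, residue.icode)]
        if len(residue.atoms) <= 2:
            warnings.warn(
                f"residue {residue.name}{residue.number} has no side-chain "
                "atoms; rSASA computed on available atoms")
        return sasa / MAX_ASA[residue.name]

    def is_surface(self, chain_id: str, residue: Residue,
                   threshold: float = RSASA_THRESHOLD) -> bool:
        return self.rsasa(chain_id, residue) >= threshold


def is_surface(
    residue: Residue,
    model: StructureModel,
    chain_id: str | None = None,
    rsasa_threshold: float = RSASA_THRESHOLD,
    calculator: SurfaceCalculator | None = None,
) -> bool:
    """Whether a residue is solvent-exposed (relative SASA >= threshold).

    A threshold of 0 accepts every residue.  For repeated queries on one
    model pass a shared :class:`SurfaceCalculator`.
    """
    if chain_id is None:
        for cid, res in model.residues():
            if res is residue:
                chain_id = cid
                break
        else:
            raise ValueError("residue not found in model")
    calc = calculator or SurfaceCalculator(model)
    return calc.is_surface(chain_id, residue, threshold=rsasa_threshold)


# ---------------------------------------------------------------------------
# Interface definition
# ---------------------------------------------------------------------------

def interface_residues(
    receptor: StructureModel,
    ligand: StructureModel,
    cutoff: float = INTERFACE_CUTOFF,
) -> tuple[InterfaceAnnotation, InterfaceAnnotation]:
    """Interface residues of each partner: any heavy atom within ``cutoff``
    of any heavy atom of the other partner.  Symmetric by construction."""
    from scipy.spatial import cKDTree

    if receptor.n_residues() == 0 or ligand.n_residues() == 0:
        raise ValueError("both models must be non-empty")
    lig_coords = ligand.heavy_coords()
    rec_coords = receptor.heavy_coords()
    if cutoff <= 0 or len(lig_coords) == 0 or len(rec_coords) == 0:
        empty = frozenset()
        return (InterfaceAnnotation(empty, cutoff), InterfaceAnnotation(empty, cutoff))
    lig_tree = cKDTree(lig_coords)
    rec_tree = cKDTree(rec_coords)

    def _side(model: StructureModel, other_tree: cKDTree) -> frozenset:
        hits = set()
        for cid, res in model.residues():
            pts = res.heavy_coords()
            if not len(pts):
                continue
            for neighbors in other_tree.query_ball_point(pts, cutoff):
                if neighbors:
                    hits.add((cid, res.number))
                    break
        return frozenset(hits)

    rec_set = _side(receptor, lig_tree)
    lig_set = _side(ligand, rec_tree)
    return (InterfaceAnnotation(rec_set, cutoff), InterfaceAnnotation(lig_set, cutoff))


def interface_pairs(
    receptor: StructureModel,
    ligand: StructureModel,
    cutoff: float = INTERFACE_CUTOFF,
) -> list[tuple[tuple[str, Residue], tuple[str, Residue]]]:
    """All residue pairs across the interface (any heavy-atom contact
    within ``cutoff``)."""
    pairs = []
    for rcid, rres in receptor.residues():
        rpts = rres.heavy_coords()
        for lcid, lres in ligand.residues():
            lpts = lres.heavy_coords()
            if rpts.size and lpts.size:
                d2 = ((rpts[:, None, :] - lpts[None, :, :]) ** 2).sum(-1)
                if (d2 <= cutoff * cutoff).any():
                    pairs.append(((rcid, rres), (lcid, lres)))
    return pairs


# ---------------------------------------------------------------------------
# Unbound <-> bound residue mapping
# ---------------------------------------------------------------------------

def map_unbound_to_bound(
    unbound: list[Residue] | StructureModel,
    bound: list[Residue] | StructureModel,
    unbound_chain: str | None = None,
    bound_chain: str | None = None,
    min_identity: float = 0.30,
) -> dict[tuple[int, str], tuple[int, str]]:
    """Residue correspondence between an unbound chain and its bound
    counterpart via global sequence alignment (identity scoring, affine
    gaps).

    Returns a map from unbound ``(number, icode)`` to bound ``(number,
    icode)``; positions unaligned or with mismatched residue types are
    absent.  Raises if alignment identity falls below ``min_identity``.
    """
    from Bio import Align

    unb = _as_chain(unbound, unbound_chain)
    bnd = _as_chain(bound, bound_chain)
    seq_u = "".join(AMINO3TO1.get(r.name, "X") for r in unb)
    seq_b = "".join(AMINO3TO1.get(r.name, "X") for r in bnd)
    if not seq_u or not seq_b:
        raise ValueError("cannot extract sequences for alignment")

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    alignment = aligner.align(seq_u, seq_b)[0]

    mapping: dict[tuple[int, str], tuple[int, str]] = {}
    identical = 0
    aligned_u = alignment.aligned[0]
    aligned_b = alignment.aligned[1]
    for (us, ue), (bs, be) in zip(aligned_u, aligned_b):
        for k in range(ue - us):
            iu, ib = us + k, bs + k
            if seq_u[iu] == seq_b[ib]:
                identical += 1
                mapping[unb[iu].key] = bnd[ib].key
    identity = identical / min(len(seq_u), len(seq_b))
    if identity < min_identity:
        raise ValueError(
            f"chains do not correspond (sequence identity {identity:.0%} "
            f"below {min_identity:.0%})")
    return mapping


def _as_chain(model, chain_id: str | None) -> list[Residue]:
    if isinstance(model, StructureModel):
        if chain_id is None:
            if len(model.chains) != 1:
                raise ValueError("chain_id required for multi-chain model")
            chain_id = next(iter(model.chains))
        return model.chains[chain_id]
    return list(model)


# ---------------------------------------------------------------------------
# Rigid-body superposition (Kabsch)
# ---------------------------------------------------------------------------

def superpose(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``target``.
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    if mobile.shape != target.shape or mobile.shape[0] < 3:
        raise ValueError("superpose needs two equal point sets of >= 3 points")
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    H = (mobile - mc).T @ (target - tc)
    U, _S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = tc - R @ mc
    moved = mobile @ R.T + t
    rmsd = float(np.sqrt(((moved - target) ** 2).sum(axis=1).mean()))
    return R, t, rmsd
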
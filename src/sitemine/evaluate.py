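"""Text-mining performance metrics over complexes.

For one complex, the per-target performance is the fraction of retained
mined residues that are true interface residues, pooled over abstracts::

    P_TM = sum_i N_i_int / sum_i (N_i_int + N_i_non)

where the sums run over the N residue-containing abstracts retrieved for
the complex and abstracts whose residues were all purged are excluded.  A
complex with every abstract purged has no defined P_TM and is excluded
from the distribution.

Two filtering algorithms are compared through the shape of their P_TM
distributions::

    deltaN(P_TM) = N_tar_X1(P_TM) - N_tar_X2(P_TM)

the difference in the number of target complexes at a given P_TM value.
N(0) counts complexes with only false positives, N(1) those with only true
positives; an effective filter drives deltaN(0) negative and deltaN(1)
positive against the baseline.  Endpoint counts use exact P_TM values;
10 right-closed equal bins are used for histogram plots.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

__all__ = [
    "AbstractPool",
    "ComplexResiduePool",
    "PtmDistribution",
    "AggregateStats",
    "ptm",
    "delta_n",
    "aggregate_stats",
]

_EPS = 1e-9


@dataclass
class AbstractPool:
    """Retained mentions of one abstract, flagged interface/non-interface."""

    abstract_id: str
    n_interface: int = 0
    n_noninterface: int = 0

    @property
    def n_retained(self) -> int:
        return self.n_interface + self.n_noninterface


@dataclass
class ComplexResiduePool:
    """Per-abstract retained-mention counts for one complex under one
    filtering algorithm."""

    complex_id: str
    abstracts: list[AbstractPool] = field(default_factory=list)

    def add(self, abstract_id: str, n_interface: int, n_noninterface: int) -> None:
        self.abstracts.append(AbstractPool(abstract_id, n_interface, n_noninterface))

    @property
    def contributing(self) -> list[AbstractPool]:
        """Abstracts with >= 1 retained mention (others are excluded)."""
        return [a for a in self.abstracts if a.n_retained > 0]


def ptm(pool: ComplexResiduePool) -> float | None:
    """The complex's P_TM, or None when every abstract was fully purged."""
    used = pool.contributing
    if not used:
        return None
    n_int = sum(a.n_interface for a in used)
    n_tot = sum(a.n_retained for a in used)
    return n_int / n_tot


@dataclass
class PtmDistribution:
    """Per-complex P_TM values for one filtering algorithm."""

    algorithm: str
    values: dict[str, float] = field(default_factory=dict)  # complex_id -> P_TM

    @classmethod
    def from_pools(cls, algorithm: str,
                   pools: Iterable[ComplexResiduePool]) -> "PtmDistribution":
        dist = cls(algorithm)
        for pool in pools:
            p = ptm(pool)
            if p is not None:
                dist.values[pool.complex_id] = p
        return dist

    def n_at(self, p: float) -> int:
        """Number of complexes whose P_TM equals ``p`` exactly (used for
        the endpoint counts N(0) and N(1))."""
        return sum(1 for v in self.values.values() if abs(v - p) < _EPS)

    def histogram(self, bins: int = 10) -> list[int]:
        """Right-closed equal bins over [0, 1]; 0 falls in the first bin."""
        counts = [0] * bins
        for v in self.values.values():
            idx = 0 if v <= 0 else min(bins - 1, int((v - _EPS) * bins))
            counts[idx] += 1
        return counts

    def __len__(self) -> int:
        return len(self.values)


def delta_n(dist_x1: PtmDistribution, dist_x2: PtmDistribution, p: float) -> int:
    """Difference in the number of complexes at P_TM = ``p`` between two
    algorithms (antisymmetric in its arguments)."""
    return dist_x1.n_at(p) - dist_x2.n_at(p)


class AggregateStats(NamedTuple):
    l_tot: int               # complexes with >= 1 retained-residue abstract
    l_int: int               # complexes with >= 1 interface residue found
    coverage: float | None   # l_tot / total_complexes
    success: float | None    # l_int / total_complexes
    accuracy: float | None   # l_int / l_tot


def aggregate_stats(
    pools: Sequence[ComplexResiduePool], total_complexes: int
) -> AggregateStats:
    """Corpus-level summary mirroring the per-dictionary benchmark columns."""
    if total_complexes < len(pools):
        raise ValueError("total_complexes smaller than the number of pools")
    l_tot = sum(1 for p in pools if p.contributing)
    l_int = sum(1 for p in pools
                if any(a.n_interface > 0 for a in p.contributing))
    coverage = l_tot / total_complexes if total_complexes else None
    success = l_int / total_complexes if total_complexes else None
    accuracy = l_int / l_tot if l_tot else None
    return AggregateStats(l_tot, l_int, coverage, success, accuracy)


def write_report(
    dists: Sequence[PtmDistribution],
    pools_by_algorithm: dict[str, Sequence[ComplexResiduePool]],
    total_complexes: int,
    stream,
) -> None:
    """Tab-separated per-complex metrics plus a summary block."""
    stream.write("complex_id\talgorithm\tP_TM\tn_int\tn_non\n")
    for dist in dists:
        pools = {p.complex_id: p for p in pools_by_algorithm[dist.algorithm]}
        for cid, v in sorted(dist.values.items()):
            used = pools[cid].contributing
            n_int = sum(a.n_interface for a in used)
            n_non = sum(a.n_noninterface for a in used)
            stream.write(f"{cid}\t{dist.algorithm}\t{v:.4f}\t{n_int}\t{n_non}\n")
    stream.write("\n# summary: algorithm\tL_tot\tL_int\tcoverage\tsuccess\taccuracy\n")
    for dist in dists:
        stats = aggregate_stats(list(pools_by_algorithm[dist.algorithm]),
                                total_complexes)
        cov = f"{stats.coverage:.3f}" if stats.coverage is not None else "NA"
        suc = f"{stats.success:.3f}" if stats.success is not None else "NA"
        acc = f"{stats.accuracy:.3f}" if stats.accuracy is not None else "NA"
        stream.write(f"# {dist.algorithm}\t{stats.l_tot}\t{stats.l_int}"
                     f"\t{cov}\t{suc}\t{acc}\n")
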
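"""End-to-end orchestration: extraction -> structural filter -> advanced
NLP filter -> evaluation -> constraints.

The stages run in the flowchart order of the mining protocol: residue
mentions are extracted from abstracts, validated against the protein
structures (name/number correspondence, surface exposure) when structures
are available, then purged by the selected advanced filter.  Every mention
ends up in exactly one :class:`MentionDecision` — retained or dropped,
with the stage and rule that decided it — so the union of retained and
dropped mentions always equals the extracted pool.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Iterable, Sequence

from .classify import TrainedModel, build_features, method3_filter
from .constraints import Evidence, ScoredResidue, confidence_basic, confidence_nlp
from .deepparse import method1_filter, method2_filter
from .evaluate import ComplexResiduePool
from .lexicon import (
    DEFAULT_CONCEPT_WORDS,
    KeywordDictionary,
    SimilarityProvider,
    SimilarityThresholds,
    dictionary_filter,
    similarity_filter,
)
from .structure import StructureModel, SurfaceCalculator, match_mention
from .textcorpus import AbstractRecord, QueryType, ResidueMention

__all__ = [
    "MentionDecision",
    "FILTER_METHODS",
    "extract_decisions",
    "apply_structure_filter",
    "apply_advanced_filter",
    "build_pools",
    "aggregate_evidence",
    "score_residues",
]

FILTER_METHODS = ("basic", "dictionary", "similarity:lesk", "similarity:lin",
                  "similarity:path", "method1", "method2", "method3")


@dataclass
class MentionDecision:
    complex_id: str
    abstract_id: str
    query_type: QueryType
    sentence_index: int
    mention: ResidueMention
    kept: bool = True
    stage: str = "extraction"
    rule: str = "extracted"

    @property
    def residue_key(self) -> tuple[str, int]:
        return self.mention.key


def extract_decisions(abstracts: Iterable[AbstractRecord]) -> list[MentionDecision]:
    """One decision row per extracted mention, all initially retained."""
    out = []
    for rec in abstracts:
        for sent in rec.sentences:
            for m in sent.mentions:
                out.append(MentionDecision(
                    complex_id=rec.complex_id, abstract_id=rec.abstract_id,
                    query_type=rec.query_type, sentence_index=sent.index,
                    mention=m))
    return out


def apply_structure_filter(
    decisions: Sequence[MentionDecision],
    models_by_complex: dict[str, StructureModel],
    rsasa_threshold: float = 0.05,
) -> list[MentionDecision]:
    """Drop mentions without a name/number correspondence in the complex's
    structure, or whose matched residue is buried."""
    calculators: dict[str, SurfaceCalculator] = {}
    out = []
    for d in decisions:
        if not d.kept or d.complex_id not in models_by_complex:
            out.append(d)
            continue
        model = models_by_complex[d.complex_id]
        hit = match_mention(d.mention, model)
        if hit is None:
            out.append(replace(d, kept=False, stage="structure",
                               rule="no-correspondence"))
            continue
        cid, res = hit
        calc = calculators.setdefault(d.complex_id, SurfaceCalculator(model))
        if not calc.is_surface(cid, res, threshold=rsasa_threshold):
            out.append(replace(d, kept=False, stage="structure", rule="buried"))
        else:
            out.append(replace(d, stage="structure", rule="surface"))
    return out


def apply_advanced_filter(
    abstracts: Sequence[AbstractRecord],
    decisions: Sequence[MentionDecision],
    method: str,
    dictionary: KeywordDictionary,
    provider: SimilarityProvider | None = None,
    thresholds: SimilarityThresholds = SimilarityThresholds(),
    model: TrainedModel | None = None,
    protein_names: dict[str, Sequence] | None = None,
    concept_words: Sequence[str] = DEFAULT_CONCEPT_WORDS,
    strict_trees: bool = False,
) -> list[MentionDecision]:
    """Apply one advanced filter to the still-retained mentions.

    ``method`` is one of :data:`FILTER_METHODS`; ``basic`` applies no
    further filtering.  Methods 1-3 need parse trees on the residue
    sentences; method 3 additionally needs a trained SVM and the partner
    protein names per complex.
    """
    if method not in FILTER_METHODS:
        raise ValueError(f"unknown filter method {method!r}")
    if method == "basic":
        return list(decisions)
    by_id = {rec.abstract_id: rec for rec in abstracts}
    out = []
    for d in decisions:
        if not d.kept:
            out.append(d)
            continue
        rec = by_id[d.abstract_id]
        sent = rec.sentences[d.sentence_index]
        if method == "dictionary":
            keep = dictionary_filter(sent, dictionary)
            rule = "keyword-spotted" if keep else "no-keyword"
        elif method.startswith("similarity:"):
            measure = method.split(":", 1)[1]
            keep = similarity_filter(sent, concept_words, provider, measure,
                                     thresholds)
            rule = f"{measure}-similarity"
        elif method == "method1":
            if sent.tree is None and strict_trees:
                raise ValueError(
                    f"no parse tree for sentence {d.sentence_index} of "
                    f"abstract {d.abstract_id}")
            keep = method1_filter(sent, d.mention, dictionary,
                                  strict_trees=strict_trees)
            rule = "s_x-threshold"
        elif method == "method2":
            keep = method2_filter(rec, d.sentence_index, d.mention, dictionary,
                                  strict_trees=strict_trees)
            rule = "s_x+context-spot"
        else:  # method3
            if model is None:
                raise ValueError("method3 requires a trained SVM model")
            names = (protein_names or {}).get(d.complex_id, ())
            if not names:
                raise ValueError(
                    f"method3 requires protein names for complex {d.complex_id}")
            fv = build_features(rec, d.sentence_index, d.mention, dictionary,
                                names)
            keep = method3_filter(model, fv)
            rule = "svm"
        out.append(replace(d, kept=keep, stage=method, rule=rule))
    return out


def build_pools(
    decisions: Sequence[MentionDecision],
    is_interface: Callable[[MentionDecision], bool],
) -> list[ComplexResiduePool]:
    """Group retained mentions into per-complex, per-abstract pools with
    interface flags supplied by ``is_interface`` (gold labels or a bound
    structure lookup)."""
    pools: dict[str, ComplexResiduePool] = {}
    counts: dict[tuple[str, str], list[int]] = {}
    order: list[tuple[str, str]] = []
    for d in decisions:
        key = (d.complex_id, d.abstract_id)
        if key not in counts:
            counts[key] = [0, 0]
            order.append(key)
        if d.kept:
            counts[key][0 if is_interface(d) else 1] += 1
    for complex_id, abstract_id in order:
        n_int, n_non = counts[(complex_id, abstract_id)]
        pool = pools.setdefault(complex_id, ComplexResiduePool(complex_id))
        pool.add(abstract_id, n_int, n_non)
    return list(pools.values())


def aggregate_evidence(
    decisions: Sequence[MentionDecision],
    basic_decisions: Sequence[MentionDecision] | None = None,
) -> dict[tuple[str, tuple[str, int]], list[Evidence]]:
    """Per-residue abstract evidence for the confidence schemes.

    A residue's evidence lists every abstract that mentions it (surviving
    the basic/structural stage); ``nlp_pass`` records whether any of its
    mentions in that abstract also survived the advanced filter in
    ``decisions``.  When only one decision list is given it serves both
    roles.
    """
    basic = basic_decisions if basic_decisions is not None else decisions
    passed: dict[tuple[str, tuple[str, int], str], bool] = {}
    for d in decisions:
        key = (d.complex_id, d.residue_key, d.abstract_id)
        passed[key] = passed.get(key, False) or d.kept
    out: dict[tuple[str, tuple[str, int]], list[Evidence]] = {}
    seen: set[tuple[str, tuple[str, int], str]] = set()
    for d in basic:
        if not d.kept and d.stage != "extraction" and basic_decisions is not None:
            continue
        key = (d.complex_id, d.residue_key, d.abstract_id)
        if key in seen:
            continue
        seen.add(key)
        out.setdefault((d.complex_id, d.residue_key), []).append(Evidence(
            abstract_id=d.abstract_id, query_type=d.query_type,
            nlp_pass=passed.get(key, False)))
    return out


def score_residues(
    evidence: dict[tuple[str, tuple[str, int]], list[Evidence]],
    scheme: str = "basic_eq6",
    protein_role: str = "receptor",
    chain_id: str = "",
) -> dict[str, list[ScoredResidue]]:
    """Confidence-score residues per complex under the basic or NLP
    re-ranked scheme."""
    if scheme not in ("basic_eq6", "nlp_eq7"):
        raise ValueError(f"unknown constraint scheme {scheme!r}")
    fn = confidence_basic if scheme == "basic_eq6" else confidence_nlp
    out: dict[str, list[ScoredResidue]] = {}
    for (complex_id, (resname, resnum)), ev in evidence.items():
        out.setdefault(complex_id, []).append(ScoredResidue(
            protein_role=protein_role, chain_id=chain_id,
            residue_number=resnum, residue_name=resname,
            f=fn(ev), evidence=tuple(ev)))
    return out
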
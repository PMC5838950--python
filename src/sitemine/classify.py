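"""SVM classification of residue-containing sentences (Method 3).

Each residue-containing sentence is described by six features: the
parse-tree keyword score S_X of the residue, the root-anchored keyword
scores of the preceding and following (context) sentences, and a
protein-name score S_prot in {0, 1, 2} (neither / one / both partner
names present) for each of the three sentences.  Missing neighbors
contribute zeros.  A kernel SVM — by default RBF with gamma = 16, the
best-performing configuration — is trained on labeled sentences split
50/50 into training and validation halves, and its positive/negative
prediction keeps or drops all residues of a sentence.

Classifier performance is reported as precision, recall, accuracy and
F-score computed from the validation confusion counts; ratios with a zero
denominator are reported as undefined (None), never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .deepparse import context_root_score, score_residue
from .lexicon import KeywordDictionary
from .textcorpus import AbstractRecord, ResidueMention, Sentence

__all__ = [
    "FeatureVector",
    "LabeledSentenceSet",
    "SvmConfig",
    "TrainedModel",
    "PRAF",
    "s_prot",
    "build_features",
    "train",
    "method3_filter",
    "praf",
    "save_model",
    "load_model",
]

FEATURE_LAYOUT = ("s_x", "s_ctx_prev", "s_ctx_next",
                  "s_prot_res", "s_prot_prev", "s_prot_next")
FEATURE_LAYOUT_VERSION = 1


@dataclass(frozen=True)
class FeatureVector:
    s_x: float
    s_ctx_prev: float
    s_ctx_next: float
    s_prot_res: int
    s_prot_prev: int
    s_prot_next: int

    def __post_init__(self):
        for v in (self.s_prot_res, self.s_prot_prev, self.s_prot_next):
            if v not in (0, 1, 2):
                raise ValueError("protein-name scores must be 0, 1 or 2")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in FEATURE_LAYOUT], dtype=float)


@dataclass
class LabeledSentenceSet:
    """(features, binary label) pairs with provenance ids.

    A sentence is *positive* when it contains at least one interface
    residue and *negative* when it contains residues but none at the
    interface.
    """

    items: list[tuple[FeatureVector, int]] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    def add(self, fv: FeatureVector, label: int, provenance_id: str) -> None:
        if label not in (0, 1):
            raise ValueError("labels are binary")
        if provenance_id in self.provenance:
            raise ValueError(f"duplicate provenance id {provenance_id!r}")
        self.items.append((fv, label))
        self.provenance.append(provenance_id)

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        X = np.array([fv.as_array() for fv, _ in self.items])
        y = np.array([label for _, label in self.items])
        return X, y

    def __len__(self) -> int:
        return len(self.items)


@dataclass(frozen=True)
class SvmConfig:
    kernel: str = "rbf"
    gamma: float = 16.0
    cost: float = 1.0
    split_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.kernel not in ("linear", "poly", "polynomial", "rbf"):
            raise ValueError(f"unsupported kernel {self.kernel!r}")
        if self.kernel == "rbf" and self.gamma <= 0:
            raise ValueError("gamma must be positive for the RBF kernel")


@dataclass
class TrainedModel:
    estimator: object                 # fitted sklearn SVC
    config: SvmConfig
    layout_version: int = FEATURE_LAYOUT_VERSION
    validation: "PRAF | None" = None
    validation_counts: tuple[int, int, int, int] | None = None  # tp, fp, tn, fn

    def predict(self, fv: FeatureVector) -> int:
        return int(self.estimator.predict(fv.as_array()[None, :])[0])


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------

def s_prot(sentence: Sentence, protein_names: Sequence[Sequence[str]]) -> int:
    """Protein-name score: 0 (neither partner named), 1 (exactly one),
    2 (both).  Each partner is a list of its name plus synonyms; presence,
    not occurrence count, is what matters."""
    if not protein_names:
        raise ValueError("protein_names must be non-empty")
    toks = {t.lower() for t in sentence.tokens}
    present = 0
    for synonyms in protein_names:
        names = [synonyms] if isinstance(synonyms, str) else list(synonyms)
        if any(n.lower() in toks for n in names):
            present += 1
    return min(present, 2)


def build_features(
    abstract: AbstractRecord,
    sentence_index: int,
    mention: ResidueMention,
    dictionary: KeywordDictionary,
    protein_names: Sequence[Sequence[str]],
) -> FeatureVector:
    """Assemble the 6-feature vector for one mention.

    The residue-containing sentence must carry a parse tree; context trees
    are optional (their scores default to 0 via ``context_root_score``).
    """
    sentence = abstract.sentences[sentence_index]
    if sentence.tree is None:
        raise ValueError(
            f"sentence {sentence_index} of abstract {abstract.abstract_id} "
            "has no parse tree; features are undefined")
    sx = score_residue(sentence.tree, mention, dictionary).s_x

    def neighbor(idx: int) -> Sentence | None:
        return abstract.sentences[idx] if 0 <= idx < len(abstract.sentences) else None

    prev_s = neighbor(sentence_index - 1)
    next_s = neighbor(sentence_index + 1)
    return FeatureVector(
        s_x=sx,
        s_ctx_prev=context_root_score(prev_s.tree, dictionary) if prev_s else 0.0,
        s_ctx_next=context_root_score(next_s.tree, dictionary) if next_s else 0.0,
        s_prot_res=s_prot(sentence, protein_names),
        s_prot_prev=s_prot(prev_s, protein_names) if prev_s else 0,
        s_prot_next=s_prot(next_s, protein_names) if next_s else 0,
    )


# ---------------------------------------------------------------------------
# Training and prediction
# ---------------------------------------------------------------------------

def train(labeled: LabeledSentenceSet, config: SvmConfig = SvmConfig()) -> TrainedModel:
    """Fit the sentence classifier on a seeded, label-stratified 50/50 split
    and record validation metrics on the held-out half."""
    from sklearn.model_selection import train_test_split
    from sklearn.svm import SVC

    if len(labeled) == 0:
        raise ValueError("empty training set")
    X, y = labeled.arrays()
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    X_tr, X_va, y_tr, y_va = train_test_split(
        X, y, test_size=1.0 - config.split_fraction, stratify=y,
        random_state=config.seed)
    if len(np.unique(y_tr)) < 2:
        raise ValueError("both classes must be present in the training half")
    kernel = "poly" if config.kernel == "polynomial" else config.kernel
    clf = SVC(kernel=kernel, gamma=config.gamma if kernel != "linear" else "scale",
              C=config.cost, random_state=config.seed)
    clf.fit(X_tr, y_tr)
    pred = clf.predict(X_va)
    tp = int(((pred == 1) & (y_va == 1)).sum())
    fp = int(((pred == 1) & (y_va == 0)).sum())
    tn = int(((pred == 0) & (y_va == 0)).sum())
    fn = int(((pred == 0) & (y_va == 1)).sum())
    return TrainedModel(estimator=clf, config=config,
                        validation=praf(tp, fp, tn, fn),
                        validation_counts=(tp, fp, tn, fn))


def method3_filter(model: TrainedModel, features: FeatureVector) -> bool:
    """Keep iff the trained SVM predicts the positive (interface) class."""
    if model is None:
        raise ValueError("no trained model supplied")
    if model.layout_version != FEATURE_LAYOUT_VERSION:
        raise ValueError(
            f"model feature layout v{model.layout_version} does not match "
            f"v{FEATURE_LAYOUT_VERSION}")
    return model.predict(features) == 1


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

class PRAF(NamedTuple):
    precision: float | None
    recall: float | None
    accuracy: float | None
    f_score: float | None


def praf(tp: int, fp: int, tn: int, fn: int) -> PRAF:
    """Precision, recall, accuracy and F-score from confusion counts.

    Components with a zero denominator come back as None (undefined), not
    as 0; all-zero counts are an error.
    """
    counts = (tp, fp, tn, fn)
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    total = sum(counts)
    if total == 0:
        raise ValueError("all confusion counts are zero")
    p = tp / (tp + fp) if (tp + fp) else None
    r = tp / (tp + fn) if (tp + fn) else None
    a = (tp + tn) / total
    f = (2 * p * r / (p + r)) if (p is not None and r is not None and (p + r) > 0) else None
    return PRAF(p, r, a, f)


# ---------------------------------------------------------------------------
# Model persistence (self-describing: kernel, gamma, layout version)
# ---------------------------------------------------------------------------

def save_model(model: TrainedModel, path) -> None:
    import joblib

    joblib.dump({
        "format": "sitemine-svm",
        "layout_version": model.layout_version,
        "layout": FEATURE_LAYOUT,
        "config": model.config.__dict__,
        "estimator": model.estimator,
        "validation_counts": model.validation_counts,
    }, path)


def load_model(path) -> TrainedModel:
    import joblib

    blob = joblib.load(path)
    if blob.get("format") != "sitemine-svm":
        raise ValueError("not a sitemine SVM model file")
    cfg = SvmConfig(**blob["config"])
    counts = blob.get("validation_counts")
    return TrainedModel(estimator=blob["estimator"], config=cfg,
                        layout_version=blob["layout_version"],
                        validation=praf(*counts) if counts else None,
                        validation_counts=counts)
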
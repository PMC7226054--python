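"""Stacked-generalization ensemble over PHI taggers.

Each registered submodel (rule-based, CRF, and optionally any third tagger
honoring the contract ``fit(docs)`` / ``predict(doc) -> entities``) proposes
PHI entities. Identical (start, end, category) proposals collapse into one
candidate with merged sources; overlapping-but-different proposals stay
separate. Every candidate is featurized — which submodels proposed it, how
much it overlaps other candidates, its category, its length in subword
tokens — and a binary RBF-kernel SVM scores it. Candidates above the
decision threshold are kept, with residual overlaps resolved greedily by
descending score.

The stacker's training labels come from out-of-fold submodel predictions
(submodels are retrained per fold), so the meta-classifier never sees
in-sample submodel output; a candidate is labeled positive iff it strictly
matches a gold entity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol

import numpy as np
from sklearn.model_selection import KFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .corpus_io import AnnotatedDocument, I2B2_CATEGORIES, PHIEntity
from .tokenizer import split_char_runs


class Tagger(Protocol):
    def fit(self, docs: list[AnnotatedDocument]) -> None: ...

    def predict(self, doc: AnnotatedDocument) -> list[PHIEntity]: ...


TaggerFactory = Callable[[], Tagger]


@dataclass
class StackerConfig:
    c_pos: float = 5.2  # misclassification weight, positive class
    c_neg: float = 12.48  # misclassification weight, negative class
    gamma: float = 0.009  # RBF kernel width
    threshold: float = 0.0  # decision-function cutoff
    folds: int = 5  # out-of-fold label construction
    seed: int = 0

    def __post_init__(self) -> None:
        if self.c_pos <= 0 or self.c_neg <= 0 or self.gamma <= 0:
            raise ValueError("class weights and gamma must be positive")


@dataclass(frozen=True)
class CandidatePHI:
    entity: PHIEntity
    sources: frozenset[str]
    score: float = 0.0


def collect_candidates(
    per_tagger: dict[str, list[PHIEntity]], registered: list[str]
) -> list[CandidatePHI]:
    """Pool submodel predictions; merge exact duplicates, keep overlaps."""
    merged: dict[tuple, set[str]] = {}
    ents: dict[tuple, PHIEntity] = {}
    for name, entities in per_tagger.items():
        if name not in registered:
            raise ValueError(f"unregistered tagger {name!r}")
        for ent in entities:
            key = (ent.start, ent.end, ent.category)
            merged.setdefault(key, set()).add(name)
            ents[key] = ent
    return [
        CandidatePHI(ents[key], frozenset(sources))
        for key, sources in sorted(merged.items())
    ]


_CATEGORY_ORDER = tuple(I2B2_CATEGORIES) + ("NAME",)


def featurize_candidate(
    cand: CandidatePHI, all_candidates: list[CandidatePHI], registered: list[str]
) -> np.ndarray:
    """Stacking features: source indicators, overlap statistics, category
    one-hot, and length in subword tokens."""
    ent = cand.entity
    indicators = [1.0 if name in cand.sources else 0.0 for name in registered]
    n_overlap = 0
    max_frac = 0.0
    for other in all_candidates:
        oent = other.entity
        if other is cand:
            continue
        lo = max(ent.start, oent.start)
        hi = min(ent.end, oent.end)
        if lo < hi:
            n_overlap += 1
            max_frac = max(max_frac, (hi - lo) / (ent.end - ent.start))
    onehot = [1.0 if ent.category == c else 0.0 for c in _CATEGORY_ORDER]
    n_tokens = len(split_char_runs(ent.text or " ").tokens)
    return np.array(
        indicators + [float(n_overlap), max_frac] + onehot + [float(n_tokens)]
    )


# ---------------------------------------------------------------------------
# Stacker training
# ---------------------------------------------------------------------------


@dataclass
class StackerModel:
    registered: list[str]
    config: StackerConfig
    svm: SVC | None = None
    scaler: StandardScaler | None = None
    constant_score: float | None = None  # degenerate single-class fallback

    def decision_scores(self, x: np.ndarray) -> np.ndarray:
        if self.constant_score is not None:
            return np.full(len(x), self.constant_score)
        return self.svm.decision_function(self.scaler.transform(x))


def compute_oof_predictions(
    docs: list[AnnotatedDocument],
    factories: dict[str, TaggerFactory],
    folds: int,
    seed: int,
) -> dict[str, dict[str, list[PHIEntity]]]:
    """Out-of-fold predictions per tagger: retrain on k−1 folds, predict the
    held-out fold. Keys: tagger name -> doc_id -> entities."""
    n_splits = min(folds, len(docs))
    if n_splits < 2:
        raise ValueError("need at least 2 documents for out-of-fold stacking")
    kf = KFold(n_splits=n_splits, shuffle=True, random_state=seed)
    out: dict[str, dict[str, list[PHIEntity]]] = {name: {} for name in factories}
    for train_idx, test_idx in kf.split(docs):
        train = [docs[i] for i in train_idx]
        for name, factory in factories.items():
            tagger = factory()
            tagger.fit(train)
            for i in test_idx:
                out[name][docs[i].doc_id] = tagger.predict(docs[i])
    return out


def build_stacking_data(
    docs: list[AnnotatedDocument],
    predictions: dict[str, dict[str, list[PHIEntity]]],
    registered: list[str],
):
    """Candidates, feature matrix and strict-match labels over a corpus."""
    xs, ys = [], []
    for doc in docs:
        per_tagger = {
            name: predictions[name].get(doc.doc_id, []) for name in registered
        }
        candidates = collect_candidates(per_tagger, registered)
        gold = {(e.start, e.end, e.category) for e in doc.entities}
        for cand in candidates:
            xs.append(featurize_candidate(cand, candidates, registered))
            key = (cand.entity.start, cand.entity.end, cand.entity.category)
            ys.append(1 if key in gold else 0)
    if not xs:
        raise ValueError(
            "no candidates produced on the stacking folds; "
            "the submodels may need more training data"
        )
    return np.vstack(xs), np.array(ys, dtype=int)


def fit_stacker(
    x: np.ndarray, y: np.ndarray, config: StackerConfig, registered: list[str]
) -> StackerModel:
    model = StackerModel(registered=list(registered), config=config)
    if len(np.unique(y)) < 2:
        # all candidates share one label; the SVM is degenerate
        model.constant_score = 1.0 if y[0] == 1 else -1.0
        return model
    # standardize so the RBF width is meaningful across mixed binary/count
    # features; without it the kernel is nearly flat over the one-hot block
    model.scaler = StandardScaler().fit(x)
    model.svm = SVC(
        C=1.0,
        kernel="rbf",
        gamma=config.gamma,
        class_weight={1: config.c_pos, 0: config.c_neg},
    )
    model.svm.fit(model.scaler.transform(x), y)
    return model


def train_stacker(
    docs: list[AnnotatedDocument],
    factories: dict[str, TaggerFactory],
    config: StackerConfig | None = None,
) -> StackerModel:
    """Train the meta-classifier from out-of-fold submodel predictions."""
    config = config or StackerConfig()
    registered = sorted(factories)
    oof = compute_oof_predictions(docs, factories, config.folds, config.seed)
    x, y = build_stacking_data(docs, oof, registered)
    return fit_stacker(x, y, config, registered)


def select_phi(
    candidates: list[CandidatePHI],
    model: StackerModel,
    threshold: float | None = None,
) -> list[PHIEntity]:
    """Score candidates; keep those above threshold; resolve overlaps greedily
    by descending score. Output is sorted and non-overlapping."""
    if not candidates:
        return []
    threshold = model.config.threshold if threshold is None else threshold
    x = np.vstack(
        [featurize_candidate(c, candidates, model.registered) for c in candidates]
    )
    scores = model.decision_scores(x)
    order = sorted(
        range(len(candidates)),
        key=lambda k: (
            -scores[k],
            candidates[k].entity.start,
            candidates[k].entity.end,
            candidates[k].entity.category,
        ),
    )
    kept: list[PHIEntity] = []
    for k in order:
        if scores[k] <= threshold:
            continue
        ent = candidates[k].entity
        if any(ent.overlaps(other) for other in kept):
            continue
        kept.append(ent)
    return sorted(kept)
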
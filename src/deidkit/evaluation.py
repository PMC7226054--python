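"""Strict entity-level evaluation.

A prediction counts as a true positive only when its start offset, end
offset, and i2b2 category all equal a gold entity's, each gold entity
matching at most one prediction. Precision, recall and F1 are micro-averaged
over all documents and reported as percentages with two decimals; a
per-category breakdown uses the same counts partitioned by category.

Duplicate identical predictions are deduplicated before matching (the
defensible convention where the original challenge script is unavailable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .corpus_io import AnnotatedDocument, PHIEntity


def strict_match(pred: PHIEntity, gold: PHIEntity) -> bool:
    """True iff start, end and category are all equal."""
    return (
        pred.start == gold.start
        and pred.end == gold.end
        and pred.category == gold.category
    )


@dataclass
class CategoryCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def precision(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


@dataclass
class EvaluationResult:
    overall: CategoryCounts = field(default_factory=CategoryCounts)
    per_category: dict[str, CategoryCounts] = field(default_factory=dict)

    @property
    def precision(self) -> float:
        return self.overall.precision

    @property
    def recall(self) -> float:
        return self.overall.recall

    @property
    def f1(self) -> float:
        return self.overall.f1

    def to_dict(self) -> dict:
        def row(c: CategoryCounts) -> dict:
            return {
                "tp": c.tp,
                "fp": c.fp,
                "fn": c.fn,
                "precision": round(c.precision, 2),
                "recall": round(c.recall, 2),
                "f1": round(c.f1, 2),
            }

        return {
            "overall": row(self.overall),
            "per_category": {
                cat: row(c) for cat, c in sorted(self.per_category.items())
            },
        }

    def format_table(self) -> str:
        lines = [
            f"{'category':<16}{'TP':>6}{'FP':>6}{'FN':>6}"
            f"{'P%':>9}{'R%':>9}{'F1%':>9}"
        ]
        rows = sorted(self.per_category.items()) + [("OVERALL", self.overall)]
        for cat, c in rows:
            lines.append(
                f"{cat:<16}{c.tp:>6}{c.fp:>6}{c.fn:>6}"
                f"{c.precision:>9.2f}{c.recall:>9.2f}{c.f1:>9.2f}"
            )
        return "\n".join(lines)


def evaluate(
    pred_docs: list[AnnotatedDocument], gold_docs: list[AnnotatedDocument]
) -> EvaluationResult:
    """Micro-averaged strict entity-level P/R/F1 with per-category breakdown."""
    pred_ids = {d.doc_id for d in pred_docs}
    gold_ids = {d.doc_id for d in gold_docs}
    if pred_ids != gold_ids:
        raise ValueError(
            f"doc_id sets differ: only-pred={sorted(pred_ids - gold_ids)}, "
            f"only-gold={sorted(gold_ids - pred_ids)}"
        )
    gold_by_id = {d.doc_id: d for d in gold_docs}
    result = EvaluationResult()

    def counts(cat: str) -> CategoryCounts:
        return result.per_category.setdefault(cat, CategoryCounts())

    for pdoc in pred_docs:
        gdoc = gold_by_id[pdoc.doc_id]
        preds = {(e.start, e.end, e.category) for e in pdoc.entities}
        golds = {(e.start, e.end, e.category) for e in gdoc.entities}
        for key in preds & golds:
            counts(key[2]).tp += 1
        for key in preds - golds:
            counts(key[2]).fp += 1
        for key in golds - preds:
            counts(key[2]).fn += 1
    result.overall = CategoryCounts(
        tp=sum(c.tp for c in result.per_category.values()),
        fp=sum(c.fp for c in result.per_category.values()),
        fn=sum(c.fn for c in result.per_category.values()),
    )
    return result
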
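"""End-to-end orchestration and command-line interface.

The pipeline trains three layers on an annotated corpus: (1) the regex
initial annotator plus learned transformation rules, (2) the CRF over the
unified feature set with feature crosses, and (3) the stacked-generalization
SVM that arbitrates among submodel predictions. A single root seed flows
into every random draw (fold shuffling, synthetic generation), so re-running
with the same seed reproduces every artifact and report byte for byte.

Library entry points: :func:`train_pipeline`, :func:`tag_corpus`,
:func:`ablate`. The ``deidkit`` console script exposes them as shell verbs
(gen-synthetic, train, train-rules, train-crf, train-ensemble, tag,
evaluate, ablate).
"""

from __future__ import annotations

import json
import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import click

from . import corpus_io, crf, ensemble, evaluation, initial_annotator, synthetic, tbed
from .corpus_io import AnnotatedDocument, decode_iob, encode_iob
from .features import CrossSpec, HeuristicTagger, build_crosses, extract_features
from .tokenizer import BPEModel, TokenSequence, learn_bpe, split_char_runs, tokenize

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    patterns_path: str | None = None  # None -> shipped defaults
    templates_path: str | None = None
    crosses_path: str | None = None
    num_bpe_merges: int = 200
    tbed: tbed.TrainConfig = field(default_factory=tbed.TrainConfig)
    crf: crf.CRFTrainConfig = field(
        default_factory=lambda: crf.CRFTrainConfig(epochs=40)
    )
    stacker: ensemble.StackerConfig = field(default_factory=ensemble.StackerConfig)
    use_heuristic_pos: bool = True  # built-in POS/NER fallback tagger
    seed: int = 0

    def __post_init__(self) -> None:
        self.stacker.seed = self.seed

    def external_tagger(self):
        return HeuristicTagger() if self.use_heuristic_pos else None


# ---------------------------------------------------------------------------
# Submodel adapters honoring the ensemble tagger contract
# ---------------------------------------------------------------------------


class RuleBasedTagger:
    """Initial regex annotator + learned transformation rules."""

    def __init__(self, config: PipelineConfig, bpe: BPEModel | None = None):
        self.config = config
        self.bpe = bpe
        self.patterns = (
            initial_annotator.load_patterns(config.patterns_path)
            if config.patterns_path
            else initial_annotator.default_patterns()
        )
        self.templates = tbed.load_templates(config.templates_path)
        self.rules: list[tbed.ScoredRule] = []
        self.trace: list[tbed.TraceEntry] = []

    def _prepare(self, doc: AnnotatedDocument) -> tuple[TokenSequence, list, list[str]]:
        tokens = tokenize(doc.text, self.bpe)
        feats = extract_features(doc, tokens, self.config.external_tagger())
        init = initial_annotator.annotate(doc.text, tokens, self.patterns)
        return tokens, feats, init

    def fit(self, docs: list[AnnotatedDocument]) -> None:
        features, gold, current = [], [], []
        for doc in docs:
            tokens, feats, init = self._prepare(doc)
            features.append(feats)
            gold.append(encode_iob(tokens, doc.entities))
            current.append(init)
        state = tbed.TBEDState(features, gold, current)
        self.trace = []
        self.rules = tbed.train_tbed(
            state, self.templates, self.config.tbed, trace=self.trace
        )

    def predict(self, doc: AnnotatedDocument) -> list[corpus_io.PHIEntity]:
        tokens, feats, init = self._prepare(doc)
        tags = tbed.apply_rules(self.rules, feats, init)
        return decode_iob(tokens, tags, doc.text)


class CRFTagger:
    """Linear-chain CRF over the unified feature set with crosses."""

    def __init__(self, config: PipelineConfig, bpe: BPEModel | None = None):
        self.config = config
        self.bpe = bpe
        self.crosses = (
            CrossSpec.load(config.crosses_path)
            if config.crosses_path
            else CrossSpec.default()
        )
        self.model: crf.CRFModel | None = None

    def _vectors(self, doc: AnnotatedDocument) -> tuple[TokenSequence, list[dict]]:
        tokens = tokenize(doc.text, self.bpe)
        feats = extract_features(doc, tokens, self.config.external_tagger())
        return tokens, build_crosses(feats, self.crosses)

    def fit(self, docs: list[AnnotatedDocument]) -> None:
        data = []
        for doc in docs:
            tokens, vectors = self._vectors(doc)
            data.append((vectors, encode_iob(tokens, doc.entities)))
        self.model = crf.train_crf(data, self.config.crf)

    def predict(self, doc: AnnotatedDocument) -> list[corpus_io.PHIEntity]:
        if self.model is None:
            raise RuntimeError("CRFTagger.predict called before fit")
        tokens, vectors = self._vectors(doc)
        if not len(tokens):
            return []
        return decode_iob(tokens, crf.decode(self.model, vectors), doc.text)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


@dataclass
class TrainedPipeline:
    config: PipelineConfig
    bpe: BPEModel
    taggers: dict[str, object]  # fitted submodels
    stacker: ensemble.StackerModel
    oof_predictions: dict  # cached per-submodel out-of-fold predictions


def _learn_bpe(docs: list[AnnotatedDocument], num_merges: int) -> BPEModel:
    corpus = [tokenize(doc.text) for doc in docs]
    return learn_bpe(corpus, num_merges)


def submodel_factories(config: PipelineConfig, bpe: BPEModel, extra=None):
    factories = {
        "rule": lambda: RuleBasedTagger(config, bpe),
        "crf": lambda: CRFTagger(config, bpe),
    }
    if extra:
        factories.update(extra)
    return factories


def train_pipeline(
    docs: list[AnnotatedDocument],
    config: PipelineConfig | None = None,
    extra_taggers: dict[str, ensemble.TaggerFactory] | None = None,
) -> TrainedPipeline:
    """Train submodels and the stacking ensemble on an annotated corpus.

    ``extra_taggers`` registers third-party submodels (anything honoring the
    fit/predict contract) alongside the rule-based and CRF taggers.
    """
    config = config or PipelineConfig()
    bpe = _learn_bpe(docs, config.num_bpe_merges)
    factories = submodel_factories(config, bpe, extra_taggers)
    logger.info("computing out-of-fold predictions (%d folds)", config.stacker.folds)
    oof = ensemble.compute_oof_predictions(
        docs, factories, config.stacker.folds, config.seed
    )
    registered = sorted(factories)
    x, y = ensemble.build_stacking_data(docs, oof, registered)
    stacker = ensemble.fit_stacker(x, y, config.stacker, registered)
    fitted = {}
    for name, factory in factories.items():
        tagger = factory()
        tagger.fit(docs)
        fitted[name] = tagger
    return TrainedPipeline(config, bpe, fitted, stacker, oof)


def predict_document(pipe: TrainedPipeline, doc: AnnotatedDocument) -> AnnotatedDocument:
    per_tagger = {
        name: tagger.predict(doc) for name, tagger in pipe.taggers.items()
    }
    candidates = ensemble.collect_candidates(per_tagger, pipe.stacker.registered)
    selected = ensemble.select_phi(candidates, pipe.stacker)
    return AnnotatedDocument(doc.doc_id, doc.text, selected)


def tag_corpus(pipe: TrainedPipeline, docs: list[AnnotatedDocument]) -> list[AnnotatedDocument]:
    return [predict_document(pipe, doc) for doc in docs]


def submodel_predictions(
    pipe: TrainedPipeline, docs: list[AnnotatedDocument], name: str
) -> list[AnnotatedDocument]:
    """Predictions of a single fitted submodel as annotated documents."""
    out = []
    for doc in docs:
        ents = pipe.taggers[name].predict(doc)
        out.append(AnnotatedDocument(doc.doc_id, doc.text, _drop_overlaps(ents)))
    return out


def _drop_overlaps(ents):
    kept = []
    for ent in sorted(ents):
        if not kept or ent.start >= kept[-1].end:
            kept.append(ent)
    return kept


def ablate(
    pipe: TrainedPipeline,
    train_docs: list[AnnotatedDocument],
    test_docs: list[AnnotatedDocument],
    without: str,
) -> dict:
    """Retrain the stacker with one submodel removed; report the F1 delta.

    Reuses the cached out-of-fold predictions, so only the meta-classifier
    is refit.
    """
    if without not in pipe.stacker.registered:
        raise ValueError(f"unknown submodel {without!r}")
    remaining = [n for n in pipe.stacker.registered if n != without]
    if not remaining:
        raise ValueError("cannot ablate the only submodel")
    x, y = ensemble.build_stacking_data(train_docs, pipe.oof_predictions, remaining)
    ablated = ensemble.fit_stacker(x, y, pipe.config.stacker, remaining)

    def run(stacker, names):
        preds = []
        for doc in test_docs:
            per_tagger = {n: pipe.taggers[n].predict(doc) for n in names}
            cands = ensemble.collect_candidates(per_tagger, names)
            preds.append(
                AnnotatedDocument(doc.doc_id, doc.text, ensemble.select_phi(cands, stacker))
            )
        return evaluation.evaluate(preds, test_docs)

    full = run(pipe.stacker, pipe.stacker.registered)
    reduced = run(ablated, remaining)
    return {
        "without": without,
        "full_f1": round(full.f1, 2),
        "ablated_f1": round(reduced.f1, 2),
        "delta": round(reduced.f1 - full.f1, 2),
    }


# ---------------------------------------------------------------------------
# Artifact persistence
# ---------------------------------------------------------------------------


def save_pipeline(pipe: TrainedPipeline, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pipe.bpe.save(outdir / "bpe_merges.txt")
    rule_tagger = pipe.taggers.get("rule")
    if rule_tagger is not None:
        tbed.save_rules(rule_tagger.rules, outdir / "rules.txt")
    crf_tagger = pipe.taggers.get("crf")
    if crf_tagger is not None and crf_tagger.model is not None:
        crf.save_model(crf_tagger.model, outdir / "crf.json")
    with open(outdir / "stacker.pkl", "wb") as fh:
        pickle.dump(pipe, fh)


def load_pipeline(outdir) -> TrainedPipeline:
    path = Path(outdir) / "stacker.pkl"
    if not path.exists():
        raise FileNotFoundError(
            f"no trained pipeline at {path}; run `deidkit train` first"
        )
    with open(path, "rb") as fh:
        return pickle.load(fh)


def _load_dir(path) -> list[AnnotatedDocument]:
    files = sorted(Path(path).glob("*.json")) + sorted(Path(path).glob("*.xml"))
    if not files:
        raise click.ClickException(f"no .json/.xml documents in {path}")
    return [corpus_io.read_annotated(str(f)) for f in files]


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------


@click.group()
@click.option("-v", "--verbose", is_flag=True, help="Log progress to stderr.")
def cli(verbose: bool) -> None:
    """Hybrid PHI de-identification: rules + CRF + stacking ensemble."""
    logging.basicConfig(
        level=logging.INFO if verbose else logging.WARNING,
        format="%(levelname)s %(name)s: %(message)s",
    )


@cli.command("gen-synthetic")
@click.option("--n", default=100, show_default=True, help="Number of documents.")
@click.option("--seed", default=7, show_default=True)
@click.option("--hard", is_flag=True, help="Inject confusion cases.")
@click.option("--format", "fmt", type=click.Choice(["json", "xml"]), default="json")
@click.option("--out", type=click.Path(), required=True)
def gen_synthetic_cmd(n, seed, hard, fmt, out):
    """Generate a synthetic annotated corpus."""
    docs = synthetic.generate_corpus(
        synthetic.GeneratorConfig(n_docs=n, seed=seed, hard=hard)
    )
    outdir = Path(out)
    outdir.mkdir(parents=True, exist_ok=True)
    for doc in docs:
        corpus_io.write_annotated(doc, str(outdir / f"{doc.doc_id}.{fmt}"), fmt)
    click.echo(f"wrote {len(docs)} documents to {outdir}")


def _config_from_options(seed, folds, c_pos, c_neg, gamma, lr, l2, epochs) -> PipelineConfig:
    return PipelineConfig(
        seed=seed,
        stacker=ensemble.StackerConfig(
            c_pos=c_pos, c_neg=c_neg, gamma=gamma, folds=folds, seed=seed
        ),
        crf=crf.CRFTrainConfig(learning_rate=lr, l2=l2, epochs=epochs),
    )


_train_options = [
    click.option("--train", "train_dir", type=click.Path(exists=True), required=True),
    click.option("--artifacts", type=click.Path(), default="artifacts", show_default=True),
    click.option("--seed", default=0, show_default=True),
    click.option("--folds", default=5, show_default=True),
    click.option("--c-pos", default=5.2, show_default=True),
    click.option("--c-neg", default=12.48, show_default=True),
    click.option("--gamma", default=0.009, show_default=True),
    click.option("--lr", default=0.0005, show_default=True),
    click.option("--l2", default=0.0003, show_default=True),
    click.option("--epochs", default=40, show_default=True),
]


def _with_train_options(fn):
    for opt in reversed(_train_options):
        fn = opt(fn)
    return fn


@cli.command("train")
@_with_train_options
def train_cmd(train_dir, artifacts, seed, folds, c_pos, c_neg, gamma, lr, l2, epochs):
    """Train rules, CRF and the stacking ensemble; write artifacts."""
    docs = _load_dir(train_dir)
    config = _config_from_options(seed, folds, c_pos, c_neg, gamma, lr, l2, epochs)
    pipe = train_pipeline(docs, config)
    save_pipeline(pipe, artifacts)
    n_rules = len(pipe.taggers["rule"].rules)
    click.echo(f"trained on {len(docs)} docs; learned {n_rules} rules; artifacts in {artifacts}")


@cli.command("train-rules")
@click.option("--train", "train_dir", type=click.Path(exists=True), required=True)
@click.option("--out", type=click.Path(), default="rules.txt", show_default=True)
@click.option("--max-iters", default=200, show_default=True)
@click.option("--min-score", default=1, show_default=True)
def train_rules_cmd(train_dir, out, max_iters, min_score):
    """Train only the transformation-rule tagger; write the rule file."""
    docs = _load_dir(train_dir)
    config = PipelineConfig(tbed=tbed.TrainConfig(max_iters=max_iters, min_score=min_score))
    tagger = RuleBasedTagger(config, _learn_bpe(docs, config.num_bpe_merges))
    tagger.fit(docs)
    tbed.save_rules(tagger.rules, out)
    for entry in tagger.trace:
        click.echo(
            f"iter {entry.iteration}: score={entry.score} "
            f"remaining_errors={entry.remaining_errors} :: {entry.rule}"
        )
    click.echo(f"learned {len(tagger.rules)} rules -> {out}")


@cli.command("train-crf")
@click.option("--train", "train_dir", type=click.Path(exists=True), required=True)
@click.option("--out", type=click.Path(), default="crf.json", show_default=True)
@click.option("--lr", default=0.0005, show_default=True)
@click.option("--l2", default=0.0003, show_default=True)
@click.option("--epochs", default=40, show_default=True)
def train_crf_cmd(train_dir, out, lr, l2, epochs):
    """Train only the CRF submodel; write the model container."""
    docs = _load_dir(train_dir)
    config = PipelineConfig(crf=crf.CRFTrainConfig(learning_rate=lr, l2=l2, epochs=epochs))
    tagger = CRFTagger(config, _learn_bpe(docs, config.num_bpe_merges))
    tagger.fit(docs)
    crf.save_model(tagger.model, out)
    ll = tagger.model.history[-1] if tagger.model.history else float("nan")
    click.echo(f"final train log-likelihood {ll:.4f} -> {out}")


@cli.command("train-ensemble")
@_with_train_options
def train_ensemble_cmd(train_dir, artifacts, seed, folds, c_pos, c_neg, gamma, lr, l2, epochs):
    """Alias of `train` emphasizing the stacking stage."""
    train_cmd.callback(train_dir, artifacts, seed, folds, c_pos, c_neg, gamma, lr, l2, epochs)


@cli.command("tag")
@click.option("--input", "input_dir", type=click.Path(exists=True), required=True)
@click.option("--artifacts", type=click.Path(), default="artifacts", show_default=True)
@click.option("--out", type=click.Path(), required=True)
@click.option("--format", "fmt", type=click.Choice(["json", "xml"]), default="json")
def tag_cmd(input_dir, artifacts, out, fmt):
    """Tag documents with the trained ensemble; write standoff annotations."""
    try:
        pipe = load_pipeline(artifacts)
    except FileNotFoundError as exc:
        raise click.ClickException(str(exc))
    docs = _load_dir(input_dir)
    outdir = Path(out)
    outdir.mkdir(parents=True, exist_ok=True)
    for doc in docs:
        pred = predict_document(pipe, doc)
        corpus_io.write_annotated(pred, str(outdir / f"{doc.doc_id}.{fmt}"), fmt)
    click.echo(f"tagged {len(docs)} documents -> {outdir}")


@cli.command("evaluate")
@click.option("--pred", type=click.Path(exists=True), required=True)
@click.option("--gold", type=click.Path(exists=True), required=True)
@click.option("--per-category", is_flag=True)
@click.option("--json-out", type=click.Path())
def evaluate_cmd(pred, gold, per_category, json_out):
    """Strict entity-level micro P/R/F1 of predictions against gold."""
    result = evaluation.evaluate(_load_dir(pred), _load_dir(gold))
    if per_category:
        click.echo(result.format_table())
    else:
        click.echo(
            f"P={result.precision:.2f} R={result.recall:.2f} F1={result.f1:.2f}"
        )
    if json_out:
        with open(json_out, "w", encoding="utf-8") as fh:
            json.dump(result.to_dict(), fh, indent=1)
            fh.write("\n")


@cli.command("ablate")
@click.option("--train", "train_dir", type=click.Path(exists=True), required=True)
@click.option("--test", "test_dir", type=click.Path(exists=True), required=True)
@click.option("--artifacts", type=click.Path(), default="artifacts", show_default=True)
@click.option("--without", required=True, help="Submodel name to remove (rule|crf|...).")
def ablate_cmd(train_dir, test_dir, artifacts, without):
    """Retrain the stacker without one submodel and report the F1 delta."""
    try:
        pipe = load_pipeline(artifacts)
    except FileNotFoundError as exc:
        raise click.ClickException(str(exc))
    report = ablate(pipe, _load_dir(train_dir), _load_dir(test_dir), without)
    click.echo(json.dumps(report))


if __name__ == "__main__":
    cli()
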
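# deidkit

Hybrid de-identification of clinical text: detect protected health
information (PHI) — names, dates, record numbers, locations, and the rest
of the 23 i2b2 subcategories — in clinical notes, as token-level sequence
labeling with exact character offsets. Built for NLP researchers and
clinical-informatics engineers who need a de-identification system whose
every stage is inspectable and reproducible without access to restricted
corpora.

The system combines three submodels under stacked generalization:

1. **Rule-based tagger** — a regex initial-state annotator whose output is
   corrected by an ordered list of transformation rules learned with
   transformation-based error-driven learning (TBED, Brill-style): at each
   iteration the rule with the greatest benefit
   *s(r) = errors fixed − correct tags broken* over the training corpus is
   appended and applied, until no rule reaches the minimum benefit.
2. **Linear-chain CRF** — models P(T | S) ∝ exp Σᵢ Σⱼ λⱼ fⱼ(tᵢ₋₁, tᵢ, S, i)
   with indicator feature functions over a unified feature set (token
   shape, affixes, stems, sentence length, section, POS/NER slots) plus 49
   feature crosses; trained by L2-penalized maximum likelihood, decoded
   with Viterbi.
3. **Stacking ensemble** — PHI candidates pooled from all submodels are
   featurized (which submodels proposed the span, overlap with other
   candidates, category, length) and scored by a class-weighted RBF-kernel
   SVM trained on out-of-fold submodel predictions; candidates above the
   decision threshold are kept, overlaps resolved by descending score.

Inputs are plain-text notes with standoff PHI annotations (i2b2-2014-style
XML or a small JSON dialect). Text is tokenized at subword level —
character-class splitting, uppercase splitting, then byte pair encoding —
so PHI boundaries inside whitespace tokens ("Dr.Smith") stay reachable.
Evaluation is strict entity-level micro P/R/F1: a prediction counts only
if start, end, and category all match a gold entity.

Because the i2b2 2014 corpus is distributed only under a data use
agreement, the package ships a synthetic-note generator (fictional
surrogate PHI at the published category proportions, exact gold offsets,
and a "hard mode" with the confusion cases that make ensembling
non-trivial). All tests and benchmarks run on generated data; see
`docs/methods.md` for what that does and does not demonstrate.

## Worked example

Train on 100 synthetic hard-mode documents, evaluate on 50 held-out ones:

```python
import deidkit as dk
from deidkit.app import (PipelineConfig, train_pipeline, tag_corpus,
                         ablate, submodel_predictions)
from deidkit.evaluation import evaluate

train = dk.generate_corpus(dk.GeneratorConfig(n_docs=100, seed=7, hard=True))
test = dk.generate_corpus(dk.GeneratorConfig(n_docs=50, seed=8, hard=True))

pipe = train_pipeline(train, PipelineConfig(seed=1))
print("learned rules:", len(pipe.taggers["rule"].rules))
for name in ("rule", "crf"):
    r = evaluate(submodel_predictions(pipe, test, name), test)
    print(f"{name:>8} F1 = {r.f1:.2f}")
result = evaluate(tag_corpus(pipe, test), test)
print(f"ensemble F1 = {result.f1:.2f}  (P = {result.precision:.2f}, R = {result.recall:.2f})")
print("ablation:", ablate(pipe, train, test, "rule"))
```

prints

```
learned rules: 85
    rule F1 = 93.92
     crf F1 = 98.47
ensemble F1 = 99.15  (P = 99.66, R = 98.65)
ablation: {'without': 'rule', 'full_f1': 99.15, 'ablated_f1': 98.47, 'delta': -0.69}
```

Reading: the regex-plus-learned-rules tagger alone reaches F1 93.92 and
the CRF 98.47; stacking them is better than either (99.15), and retraining
the stacker without the rule submodel costs 0.69 points — the rule model
contributes even though it is the weaker tagger, the central qualitative
finding the package reproduces. (On restricted real data the absolute
numbers are lower across the board; the ordering is the point.)

The same flow is available from the shell:

```sh
deidkit gen-synthetic --n 100 --seed 7 --hard --out corpus/train
deidkit gen-synthetic --n 50 --seed 8 --hard --out corpus/test
deidkit train --train corpus/train --artifacts artifacts --seed 1
deidkit tag --input corpus/test --artifacts artifacts --out pred
deidkit evaluate --pred pred --gold corpus/test --per-category
deidkit ablate --train corpus/train --test corpus/test --artifacts artifacts --without rule
```

`deidkit train-rules` and `deidkit train-crf` train single submodels and
write their artifacts (a human-readable ordered rule file; a JSON model
container).

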
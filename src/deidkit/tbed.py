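"""Transformation-based error-driven rule learning (Brill-style).

Starting from the initial annotator's tagging of the training corpus, the
learner repeats a greedy loop: at every position where the current tag
disagrees with gold, instantiate one candidate rule per template ("if the
features at this position take these values, change the current tag to the
gold tag"); score every candidate by its net benefit over the whole corpus
— errors it fixes minus correct tags it breaks; append the best rule to the
ordered rule list and apply it everywhere. Training stops when no candidate
reaches ``min_score`` or after ``max_iters`` iterations.

Rules are applied *simultaneously*: conditions are evaluated against the
pre-application tags at all positions, then all firing positions are
rewritten. Under this convention the corpus error count drops by exactly
the selected rule's score each iteration, so the training error sequence is
strictly decreasing.

Templates are configuration (``data/templates_default.txt``): condition
slots ``feature@offset`` with offsets in −2…+2. The feature named ``tag``
reads the current working tags and is re-evaluated as rules rewrite them;
every other feature is computed once from the text.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

BOUNDARY_BEFORE = "BOS"
BOUNDARY_AFTER = "EOS"


# ---------------------------------------------------------------------------
# Templates and rules
# ---------------------------------------------------------------------------

Slot = tuple[str, int]  # (feature name, window offset)


@dataclass(frozen=True)
class RuleTemplate:
    slots: tuple[Slot, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.slots) <= 3:
            raise ValueError("template arity must be 1..3")
        for name, off in self.slots:
            if not -2 <= off <= 2:
                raise ValueError(f"slot offset {off} outside -2..+2")

    @classmethod
    def parse(cls, line: str) -> "RuleTemplate":
        slots = []
        for item in line.split("&"):
            name, _, off = item.strip().partition("@")
            slots.append((name.strip(), int(off) if off else 0))
        return cls(tuple(slots))

    def __str__(self) -> str:
        return " & ".join(f"{n}@{o}" for n, o in self.slots)


def load_templates(path=None) -> list[RuleTemplate]:
    """Load rule templates; with no path, the shipped default set."""
    if path is None:
        text = (
            resources.files("deidkit.data")
            .joinpath("templates_default.txt")
            .read_text(encoding="utf-8")
        )
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    templates = []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            templates.append(RuleTemplate.parse(line))
    return templates


@dataclass(frozen=True)
class TransformationRule:
    """Bound condition values for a template, plus the tag rewrite."""

    template: RuleTemplate
    values: tuple[str, ...]
    from_tag: str
    to_tag: str

    def __post_init__(self) -> None:
        if self.from_tag == self.to_tag:
            raise ValueError("from_tag must differ from to_tag")
        if len(self.values) != len(self.template.slots):
            raise ValueError("one bound value per template slot required")

    def __str__(self) -> str:
        conds = " AND ".join(
            f"{name}@{off}={_quote(val)}"
            for (name, off), val in zip(self.template.slots, self.values)
        )
        return f"IF {conds} THEN {self.from_tag}->{self.to_tag}"


@dataclass(frozen=True)
class ScoredRule:
    rule: TransformationRule
    fixed: int
    broken: int

    @property
    def score(self) -> int:
        return self.fixed - self.broken


def _quote(val: str) -> str:
    return "'" + val.replace("\\", "\\\\").replace("'", "\\'") + "'"


_COND_RE = re.compile(r"(?P<name>[A-Za-z_0-9]+)@(?P<off>-?\d)='(?P<val>(?:[^'\\]|\\.)*)'")
_RULE_RE = re.compile(
    r"^IF (?P<conds>.+) THEN (?P<from>\S+)->(?P<to>\S+?)(?:\s*#.*)?$"
)


def parse_rule(line: str) -> TransformationRule:
    m = _RULE_RE.match(line.strip())
    if not m:
        raise ValueError(f"cannot parse rule line {line!r}")
    slots, values = [], []
    for cm in _COND_RE.finditer(m.group("conds")):
        slots.append((cm.group("name"), int(cm.group("off"))))
        values.append(cm.group("val").replace("\\'", "'").replace("\\\\", "\\"))
    return TransformationRule(
        RuleTemplate(tuple(slots)), tuple(values), m.group("from"), m.group("to")
    )


def save_rules(rules: list[ScoredRule], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sr in rules:
            fh.write(f"{sr.rule} # score={sr.score}\n")


def load_rules(path) -> list[TransformationRule]:
    rules = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                rules.append(parse_rule(line))
    return rules


# ---------------------------------------------------------------------------
# Corpus state
# ---------------------------------------------------------------------------


@dataclass
class TBEDState:
    """Per-document feature vectors, gold tags, and the working tagging."""

    features: list[list[dict]]  # [doc][position] -> feature dict
    gold: list[list[str]]
    current: list[list[str]]

    def __post_init__(self) -> None:
        for f, g, c in zip(self.features, self.gold, self.current):
            if not len(f) == len(g) == len(c):
                raise ValueError("features/gold/current lengths differ")

    def error_count(self) -> int:
        return sum(
            t != g for gold, cur in zip(self.gold, self.current) for g, t in zip(gold, cur)
        )

    def positions(self):
        for d in range(len(self.gold)):
            for i in range(len(self.gold[d])):
                yield d, i

    def value(self, d: int, i: int, slot: Slot) -> str:
        """The value of a condition slot at document d, position i."""
        name, off = slot
        j = i + off
        seq_len = len(self.gold[d])
        if j < 0:
            return BOUNDARY_BEFORE
        if j >= seq_len:
            return BOUNDARY_AFTER
        if name == "tag":
            return self.current[d][j]
        return str(self.features[d][j][name])

    def copy(self) -> "TBEDState":
        return TBEDState(self.features, self.gold, [list(t) for t in self.current])


def rule_fires(rule: TransformationRule, state: TBEDState, d: int, i: int) -> bool:
    if state.current[d][i] != rule.from_tag:
        return False
    return all(
        state.value(d, i, slot) == val
        for slot, val in zip(rule.template.slots, rule.values)
    )


# ---------------------------------------------------------------------------
# Candidate generation, scoring, application
# ---------------------------------------------------------------------------


def generate_candidates(
    state: TBEDState, templates: list[RuleTemplate]
) -> set[TransformationRule]:
    """One candidate per (error position, template), deduplicated."""
    out: set[TransformationRule] = set()
    for d, i in state.positions():
        cur, gold = state.current[d][i], state.gold[d][i]
        if cur == gold:
            continue
        for tpl in templates:
            values = tuple(state.value(d, i, slot) for slot in tpl.slots)
            out.add(TransformationRule(tpl, values, cur, gold))
    return out


def score_rule(rule: TransformationRule, state: TBEDState) -> ScoredRule:
    """Net benefit of a rule: errors fixed minus correct tags broken.

    Pure simulation — the state is not modified. A position counts as fixed
    when the rewrite lands on gold and as broken when it leaves gold; a
    rewrite from one wrong tag to another wrong tag is neutral.
    """
    fixed = broken = 0
    for d, i in state.positions():
        if not rule_fires(rule, state, d, i):
            continue
        gold = state.gold[d][i]
        if gold == rule.to_tag:
            fixed += 1
        elif gold == rule.from_tag:
            broken += 1
    return ScoredRule(rule, fixed, broken)


def apply_rule(rule: TransformationRule, state: TBEDState) -> TBEDState:
    """Apply a rule simultaneously at every firing position (in place)."""
    firing = [
        (d, i) for d, i in state.positions() if rule_fires(rule, state, d, i)
    ]
    for d, i in firing:
        state.current[d][i] = rule.to_tag
    return state


def _rule_sort_key(scored: ScoredRule):
    # argmax score; ties: fewer broken, smaller arity, lexicographic string
    return (
        -scored.score,
        scored.broken,
        len(scored.rule.template.slots),
        str(scored.rule),
    )


def _score_all_candidates(
    state: TBEDState, templates: list[RuleTemplate]
) -> list[ScoredRule]:
    """Bucket positions by (template, bound values, current tag) and score
    every candidate in one corpus pass per template.

    Equivalent to calling :func:`score_rule` on each candidate from
    :func:`generate_candidates` (the exhaustive path the oracle tests take),
    but linear in corpus size.
    """
    scored: list[ScoredRule] = []
    for tpl in templates:
        buckets: dict[tuple, dict[str, int]] = {}
        candidates: set[tuple[tuple, str, str]] = set()
        for d, i in state.positions():
            cur = state.current[d][i]
            gold = state.gold[d][i]
            values = tuple(state.value(d, i, slot) for slot in tpl.slots)
            counts = buckets.setdefault((values, cur), {})
            counts[gold] = counts.get(gold, 0) + 1
            if cur != gold:
                candidates.add((values, cur, gold))
        for values, from_tag, to_tag in candidates:
            counts = buckets[(values, from_tag)]
            scored.append(
                ScoredRule(
                    TransformationRule(tpl, values, from_tag, to_tag),
                    fixed=counts.get(to_tag, 0),
                    broken=counts.get(from_tag, 0),
                )
            )
    return scored


@dataclass
class TrainConfig:
    max_iters: int = 200
    min_score: int = 1

    def __post_init__(self) -> None:
        if self.min_score < 1:
            raise ValueError("min_score must be >= 1")


@dataclass
class TraceEntry:
    iteration: int
    rule: TransformationRule
    score: int
    remaining_errors: int


def train_tbed(
    state: TBEDState,
    templates: list[RuleTemplate],
    config: TrainConfig | None = None,
    trace: list[TraceEntry] | None = None,
) -> list[ScoredRule]:
    """Greedy rule induction; returns the ordered learned rules.

    ``state`` is consumed (its working tags end at the final training
    tagging). Pass a list as ``trace`` to receive per-iteration entries.
    """
    config = config or TrainConfig()
    rules: list[ScoredRule] = []
    errors = state.error_count()
    for k in range(config.max_iters):
        if errors == 0:
            break
        scored = _score_all_candidates(state, templates)
        if not scored:
            break
        best = min(scored, key=_rule_sort_key)
        if best.score < config.min_score:
            break
        apply_rule(best.rule, state)
        errors -= best.score
        rules.append(best)
        if trace is not None:
            trace.append(TraceEntry(k + 1, best.rule, best.score, errors))
    return rules


def apply_rules(
    rules: list[TransformationRule],
    features: list[dict],
    init_tags: list[str],
) -> list[str]:
    """Apply an ordered rule list to one document's initial tagging."""
    state = TBEDState([features], [["O"] * len(init_tags)], [list(init_tags)])
    for rule in rules:
        rule = rule.rule if isinstance(rule, ScoredRule) else rule
        apply_rule(rule, state)
    return state.current[0]
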
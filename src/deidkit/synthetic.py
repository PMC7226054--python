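"""Synthetic clinical-note generator with gold PHI annotations.

The reference de-identification corpus is distributed only under a data use
agreement, so every component here is exercised on surrogate notes instead:
templated narrative sentences with fictional PHI of all 23 i2b2 categories
inserted at recorded character offsets. Category frequencies default to the
published training-set distribution (dates dominate, followed by doctor and
patient names). The generator targets structural coverage — section
headers, structured identifiers matchable by the default regex patterns,
names in predictable contexts — not linguistic realism.

``hard=True`` additionally injects the confusion cases that make the
ensemble interesting: four-digit laboratory values that a bare ``\\d{4}``
date pattern false-positives on, and multi-token state names.

``plant_rule_corpus`` builds corrupted initial taggings for the rule
learner's recovery tests: a corruption is a transformation rule applied to
the gold tags at every qualifying site, so training must re-discover its
inverse.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from importlib import resources

from .corpus_io import AnnotatedDocument, PHIEntity, encode_iob
from .features import extract_features
from .tbed import RuleTemplate, TBEDState, TransformationRule
from .tokenizer import tokenize

#: Published training-set PHI counts; used as default sampling weights.
DEFAULT_CATEGORY_WEIGHTS: dict[str, int] = {
    "DATE": 7502,
    "DOCTOR": 2885,
    "HOSPITAL": 1437,
    "PATIENT": 1316,
    "AGE": 1233,
    "MEDICALRECORD": 611,
    "CITY": 394,
    "STATE": 314,
    "PHONE": 309,
    "USERNAME": 264,
    "IDNUM": 261,
    "PROFESSION": 234,
    "STREET": 216,
    "ZIP": 212,
    "ORGANIZATION": 124,
    "COUNTRY": 66,
    "FAX": 8,
    "DEVICE": 7,
    "EMAIL": 4,
    "LOCATION-OTHER": 4,
    "URL": 2,
    "BIOID": 1,
    "HEALTHPLAN": 1,
}


def default_lexicons() -> dict[str, list[str]]:
    data = resources.files("deidkit.data").joinpath("lexicons.json")
    return json.loads(data.read_text(encoding="utf-8"))


@dataclass
class GeneratorConfig:
    n_docs: int = 100
    category_weights: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_WEIGHTS)
    )
    lexicons: dict[str, list[str]] = field(default_factory=default_lexicons)
    seed: int = 0
    hard: bool = False
    phi_per_doc: tuple[int, int] = (4, 8)

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.category_weights.values()):
            raise ValueError("category weights must be nonnegative")
        if not any(self.category_weights.values()):
            raise ValueError("at least one category weight must be positive")


# Sentence templates: (prefix, suffix) around the inserted PHI surface form.
_TEMPLATES: dict[str, list[tuple[str, str]]] = {
    "DATE": [("Seen on ", " for follow up."), ("Labs drawn on ", " were stable.")],
    "DOCTOR": [("Evaluated by Dr. ", " in clinic."), ("Plan discussed with Dr. ", " .")],
    "PATIENT": [("", " is recovering well."), ("Family contact: ", " at bedside.")],
    "USERNAME": [("Note entered by ", " this morning.")],
    "AGE": [("The patient is a ", " years old gentleman."), ("She is a ", " years old retiree.")],
    "PHONE": [("Call the office at ", " with questions.")],
    "FAX": [("Fax results to ", " before noon.")],
    "EMAIL": [("Send records to ", " for review.")],
    "URL": [("Instructions posted at ", " online.")],
    "MEDICALRECORD": [("Medical record number ", " confirmed.")],
    "IDNUM": [("Insurance id ", " on file.")],
    "DEVICE": [("Pacemaker serial ", " interrogated.")],
    "BIOID": [("Biometric identifier ", " archived.")],
    "HEALTHPLAN": [("Health plan number ", " verified.")],
    "HOSPITAL": [("Transferred from ", " overnight."), ("Admitted to ", " yesterday.")],
    "CITY": [("Lives near ", " with family.")],
    "STATE": [("Will go back to ", " next month.")],
    "STREET": [("Resides at ", " currently.")],
    "ZIP": [("Mailing zip code ", " noted.")],
    "ORGANIZATION": [("Coverage through ", " was confirmed.")],
    "COUNTRY": [("Recently returned from ", " abroad.")],
    "LOCATION-OTHER": [("Found at ", " by neighbors.")],
    "PROFESSION": [("Works as a ", " in town.")],
}

_CONFUSION = [
    ("A CK of ", " was noted."),
    ("With SVR of ", " measured."),
    ("An LDH of ", " resulted."),
]

# In hard mode the three geographic categories share one context pool, so the
# context no longer identifies the category — only the surface form does
# (mirroring confusions like a state name read as a hospital or record id).
_SHARED_LOCATION_TEMPLATES = [
    ("Lives near ", " with family."),
    ("Will go back to ", " next month."),
    ("Recently returned from ", " abroad."),
    ("Relocated to ", " last spring."),
]
_SHARED_LOCATION_CATEGORIES = ("CITY", "STATE", "COUNTRY")


def _sample_value(category: str, lex: dict[str, list[str]], rng: random.Random) -> str:
    def name() -> str:
        return f"{rng.choice(lex['first_names'])} {rng.choice(lex['last_names'])}"

    if category == "DATE":
        style = rng.randrange(3)
        y = rng.randint(2060, 2079)
        m, d = rng.randint(1, 12), rng.randint(1, 28)
        if style == 0:
            return f"{y}-{m:02d}-{d:02d}"
        if style == 1:
            return f"{m:02d}/{d:02d}/{y}"
        return str(y)
    if category in ("DOCTOR", "PATIENT"):
        return name()
    if category == "USERNAME":
        letters = "".join(rng.choice("abcdefghijklmnopqrstuvwxyz") for _ in range(2))
        return f"{letters} {rng.randint(10, 99)}"
    if category == "AGE":
        return str(rng.randint(21, 99))
    if category in ("PHONE", "FAX"):
        return f"{rng.randint(200, 999)}-{rng.randint(200, 999)}-{rng.randint(1000, 9999)}"
    if category == "EMAIL":
        return f"{rng.choice(lex['last_names']).lower()}@mail.{rng.choice(['org', 'com', 'net'])}"
    if category == "URL":
        return f"www.{rng.choice(lex['organizations']).split()[0].lower()}.org"
    if category == "MEDICALRECORD":
        return str(rng.randint(1000000, 9999999))
    if category == "IDNUM":
        return f"{rng.choice('KLMNP')}{rng.randint(100000, 999999)}"
    if category == "DEVICE":
        return f"{rng.randint(100, 999)}{rng.choice('ABC')}"
    if category == "BIOID":
        return str(rng.randint(100000000, 999999999))
    if category == "HEALTHPLAN":
        return f"HP{rng.randint(10000, 99999)}"
    if category == "HOSPITAL":
        return rng.choice(lex["hospitals"])
    if category == "CITY":
        return rng.choice(lex["cities"])
    if category == "STATE":
        return rng.choice(lex["states"])
    if category == "STREET":
        return rng.choice(lex["streets"])
    if category == "ZIP":
        return f"{rng.randint(10000, 99999)}"
    if category == "ORGANIZATION":
        return rng.choice(lex["organizations"])
    if category == "COUNTRY":
        return rng.choice(lex["countries"])
    if category == "LOCATION-OTHER":
        return f"the {rng.choice(['east', 'west', 'north'])} ward"
    if category == "PROFESSION":
        return rng.choice(lex["professions"])
    raise ValueError(f"no surrogate recipe for category {category!r}")


def generate_document(doc_id: str, config: GeneratorConfig, rng: random.Random) -> AnnotatedDocument:
    cats = list(config.category_weights)
    weights = [config.category_weights[c] for c in cats]
    k = rng.randint(*config.phi_per_doc)
    draws = rng.choices(cats, weights=weights, k=k)

    parts: list[str] = []
    entities: list[PHIEntity] = []
    pos = 0

    def add_line(prefix: str, value: str | None, suffix: str, category: str | None):
        nonlocal pos
        line = prefix + (value or "") + suffix + "\n"
        if value is not None and category is not None:
            start = pos + len(prefix)
            entities.append(PHIEntity(start, start + len(value), category, value))
        parts.append(line)
        pos += len(line)

    header_date = None
    if "DATE" in draws:
        draws.remove("DATE")
        header_date = _sample_value("DATE", config.lexicons, rng)
    if header_date is not None:
        add_line("Record date: ", header_date, "", "DATE")
        add_line("", None, "", None)  # blank line
    add_line("HPI:", None, "", None)

    body: list[tuple[str, str, str, str | None]] = []
    for cat in draws:
        if config.hard and cat in _SHARED_LOCATION_CATEGORIES:
            prefix, suffix = rng.choice(_SHARED_LOCATION_TEMPLATES)
        else:
            prefix, suffix = rng.choice(_TEMPLATES[cat])
        body.append((prefix, _sample_value(cat, config.lexicons, rng), suffix, cat))
    if config.hard:
        for _ in range(rng.randint(2, 4)):
            prefix, suffix = rng.choice(_CONFUSION)
            body.append((prefix, str(rng.randint(1000, 2059)), suffix, None))
    rng.shuffle(body)
    for prefix, value, suffix, cat in body:
        add_line(prefix, value, suffix, cat)

    return AnnotatedDocument(doc_id, "".join(parts), entities)


def generate_corpus(config: GeneratorConfig) -> list[AnnotatedDocument]:
    """Generate a seeded corpus; identical config (incl. seed) gives a
    byte-identical corpus."""
    rng = random.Random(config.seed)
    return [
        generate_document(f"doc-{i:04d}", config, rng) for i in range(config.n_docs)
    ]


# ---------------------------------------------------------------------------
# Planted-rule corpora for the rule learner's recovery tests
# ---------------------------------------------------------------------------


def plant_rule_corpus(
    docs: list[AnnotatedDocument],
    corruptions: list[TransformationRule],
    templates: list[RuleTemplate],
    external_tagger=None,
) -> tuple[TBEDState, list[int]]:
    """Corrupt gold taggings with planted transformations.

    Each corruption rewrites the gold tag (its ``from_tag``) to a wrong tag
    (its ``to_tag``) at every position where its conditions hold against the
    gold tagging. Returns the TBED state (current = corrupted, gold = gold)
    and the per-corruption site counts. Raises if a corruption's template is
    not in the shipped/provided template set, since training could then
    never express the inverse.
    """
    tpl_set = set(templates)
    for c in corruptions:
        if c.template not in tpl_set:
            raise ValueError(
                f"planted corruption template {c.template} not expressible "
                f"by the provided templates"
            )
    features, gold, current = [], [], []
    for doc in docs:
        tokens = tokenize(doc.text)
        features.append(extract_features(doc, tokens, external_tagger))
        gold.append(encode_iob(tokens, doc.entities))
    gold_state = TBEDState(features, gold, [list(t) for t in gold])
    site_counts = [0] * len(corruptions)
    init = [list(t) for t in gold]
    for ci, corr in enumerate(corruptions):
        for d, i in gold_state.positions():
            if gold[d][i] != corr.from_tag:
                continue
            if all(
                gold_state.value(d, i, slot) == val
                for slot, val in zip(corr.template.slots, corr.values)
            ):
                init[d][i] = corr.to_tag
                site_counts[ci] += 1
    return TBEDState(features, gold, init), site_counts
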
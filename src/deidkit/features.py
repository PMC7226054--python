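"""Unified feature set shared by the rule learner and the CRF.

Three groups of per-token features:

* token-level — surface text, length, all-digits and initial-uppercase
  flags, a Porter-style stem, and prefixes/suffixes of lengths 1-4;
* global — sentence length in tokens and a section label derived from
  header lines such as ``Record date:`` or ``HPI:``;
* tagging-based — part-of-speech and general NER tags from a pluggable
  external tagger (``NA`` sentinels when none is configured).

Composite "feature crosses" conjoin several base features, possibly at
different token offsets in a −2…+2 window, into a single feature whose value
concatenates the member values. The shipped default inventory of 49 crosses
lives in ``data/crosses_default.txt`` and is configuration, not code.

Feature extraction is pure: the same (document, tokens, index, tagger
output) always produces the same vector.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources

from .tokenizer import TokenSequence

logger = logging.getLogger(__name__)

NA = "NA"
CROSS_SEP = "|"

#: Canonical base feature names, all present in every vector.
BASE_FEATURES: tuple[str, ...] = (
    "token",
    "length",
    "all_digits",
    "init_upper",
    "stem",
    "prefix1",
    "prefix2",
    "prefix3",
    "prefix4",
    "suffix1",
    "suffix2",
    "suffix3",
    "suffix4",
    "sentence_length",
    "section",
    "pos",
    "ner",
)


class ContractError(ValueError):
    """An external tagger violated the plug-in contract."""


def porter_stem(word: str) -> str:
    """A compact Porter-style suffix stripper (lowercases its input).

    Covers the high-frequency English inflectional endings; not a full
    Porter implementation, but deterministic and adequate as a sparsity
    reducer for feature values.
    """
    w = word.lower()
    if len(w) <= 3:
        return w
    if w.endswith("sses"):
        return w[:-2]
    if w.endswith("ies"):
        return w[:-2]
    if w.endswith("ss"):
        return w
    if w.endswith("s") and not w.endswith("us"):
        return w[:-1]
    for suf in ("ational", "tional", "iveness", "fulness", "ousness"):
        if w.endswith(suf) and len(w) - len(suf) >= 2:
            return w[: len(w) - len(suf)] + ("ate" if suf == "ational" else "")
    for suf in ("ing", "edly", "ed", "ly", "ment", "ness", "tion"):
        if w.endswith(suf) and len(w) - len(suf) >= 3:
            return w[: len(w) - len(suf)]
    return w


# ---------------------------------------------------------------------------
# Section detection
# ---------------------------------------------------------------------------

_HEADER_RE = re.compile(r"^[A-Z][A-Za-z ]{2,40}:\s*$")
KNOWN_HEADERS = ("Record date", "HPI", "Medications", "Assessment", "Plan")


def _header_label(line: str) -> str | None:
    stripped = line.strip()
    if _HEADER_RE.match(stripped):
        return stripped.rstrip(": ").upper().replace(" ", "_")
    for known in KNOWN_HEADERS:
        if stripped.startswith(known + ":"):
            return known.upper().replace(" ", "_")
    return None


def section_labels(text: str, tokens: TokenSequence) -> list[str]:
    """Per-token section labels.

    Tokens on a header line get ``HEADER``; tokens below a header carry that
    header's normalized name until the next header; documents without
    headers are all ``BODY``.
    """
    # line spans
    lines: list[tuple[int, int, str]] = []
    pos = 0
    for line in text.split("\n"):
        lines.append((pos, pos + len(line), line))
        pos += len(line) + 1
    labels = []
    current = "BODY"
    li = 0
    header_cache = [(s, e, _header_label(line)) for s, e, line in lines]
    for tok in tokens:
        while li < len(header_cache) and tok.start >= header_cache[li][1] + 1:
            if header_cache[li][2] is not None:
                current = header_cache[li][2]
            li += 1
        s, e, hdr = header_cache[li] if li < len(header_cache) else (0, 0, None)
        labels.append("HEADER" if hdr is not None and s <= tok.start < e else current)
    return labels


# ---------------------------------------------------------------------------
# Per-token feature extraction
# ---------------------------------------------------------------------------


def token_features(doc, tokens: TokenSequence, i: int) -> dict:
    """Token-level features for token ``i`` (see module docstring)."""
    if not (0 <= i < len(tokens)):
        raise IndexError(f"token index {i} out of range 0..{len(tokens) - 1}")
    t = tokens[i].text
    feats = {
        "token": t,
        "length": len(t),
        "all_digits": t.isdigit(),
        "init_upper": t[:1].isupper(),
        "stem": porter_stem(t) if t.isalpha() else t.lower(),
    }
    for k in range(1, 5):
        feats[f"prefix{k}"] = t[:k] if len(t) >= k else NA
        feats[f"suffix{k}"] = t[-k:] if len(t) >= k else NA
    return feats


def global_features(doc, tokens: TokenSequence, i: int) -> dict:
    """Sentence length (in tokens) and section label for token ``i``."""
    spans = tokens.sentence_spans()
    sent = tokens.sentence_index_of(i)
    s, e = spans[sent]
    text = doc.text if hasattr(doc, "text") else str(doc)
    sections = section_labels(text, tokens)
    return {"sentence_length": e - s, "section": sections[i]}


def tagging_features(tokens: TokenSequence, external_tagger=None) -> list[dict]:
    """POS/NER features for every token from the external tagger plug-in.

    The contract: ``external_tagger(tokens) -> (pos_labels, ner_labels)``,
    one label each per token. When absent, ``NA`` sentinels are emitted and
    a warning is logged once per call.
    """
    n = len(tokens)
    if external_tagger is None:
        logger.warning(
            "no external POS/NER tagger configured; emitting %r sentinels", NA
        )
        return [{"pos": NA, "ner": NA} for _ in range(n)]
    pos, ner = external_tagger(tokens)
    if len(pos) != n or len(ner) != n:
        raise ContractError(
            f"external tagger returned {len(pos)} POS / {len(ner)} NER labels "
            f"for {n} tokens"
        )
    return [{"pos": str(p), "ner": str(e)} for p, e in zip(pos, ner)]


class HeuristicTagger:
    """Built-in fallback POS/NER tagger based on surface shape.

    Deliberately crude — it exists so the tagging-based feature slots are
    populated without any external NLP dependency; any tagger honoring the
    plug-in contract can replace it.
    """

    def __call__(self, tokens: TokenSequence):
        pos, ner = [], []
        for tok in tokens:
            t = tok.text
            if t.isdigit():
                pos.append("CD")
                ner.append("NUMBER")
            elif t.isalpha():
                pos.append("NNP" if t[0].isupper() else "NN")
                ner.append("ENTITY" if t[0].isupper() else "O")
            else:
                pos.append("PUNCT")
                ner.append("O")
        return pos, ner


def extract_features(doc, tokens: TokenSequence, external_tagger=None) -> list[dict]:
    """All base features for every token of a document."""
    tagging = tagging_features(tokens, external_tagger)
    text = doc.text if hasattr(doc, "text") else str(doc)
    sections = section_labels(text, tokens)
    spans = tokens.sentence_spans()
    out = []
    sent_idx = 0
    for i in range(len(tokens)):
        while sent_idx + 1 < len(spans) and i >= spans[sent_idx][1]:
            sent_idx += 1
        s, e = spans[sent_idx] if spans else (0, 0)
        feats = token_features(doc, tokens, i)
        feats["sentence_length"] = e - s
        feats["section"] = sections[i]
        feats.update(tagging[i])
        out.append(feats)
    return out


# ---------------------------------------------------------------------------
# Feature crosses
# ---------------------------------------------------------------------------


@dataclass
class CrossSpec:
    """Tuples of (feature name, window offset) to conjoin into composites."""

    crosses: list[tuple[tuple[str, int], ...]] = field(default_factory=list)

    def validate(self, known_features=BASE_FEATURES) -> None:
        known = set(known_features)
        for cross in self.crosses:
            for name, off in cross:
                if name not in known:
                    raise ValueError(f"unknown feature name {name!r} in cross spec")
                if not -2 <= off <= 2:
                    raise ValueError(f"cross offset {off} outside window -2..+2")

    @staticmethod
    def _parse_item(item: str) -> tuple[str, int]:
        name, _, off = item.partition("@")
        return name.strip(), int(off) if off else 0

    @classmethod
    def load(cls, path_or_lines) -> "CrossSpec":
        if isinstance(path_or_lines, (str,)) or hasattr(path_or_lines, "__fspath__"):
            with open(path_or_lines, encoding="utf-8") as fh:
                lines = fh.readlines()
        else:
            lines = list(path_or_lines)
        crosses = []
        for line in lines:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            crosses.append(tuple(cls._parse_item(p) for p in line.split("&")))
        spec = cls(crosses)
        spec.validate()
        return spec

    @classmethod
    def default(cls) -> "CrossSpec":
        data = resources.files("deidkit.data").joinpath("crosses_default.txt")
        return cls.load(data.read_text(encoding="utf-8").splitlines())


def cross_name(cross: tuple[tuple[str, int], ...]) -> str:
    return "x".join(f"{name}@{off:+d}" for name, off in cross)


def build_crosses(vectors: list[dict], spec: CrossSpec) -> list[dict]:
    """Augment per-token vectors with the composite features of ``spec``.

    Offsets falling outside the sequence contribute the padding values
    ``BOS``/``EOS``. Returns new dicts; the inputs are not mutated.
    """
    if vectors:
        spec.validate(set(vectors[0]))
    n = len(vectors)
    out = [dict(v) for v in vectors]
    for cross in spec.crosses:
        name = cross_name(cross)
        for i in range(n):
            parts = []
            for feat, off in cross:
                j = i + off
                if j < 0:
                    parts.append("BOS")
                elif j >= n:
                    parts.append("EOS")
                else:
                    parts.append(str(vectors[j][feat]))
            out[i][name] = CROSS_SEP.join(parts)
    return out
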
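"""Regex initial-state annotator.

The transformation-based rule learner needs only a cheap first-pass tagging
to correct, so the initial annotator is a plain ordered list of regular
expressions, each carrying the IOB tag it assigns. Patterns are matched
against the raw text (several useful patterns contain spaces, so matching
the token stream directly would lose them) and matches are then projected
onto tokens: a token is tagged only when it lies fully inside a match;
partial overlaps leave the token untagged.

Pattern files are one ``priority<TAB>regex<TAB>tag`` per line with ``#``
comments; lower priority numbers win conflicts, then longer matches, then
leftmost. The shipped default file reproduces the published pattern table
verbatim plus a few structured-PHI patterns.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

from .corpus_io import CATEGORIES, make_tag, tag_category
from .tokenizer import TokenSequence


class PatternError(ValueError):
    """A pattern file line failed to parse or compile."""


@dataclass(frozen=True)
class RegexPattern:
    priority: int
    pattern: str
    tag: str  # "B(CAT)" or "I(CAT)"

    def __post_init__(self) -> None:
        if not (
            (self.tag.startswith("B(") or self.tag.startswith("I("))
            and self.tag.endswith(")")
            and tag_category(self.tag) in CATEGORIES
        ):
            raise PatternError(f"invalid tag {self.tag!r}")
        try:
            re.compile(self.pattern)
        except re.error as exc:
            raise PatternError(f"pattern {self.pattern!r} does not compile: {exc}")

    @property
    def compiled(self):
        return re.compile(self.pattern)


def parse_patterns(lines, source: str = "<patterns>") -> list[RegexPattern]:
    patterns = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise PatternError(
                f"{source}:{lineno}: expected 'priority<TAB>regex<TAB>tag', got {line!r}"
            )
        try:
            priority = int(parts[0])
        except ValueError:
            raise PatternError(f"{source}:{lineno}: bad priority {parts[0]!r}")
        try:
            patterns.append(RegexPattern(priority, parts[1], parts[2]))
        except PatternError as exc:
            raise PatternError(f"{source}:{lineno}: {exc}")
    patterns.sort(key=lambda p: p.priority)  # stable: file order within priority
    return patterns


def load_patterns(path) -> list[RegexPattern]:
    """Load a pattern file, ordered by priority then file order."""
    with open(path, encoding="utf-8") as fh:
        return parse_patterns(fh, source=str(path))


def default_patterns() -> list[RegexPattern]:
    text = (
        resources.files("deidkit.data")
        .joinpath("patterns_default.tsv")
        .read_text(encoding="utf-8")
    )
    return parse_patterns(text.splitlines(), source="patterns_default.tsv")


def annotate(
    text: str, tokens: TokenSequence, patterns: list[RegexPattern]
) -> list[str]:
    """Tag tokens from regex matches over the raw text.

    Conflicts are resolved per token: lower priority number first, then the
    longer match, then the leftmost. A ``B(...)`` pattern tags the first
    token inside each match B and the rest I of the same category; an
    ``I(...)`` pattern tags every covered token I (decode-time repair
    normalizes stray I tags later).
    """
    n = len(tokens)
    tags: list[str | None] = [None] * n
    matches = []
    for order, pat in enumerate(patterns):
        rx = pat.compiled
        for m in rx.finditer(text):
            if m.end() > m.start():
                matches.append(
                    (pat.priority, -(m.end() - m.start()), m.start(), order, m.end(), pat.tag)
                )
    matches.sort()
    for priority, neglen, start, order, end, tag in matches:
        cat = tag_category(tag)
        inside = [
            i
            for i, tok in enumerate(tokens)
            if start <= tok.start and tok.end <= end
        ]
        for rank, i in enumerate(inside):
            if tags[i] is not None:
                continue
            if tag.startswith("B(") and rank == 0:
                tags[i] = make_tag("B", cat)
            else:
                tags[i] = make_tag("I", cat)
    return [t if t is not None else "O" for t in tags]
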
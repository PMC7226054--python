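"""Subword tokenization for clinical notes.

Whitespace tokens routinely glue PHI to surrounding text ("Dr.Smith"
contains the name "Smith"), which makes exact character-offset spans
unreachable for a token-level tagger. The tokenizer therefore works at
subword level in three steps:

1. split every character apart except runs of letters and runs of digits;
2. split letter runs immediately before internal uppercase letters;
3. apply byte pair encoding (BPE) merges learned on the corpus, to undo
   over-splitting of frequent units.

Every token carries its half-open character span ``[start, end)`` into the
source text, and no step ever crosses a whitespace boundary, so the source
string is always reconstructible from the tokens plus the skipped
whitespace.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field


@dataclass(frozen=True)
class Token:
    """A subword token with its half-open character span in the source."""

    text: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.text):
            raise ValueError(
                f"token text {self.text!r} does not fit span [{self.start}, {self.end})"
            )


@dataclass
class TokenSequence:
    """Ordered tokens plus sentence-start indices.

    ``sentence_starts`` holds the token index opening each sentence; it always
    begins with 0 for a non-empty sequence.
    """

    tokens: list[Token] = field(default_factory=list)
    sentence_starts: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self):
        return iter(self.tokens)

    def __getitem__(self, i):
        return self.tokens[i]

    def sentence_spans(self) -> list[tuple[int, int]]:
        """Half-open token-index ranges of the sentences."""
        if not self.tokens:
            return []
        starts = self.sentence_starts or [0]
        return [
            (s, e)
            for s, e in zip(starts, list(starts[1:]) + [len(self.tokens)])
        ]

    def sentence_index_of(self, i: int) -> int:
        starts = self.sentence_starts or [0]
        lo = 0
        for k, s in enumerate(starts):
            if s <= i:
                lo = k
            else:
                break
        return lo


def _char_class(ch: str) -> str:
    if ch.isspace():
        return "space"
    cat = unicodedata.category(ch)
    if cat.startswith("L"):
        return "letter"
    if cat == "Nd":
        return "digit"
    return "other"


def split_char_runs(text: str) -> TokenSequence:
    """Split every character apart except maximal letter runs and digit runs.

    Whitespace yields no token; every other non-letter, non-digit character
    becomes a single-character token.
    """
    tokens: list[Token] = []
    i, n = 0, len(text)
    while i < n:
        cls = _char_class(text[i])
        if cls == "space":
            i += 1
            continue
        if cls in ("letter", "digit"):
            j = i + 1
            while j < n and _char_class(text[j]) == cls:
                j += 1
            tokens.append(Token(text[i:j], i, j))
            i = j
        else:
            tokens.append(Token(text[i], i, i + 1))
            i += 1
    seq = TokenSequence(tokens)
    seq.sentence_starts = _sentence_starts(text, tokens)
    return seq


def split_uppercase(token: Token) -> list[Token]:
    """Split a letter-run token immediately before every internal uppercase.

    "HealthCare" -> ["Health", "Care"]; "Edwin" stays whole; "ABC" becomes
    three single-letter tokens.
    """
    cuts = [0]
    for k in range(1, len(token.text)):
        if token.text[k].isupper():
            cuts.append(k)
    cuts.append(len(token.text))
    return [
        Token(token.text[a:b], token.start + a, token.start + b)
        for a, b in zip(cuts, cuts[1:])
        if a < b
    ]


def _split_uppercase_seq(seq: TokenSequence) -> TokenSequence:
    out: list[Token] = []
    for tok in seq.tokens:
        if tok.text and tok.text[0].isalpha() and tok.text.isalpha():
            out.extend(split_uppercase(tok))
        else:
            out.append(tok)
    new = TokenSequence(out)
    new.sentence_starts = _remap_sentence_starts(seq, new)
    return new


# ---------------------------------------------------------------------------
# Byte pair encoding over the step-1/2 token stream.
#
# Merges are restricted to token pairs that are character-adjacent, i.e. came
# from splitting a single whitespace-delimited chunk, so offsets stay exact
# and merges never swallow whitespace.
# ---------------------------------------------------------------------------


@dataclass
class BPEModel:
    """Ordered adjacent-pair merge list."""

    merges: list[tuple[str, str]] = field(default_factory=list)

    @property
    def num_merges(self) -> int:
        return len(self.merges)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for left, right in self.merges:
                fh.write(f"{left} {right}\n")

    @classmethod
    def load(cls, path) -> "BPEModel":
        merges = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                left, right = line.split(" ")
                merges.append((left, right))
        return cls(merges)


def _chunks(tokens: list[Token]) -> list[list[Token]]:
    """Group tokens into runs that are character-adjacent (one whitespace chunk)."""
    groups: list[list[Token]] = []
    for tok in tokens:
        if groups and groups[-1][-1].end == tok.start:
            groups[-1].append(tok)
        else:
            groups.append([tok])
    return groups


def _merge_chunk(chunk: list[Token], pair: tuple[str, str]) -> list[Token]:
    out: list[Token] = []
    i = 0
    while i < len(chunk):
        if (
            i + 1 < len(chunk)
            and chunk[i].text == pair[0]
            and chunk[i + 1].text == pair[1]
        ):
            out.append(
                Token(chunk[i].text + chunk[i + 1].text, chunk[i].start, chunk[i + 1].end)
            )
            i += 2
        else:
            out.append(chunk[i])
            i += 1
    return out


def learn_bpe(corpus: list[TokenSequence], num_merges: int) -> BPEModel:
    """Learn greedy most-frequent-adjacent-pair merges from a tokenized corpus.

    Ties are broken by lexicographic order of the pair. Learning stops early
    once no within-chunk pair occurs at least twice, since merging hapax
    pairs cannot reduce sparseness.
    """
    if num_merges < 0:
        raise ValueError("num_merges must be >= 0")
    chunks = [list(c) for seq in corpus for c in _chunks(seq.tokens)]
    merges: list[tuple[str, str]] = []
    for _ in range(num_merges):
        counts: dict[tuple[str, str], int] = {}
        for chunk in chunks:
            for a, b in zip(chunk, chunk[1:]):
                key = (a.text, b.text)
                counts[key] = counts.get(key, 0) + 1
        if not counts:
            break
        best = min(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        if best[1] < 2:
            break
        merges.append(best[0])
        chunks = [_merge_chunk(c, best[0]) for c in chunks]
    return BPEModel(merges)


def apply_bpe(seq: TokenSequence, model: BPEModel | None) -> TokenSequence:
    """Apply learned merges, in order, within whitespace chunks only."""
    if model is None or not model.merges:
        return seq
    out: list[Token] = []
    for chunk in _chunks(seq.tokens):
        for pair in model.merges:
            chunk = _merge_chunk(chunk, pair)
        out.extend(chunk)
    new = TokenSequence(out)
    new.sentence_starts = _remap_sentence_starts(seq, new)
    return new


# ---------------------------------------------------------------------------
# Sentence boundaries: newline, or sentence-final punctuation followed by
# whitespace and an uppercase letter. Pluggable via the `splitter` argument
# of tokenize().
# ---------------------------------------------------------------------------


def sentence_break_positions(text: str) -> list[int]:
    """Character positions at which a new sentence starts (position 0 implied)."""
    breaks: list[int] = []
    n = len(text)
    for i, ch in enumerate(text):
        if ch == "\n":
            breaks.append(i + 1)
        elif ch in ".?!":
            j = i + 1
            while j < n and text[j] in " \t":
                j += 1
            if j > i + 1 and j < n and text[j].isupper():
                breaks.append(j)
    return breaks


def _sentence_starts(text: str, tokens: list[Token]) -> list[int]:
    if not tokens:
        return []
    breaks = sentence_break_positions(text)
    starts = [0]
    bi = 0
    for k, tok in enumerate(tokens):
        while bi < len(breaks) and breaks[bi] <= tok.start:
            if k > 0 and starts[-1] != k:
                starts.append(k)
            bi += 1
    return starts


def _remap_sentence_starts(old: TokenSequence, new: TokenSequence) -> list[int]:
    """Carry sentence starts across a token-merging/splitting step by offsets."""
    if not new.tokens:
        return []
    start_chars = {old.tokens[i].start for i in (old.sentence_starts or [0])}
    starts = [
        k for k, tok in enumerate(new.tokens) if tok.start in start_chars
    ]
    if not starts or starts[0] != 0:
        starts = [0] + starts
    return starts


def tokenize(
    text: str,
    model: BPEModel | None = None,
    splitter=None,
) -> TokenSequence:
    """Run the full three-step tokenization.

    `model` is the learned BPE model (None skips step 3). `splitter`
    optionally replaces the built-in sentence boundary detector; it must map
    text -> list of character positions starting new sentences.
    """
    seq = split_char_runs(text)
    seq = _split_uppercase_seq(seq)
    if splitter is not None:
        breaks = splitter(text)
        starts = [0] if seq.tokens else []
        bi = 0
        for k, tok in enumerate(seq.tokens):
            while bi < len(breaks) and breaks[bi] <= tok.start:
                if k > 0 and starts[-1] != k:
                    starts.append(k)
                bi += 1
        seq.sentence_starts = starts
    return apply_bpe(seq, model)


def phi_alignment_error_rate(docs, model: BPEModel | None = None) -> float:
    """Fraction of gold entities whose start or end falls strictly inside a token.

    A misaligned entity can never be produced exactly by a token-level IOB
    tagger, so this rate bounds achievable recall.
    """
    total = 0
    misaligned = 0
    for doc in docs:
        seq = tokenize(doc.text, model)
        for ent in doc.entities:
            total += 1
            inside_start = any(t.start < ent.start < t.end for t in seq.tokens)
            inside_end = any(t.start < ent.end < t.end for t in seq.tokens)
            if inside_start or inside_end:
                misaligned += 1
    return misaligned / total if total else 0.0
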
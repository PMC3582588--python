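"""Sentence segmentation and parse information behind a backend contract.

The coreference rules need four things per sentence: tokens with POS and
lemma, noun-phrase chunks with head words, a flag for chunks embedding a
subordinate clause, and a few typed dependency relations (possessive,
prepositional, relative attachment).  Any parser able to emit those
qualifies as a backend; the original system used a wide-coverage HPSG
parser, but nothing here depends on one.

Two sources of parses are provided:

* :func:`load_gold_parse` — reads a line-delimited JSON fixture (one record
  per sentence, schema below) with full invariant validation.  All tests
  run from fixtures, so no external parser is ever required.
* :func:`parse_document` with a registered backend.  A self-contained
  heuristic backend (``"simple"``: regex tokenizer, lexicon/suffix POS
  tagger, greedy NP chunker) is registered so plain text can be processed
  without third-party NLP stacks.  It is deliberately modest; fixture
  parses are authoritative in tests.

Fixture schema (JSON object per line)::

    {"index": 0, "start": 0, "end": 57, "text": "...sentence text...",
     "tokens": [{"start": 0, "end": 3, "pos": "DT", "lemma": "the"}, ...],
     "chunks": [{"start": 0, "end": 14, "head": 2, "np": true,
                 "subclause": false}, ...],
     "edges": [{"label": "prep-arg12", "arg1": ["chunk", 0],
                "arg2": ["chunk", 1]}, ...]}

Offsets are document-absolute; ``head`` indexes the sentence's token list;
edge arguments name a ``["chunk", i]`` or ``["token", i]`` of the same
sentence.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Protocol, Union

from .standoff_io import Document, TextSpan

__all__ = [
    "Token",
    "Chunk",
    "DependencyEdge",
    "ParsedSentence",
    "ParseFixtureError",
    "parse_document",
    "load_gold_parse",
    "dump_gold_parse",
    "relative_argument",
    "get_backend",
    "register_backend",
    "lemma_of",
    "RELATIVE_PRONOUN_POS",
    "RELATIVE_PRONOUN_LEMMAS",
]


class ParseFixtureError(ValueError):
    """Gold-parse fixture violates the schema or a parse invariant."""


@dataclass(frozen=True)
class Token:
    span: TextSpan
    pos: str
    lemma: str


@dataclass(frozen=True)
class Chunk:
    span: TextSpan
    head: Token
    is_noun_phrase: bool = True
    contains_subordinate_clause: bool = False

    def __post_init__(self):
        if not self.span.contains(self.head.span):
            raise ParseFixtureError(
                f"chunk head {self.head.span} outside chunk span {self.span}")


EdgeArg = Union[Chunk, Token]


@dataclass(frozen=True)
class DependencyEdge:
    label: str
    arg1: EdgeArg
    arg2: EdgeArg

    def arg_span(self, which: int) -> TextSpan:
        return (self.arg1 if which == 1 else self.arg2).span


@dataclass(frozen=True)
class ParsedSentence:
    index: int
    span: TextSpan
    tokens: tuple[Token, ...] = ()
    chunks: tuple[Chunk, ...] = ()
    edges: tuple[DependencyEdge, ...] = ()
    parsed: bool = True


# ---------------------------------------------------------------------------
# Lemmatization helper shared by backends, fixtures and rule modules.

_VERB_LEMMAS = {
    "is": "be", "are": "be", "was": "be", "were": "be", "been": "be",
    "am": "be", "being": "be", "'s": "be",
    "seems": "seem", "seemed": "seem", "appears": "appear",
    "appeared": "appear", "means": "mean", "meant": "mean",
    "follows": "follow", "followed": "follow", "makes": "make",
    "made": "make", "finds": "find", "found": "find", "takes": "take",
    "took": "take", "taken": "take", "shows": "show", "has": "have",
    "had": "have", "does": "do", "did": "do",
}


def _singularize(word: str) -> str:
    if len(word) > 3 and word.endswith("ies"):
        return word[:-3] + "y"
    if len(word) > 3 and word.endswith(("ses", "xes", "ches", "shes", "zes")):
        return word[:-2]
    if len(word) > 2 and word.endswith("s") and not word.endswith(("ss", "us", "is")):
        return word[:-1]
    return word


def lemma_of(word: str, pos: str) -> str:
    """Cheap lemmatizer: lowercase, plural stripping for nouns, a small
    irregular-verb table.  Only the forms the rules inspect need to be right
    (be-forms, the pleonastic-pattern verbs, noun plurals, keyword nouns)."""
    w = word.lower()
    if pos.startswith("V"):
        return _VERB_LEMMAS.get(w, w[:-1] if w.endswith("s") and pos == "VBZ" else w)
    if pos in ("NNS", "NNPS"):
        return _singularize(w)
    return w


# ---------------------------------------------------------------------------
# Gold-parse fixtures

def _chunk_sort_key(c: Chunk):
    return (c.span.start, -c.span.end)


def _validate_sentence(sent: ParsedSentence) -> None:
    prev_end = sent.span.start
    for tok in sent.tokens:
        if not sent.span.contains(tok.span):
            raise ParseFixtureError(f"token {tok.span} outside sentence {sent.span}")
        if tok.span.start < prev_end:
            raise ParseFixtureError(f"tokens overlap or unordered at {tok.span}")
        prev_end = tok.span.end
    for c in sent.chunks:
        if not sent.span.contains(c.span):
            raise ParseFixtureError(f"chunk {c.span} outside sentence {sent.span}")
    # chunk nesting must form a forest: any two chunks disjoint or nested
    for i, a in enumerate(sent.chunks):
        for b in sent.chunks[i + 1:]:
            if a.span.overlaps(b.span) and not (
                    a.span.contains(b.span) or b.span.contains(a.span)):
                raise ParseFixtureError(
                    f"chunks {a.span} and {b.span} cross without nesting")
    for e in sent.edges:
        for arg in (e.arg1, e.arg2):
            if not sent.span.contains(arg.span):
                raise ParseFixtureError(
                    f"edge argument {arg.span} outside sentence {sent.span}")


def _sentence_from_record(rec: dict, line_no: int, path) -> ParsedSentence:
    try:
        s_start, s_end, s_text = rec["start"], rec["end"], rec["text"]
        sent_span = TextSpan(s_start, s_end, s_text)

        def slice_text(a: int, b: int) -> str:
            return s_text[a - s_start:b - s_start]

        tokens = tuple(
            Token(TextSpan(t["start"], t["end"],
                           slice_text(t["start"], t["end"])),
                  t["pos"], t.get("lemma") or lemma_of(
                      slice_text(t["start"], t["end"]), t["pos"]))
            for t in rec["tokens"])
        chunks = tuple(
            Chunk(TextSpan(c["start"], c["end"],
                           slice_text(c["start"], c["end"])),
                  tokens[c["head"]],
                  c.get("np", True), c.get("subclause", False))
            for c in rec["chunks"])

        def resolve(arg) -> EdgeArg:
            kind, idx = arg
            if kind == "chunk":
                return chunks[idx]
            if kind == "token":
                return tokens[idx]
            raise KeyError(kind)

        edges = tuple(
            DependencyEdge(e["label"], resolve(e["arg1"]), resolve(e["arg2"]))
            for e in rec.get("edges", []))
        sent = ParsedSentence(rec["index"], sent_span, tokens, chunks, edges,
                              rec.get("parsed", True))
    except ParseFixtureError as exc:
        raise ParseFixtureError(f"{path}:{line_no}: {exc}") from None
    except (KeyError, IndexError, TypeError, ValueError) as exc:
        raise ParseFixtureError(f"{path}:{line_no}: bad record ({exc!r})") from None
    _validate_sentence(sent)
    return sent


def load_gold_parse(fixture_path) -> list[ParsedSentence]:
    """Load a gold-parse fixture file, validating every invariant."""
    sentences = []
    for line_no, line in enumerate(
            Path(fixture_path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        rec = json.loads(line)
        sentences.append(_sentence_from_record(rec, line_no, fixture_path))
    for prev, cur in zip(sentences, sentences[1:]):
        if cur.span.start < prev.span.end:
            raise ParseFixtureError(
                f"{fixture_path}: sentence spans out of order at index {cur.index}")
    return sentences


def sentence_to_record(sent: ParsedSentence) -> dict:
    tok_index = {t: i for i, t in enumerate(sent.tokens)}
    chunk_index = {c: i for i, c in enumerate(sent.chunks)}

    def encode(arg: EdgeArg):
        if isinstance(arg, Chunk):
            return ["chunk", chunk_index[arg]]
        return ["token", tok_index[arg]]

    return {
        "index": sent.index,
        "start": sent.span.start,
        "end": sent.span.end,
        "text": sent.span.text,
        "parsed": sent.parsed,
        "tokens": [{"start": t.span.start, "end": t.span.end,
                    "pos": t.pos, "lemma": t.lemma} for t in sent.tokens],
        "chunks": [{"start": c.span.start, "end": c.span.end,
                    "head": tok_index[c.head], "np": c.is_noun_phrase,
                    "subclause": c.contains_subordinate_clause}
                   for c in sent.chunks],
        "edges": [{"label": e.label, "arg1": encode(e.arg1),
                   "arg2": encode(e.arg2)} for e in sent.edges],
    }


def dump_gold_parse(sentences: list[ParsedSentence], fixture_path) -> None:
    """Serialize sentences in the fixture schema (byte-stable)."""
    lines = [json.dumps(sentence_to_record(s), sort_keys=True,
                        separators=(",", ":")) for s in sentences]
    Path(fixture_path).write_text("".join(l + "\n" for l in lines),
                                  encoding="utf-8")


# ---------------------------------------------------------------------------
# Relative-pronoun attachment

RELATIVE_PRONOUN_POS = {"WDT", "WP"}
RELATIVE_PRONOUN_LEMMAS = {"that", "which", "who", "whom"}


def relative_argument(edges, relative_pronoun_token: Token):
    """Return the chunk the parser attached a relative clause to.

    ``None`` signals that the parser found no attachment (the resolution of
    that relative pronoun then fails, mirroring parse-failure behavior).
    """
    tok = relative_pronoun_token
    if tok.pos not in RELATIVE_PRONOUN_POS and \
            tok.lemma not in RELATIVE_PRONOUN_LEMMAS:
        raise ValueError(f"{tok.span.text!r} ({tok.pos}) is not a relative pronoun")
    for edge in edges:
        if not edge.label.startswith("relative"):
            continue
        for pron_arg, head_arg in ((edge.arg2, edge.arg1), (edge.arg1, edge.arg2)):
            covers = (pron_arg.span == tok.span or
                      pron_arg.span.contains(tok.span))
            if covers and isinstance(head_arg, Chunk):
                return head_arg
    return None


# ---------------------------------------------------------------------------
# Backend registry and document-level parsing

class ParserBackend(Protocol):
    def segment(self, text: str) -> list[tuple[int, int]]: ...
    def parse_sentence(self, text: str, start: int, end: int,
                       index: int) -> ParsedSentence: ...


_BACKENDS: dict[str, Callable[[], ParserBackend]] = {}


def register_backend(name: str):
    def deco(factory):
        _BACKENDS[name] = factory
        return factory
    return deco


def get_backend(name: str) -> ParserBackend:
    try:
        return _BACKENDS[name]()
    except KeyError:
        raise KeyError(
            f"unknown parser backend {name!r}; registered: {sorted(_BACKENDS)}"
        ) from None


def parse_document(document: Document, backend: ParserBackend | str
                   ) -> list[ParsedSentence]:
    """Segment and parse a document with the given backend.

    A backend failure on an individual sentence yields that sentence marked
    ``parsed=False`` with empty structure; downstream steps skip it.
    """
    if isinstance(backend, str):
        backend = get_backend(backend)
    text = document.text
    sentences: list[ParsedSentence] = []
    for index, (start, end) in enumerate(backend.segment(text)):
        try:
            sent = backend.parse_sentence(text, start, end, index)
            _validate_sentence(sent)
        except Exception:
            sent = ParsedSentence(index, TextSpan(start, end, text[start:end]),
                                  parsed=False)
        sentences.append(sent)
    return sentences


# ---------------------------------------------------------------------------
# Heuristic default backend

_TOKEN_RE = re.compile(r"[A-Za-z0-9][\w\-/().+']*|\S")
_SENT_SPLIT_RE = re.compile(r"(?<=[.!?])\s+(?=[A-Z(\"'])")

_POS_LEXICON = {
    "the": "DT", "a": "DT", "an": "DT", "this": "DT", "that": "DT",
    "these": "DT", "those": "DT", "both": "DT", "either": "DT",
    "it": "PRP", "they": "PRP", "them": "PRP", "he": "PRP", "she": "PRP",
    "we": "PRP", "i": "PRP", "you": "PRP", "us": "PRP", "me": "PRP",
    "its": "PRP$", "their": "PRP$", "his": "PRP$", "her": "PRP$",
    "our": "PRP$", "my": "PRP$", "your": "PRP$",
    "itself": "PRP", "themselves": "PRP",
    "which": "WDT", "who": "WP", "whom": "WP",
    "of": "IN", "in": "IN", "on": "IN", "for": "IN", "by": "IN",
    "with": "IN", "from": "IN", "to": "TO", "at": "IN", "into": "IN",
    "through": "IN", "via": "IN", "although": "IN", "because": "IN",
    "as": "IN", "and": "CC", "or": "CC", "but": "CC",
    "is": "VBZ", "are": "VBP", "was": "VBD", "were": "VBD", "be": "VB",
    "been": "VBN", "not": "RB", "also": "RB", "now": "RB", "here": "RB",
    "can": "MD", "may": "MD", "might": "MD", "will": "MD", "should": "MD",
}

_NP_POS = {"DT", "PRP$", "JJ", "NN", "NNS", "NNP", "NNPS", "CD"}


@register_backend("simple")
class SimpleBackend:
    """Heuristic tokenizer/POS-tagger/NP-chunker.

    Convenience for running the pipeline on plain text without external
    parsers: function words from a lexicon, suffix heuristics for the rest,
    greedy maximal determiner–modifier–noun chunks with the last noun as
    head, ``X of Y`` prepositional edges and ``NP , which`` relative edges.
    """

    def segment(self, text: str) -> list[tuple[int, int]]:
        spans, pos = [], 0
        for part in _SENT_SPLIT_RE.split(text):
            start = text.index(part, pos)
            end = start + len(part)
            if part.strip():
                spans.append((start, end))
            pos = end
        return spans

    def _tag(self, word: str, prev_pos: str) -> str:
        w = word.lower()
        if w in _POS_LEXICON:
            return _POS_LEXICON[w]
        if not word[0].isalnum():
            return word[0]
        if word.endswith("ly"):
            return "RB"
        if word.endswith("ing"):
            # gerunds after prepositions/verbs; nominal "binding" inside NPs
            return "NN" if prev_pos in _NP_POS else "VBG"
        if word.endswith("ed"):
            return "VBD"
        if prev_pos in ("PRP", "PRP$", "WDT", "WP", "NN", "NNS") and \
                word.endswith("s") and not word.endswith("ss"):
            return "VBZ"
        if word.endswith("s") and not word.endswith(("ss", "us", "is")):
            return "NNS"
        if word.endswith(("al", "ic", "ive", "ous", "able", "ary")):
            return "JJ"
        return "NN"

    def parse_sentence(self, text: str, start: int, end: int,
                       index: int) -> ParsedSentence:
        sent_text = text[start:end]
        tokens: list[Token] = []
        prev_pos = ""
        for m in _TOKEN_RE.finditer(sent_text):
            word = m.group()
            pos = self._tag(word, prev_pos)
            prev_pos = pos
            tokens.append(Token(TextSpan(start + m.start(), start + m.end(), word),
                                pos, lemma_of(word, pos)))

        chunks: list[Chunk] = []
        i = 0
        while i < len(tokens):
            if tokens[i].pos in _NP_POS:
                j = i
                while j + 1 < len(tokens) and tokens[j + 1].pos in _NP_POS:
                    j += 1
                nouns = [t for t in tokens[i:j + 1]
                         if t.pos in ("NN", "NNS", "NNP", "NNPS")]
                if nouns:
                    span = TextSpan(tokens[i].span.start, tokens[j].span.end,
                                    text[tokens[i].span.start:tokens[j].span.end])
                    chunks.append(Chunk(span, nouns[-1]))
                i = j + 1
            else:
                i += 1

        edges: list[DependencyEdge] = []
        for a, b in zip(chunks, chunks[1:]):
            between = [t for t in tokens
                       if a.span.end <= t.span.start < b.span.start]
            if len(between) == 1 and between[0].lemma == "of":
                edges.append(DependencyEdge("prep-arg12", a, b))
        for tok_i, tok in enumerate(tokens):
            if tok.pos in RELATIVE_PRONOUN_POS:
                preceding = [c for c in chunks if c.span.end <= tok.span.start]
                if preceding:
                    edges.append(DependencyEdge("relative-arg", preceding[-1], tok))
        for tok in tokens:
            if tok.pos == "PRP$":
                holder = next((c for c in chunks
                               if c.span.contains(tok.span)
                               and c.span.length > tok.span.length), None)
                if holder is not None:
                    edges.append(DependencyEdge("poss-arg12", tok, holder))

        return ParsedSentence(index, TextSpan(start, end, sent_text),
                              tuple(tokens), tuple(chunks), tuple(edges))
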
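"""Markable detection: build the set of candidate coreferential expressions.

Markables are (a) noun-phrase chunks that do not embed a subordinate clause
and (b) pronoun tokens.  When several chunks share a head token — a parser
typically emits nested NPs like "role" / "role for c-Myc in apoptosis" /
"this role for c-Myc in apoptosis" — only the longest survives, so each
retained head word yields exactly one markable per sentence.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .standoff_io import TextSpan
from .syntax_adapter import Chunk, ParsedSentence, Token

__all__ = [
    "Markable",
    "detect_markables",
    "dedupe_by_head",
    "grammatical_number",
    "SINGULAR", "PLURAL", "UNKNOWN_NUMBER",
    "PROTEIN", "NON_PROTEIN", "UNKNOWN",
    "NP", "DEFNP",
    "PRON_POSS", "PRON_PERS", "PRON_DEM", "PRON_REFL", "PRON_RELAT",
    "PRON_OTHER", "PRONOUN_TYPES",
]

# grammatical number
SINGULAR = "singular"
PLURAL = "plural"
UNKNOWN_NUMBER = "unknown"

# semantic classes
PROTEIN = "PROTEIN"
NON_PROTEIN = "NON_PROTEIN"
UNKNOWN = "UNKNOWN"

# syntactic types
NP = "NP"
DEFNP = "definite-NP"
PRON_POSS = "PRON_POSS"
PRON_PERS = "PRON_PERS"
PRON_DEM = "PRON_DEM"
PRON_REFL = "PRON_REFL"
PRON_RELAT = "PRON_RELAT"
PRON_OTHER = "PRON_OTHER"
PRONOUN_TYPES = frozenset(
    {PRON_POSS, PRON_PERS, PRON_DEM, PRON_REFL, PRON_RELAT, PRON_OTHER})

_DEMONSTRATIVES = {"this", "that", "these", "those"}
_OTHER_PRONOUNS = {"both", "either"}
_SINGULAR_PRONOUNS = {"it", "its", "itself", "this", "that"}
_PLURAL_PRONOUNS = {"they", "their", "them", "themselves", "these", "those"}
_DEFINITE_FIRST = {"the", "this", "that", "these", "those", "both",
                   "its", "their"}
_NOUN_POS = {"NN", "NNS", "NNP", "NNPS"}


@dataclass(frozen=True)
class Markable:
    """A candidate coreferential expression.

    ``tokens`` are the sentence tokens covered by the span (a single token
    for pronoun markables); ``semantic_class`` starts UNKNOWN and is filled
    by the semantic classification step.
    """

    span: TextSpan
    head: Token
    sentence_index: int
    syntactic_type: str
    number: str
    tokens: tuple[Token, ...] = ()
    semantic_class: str = UNKNOWN

    @property
    def is_pronoun(self) -> bool:
        return self.syntactic_type in PRONOUN_TYPES

    def with_semantic_class(self, semantic_class: str) -> "Markable":
        return replace(self, semantic_class=semantic_class)


def dedupe_by_head(chunks: Sequence[Chunk]) -> Chunk:
    """Of chunks sharing a head token, keep the longest (tie: earliest)."""
    if not chunks:
        raise ValueError("dedupe_by_head requires at least one chunk")
    heads = {c.head for c in chunks}
    if len(heads) != 1:
        raise ValueError("chunks passed to dedupe_by_head must share a head token")
    return max(chunks, key=lambda c: (c.span.length, -c.span.start))


def _pronoun_subtype(token: Token) -> str:
    if token.pos == "PRP$":
        return PRON_POSS
    if token.pos in ("WDT", "WP", "WP$"):
        return PRON_RELAT
    if token.lemma in ("itself", "themselves", "himself", "herself",
                       "myself", "ourselves", "yourself"):
        return PRON_REFL
    if token.lemma in _DEMONSTRATIVES:
        return PRON_DEM
    if token.lemma in _OTHER_PRONOUNS:
        return PRON_OTHER
    return PRON_PERS


def _is_coordinated(tokens: Iterable[Token]) -> bool:
    toks = list(tokens)
    has_cc = any(t.pos == "CC" and t.lemma in ("and", "or") for t in toks)
    return has_cc and sum(t.pos in _NOUN_POS for t in toks) >= 2


def grammatical_number(markable: Markable) -> str:
    """Singular / plural / unknown from lexicon (pronouns) or head POS (NPs).

    Coordinated NPs count as plural; anything undecidable is ``unknown``,
    which never triggers a number conflict downstream.
    """
    if markable.is_pronoun:
        lemma = markable.head.lemma
        if lemma in _SINGULAR_PRONOUNS:
            return SINGULAR
        if lemma in _PLURAL_PRONOUNS:
            return PLURAL
        return UNKNOWN_NUMBER
    if _is_coordinated(markable.tokens):
        return PLURAL
    pos = markable.head.pos
    if pos in ("NNS", "NNPS"):
        return PLURAL
    if pos in ("NN", "NNP"):
        return SINGULAR
    return UNKNOWN_NUMBER


def _np_syntactic_type(tokens: Sequence[Token]) -> str:
    if tokens and (tokens[0].lemma in _DEFINITE_FIRST or tokens[0].pos == "PRP$"):
        return DEFNP
    return NP


def _tokens_in(span: TextSpan, sentence: ParsedSentence) -> tuple[Token, ...]:
    return tuple(t for t in sentence.tokens if span.contains(t.span))


def _pronoun_tokens(sentence: ParsedSentence) -> list[Token]:
    """Pronoun tokens of a sentence.

    PRP/PRP$/WP/WDT tokens always count; demonstrative and both/either
    determiners only when standalone, i.e. not opening a larger NP chunk
    ("this is likely" vs "This role for c-Myc ...")."""
    out = []
    for tok in sentence.tokens:
        if tok.pos in ("PRP", "PRP$", "WP", "WP$", "WDT"):
            out.append(tok)
        elif tok.pos == "DT" and tok.lemma in (_DEMONSTRATIVES | _OTHER_PRONOUNS):
            opens_np = any(c.span.start == tok.span.start
                           and c.span.length > tok.span.length
                           for c in sentence.chunks if c.is_noun_phrase)
            if not opens_np:
                out.append(tok)
    return out


def detect_markables(parsed_sentences: Sequence[ParsedSentence]
                     ) -> list[Markable]:
    """Collect markables from parsed sentences, sorted by start offset.

    Unparsed sentences contribute nothing.  Chunks flagged as containing a
    subordinate clause are dropped before head-word deduplication, so e.g.
    "studies" wins over "studies using ... apoptosis".
    """
    markables: list[Markable] = []
    for sent in parsed_sentences:
        if not sent.parsed:
            continue
        pronouns = _pronoun_tokens(sent)
        pronoun_spans = {t.span for t in pronouns}
        for tok in pronouns:
            m = Markable(tok.span, tok, sent.index, _pronoun_subtype(tok),
                         UNKNOWN_NUMBER, (tok,))
            markables.append(replace(m, number=grammatical_number(m)))

        by_head: dict[Token, list[Chunk]] = {}
        for chunk in sent.chunks:
            if not chunk.is_noun_phrase or chunk.contains_subordinate_clause:
                continue
            if chunk.span in pronoun_spans:
                continue  # single-pronoun chunk: already a pronoun markable
            by_head.setdefault(chunk.head, []).append(chunk)
        for head, group in by_head.items():
            chunk = dedupe_by_head(group)
            tokens = _tokens_in(chunk.span, sent)
            m = Markable(chunk.span, head, sent.index,
                         _np_syntactic_type(tokens), UNKNOWN_NUMBER, tokens)
            markables.append(replace(m, number=grammatical_number(m)))

    markables.sort(key=lambda m: (m.span.start, m.span.end))
    return markables
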
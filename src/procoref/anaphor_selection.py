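"""Anaphor selection: decide which markables are anaphoric.

Pronouns and definite noun phrases are the base candidates.  Filters then
remove what cannot be a protein anaphor:

* person filter — first/second-person and human pronouns (*I, we, you, he,
  she*) never refer to proteins;
* pleonastic-*it* filter — four surface patterns ("it seems that ...",
  "it is important for X to ...") recognize non-referential *it*;
* PRO-ANA-SEM — possessive pronouns whose context NP carries no protein
  key word stay semantically unknown and are dropped;
* DEFNP-ANA-SEM — definite NPs whose head word is not a protein head word
  are dropped, as are definite NPs that directly contain a given protein
  mention (those are direct references, not anaphors).

Relative pronouns are always kept: their resolution is handled by the
parser-attachment rule downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import SimpleNamespace
from typing import Optional, Sequence

from .markable_detection import (DEFNP, Markable, NON_PROTEIN, PROTEIN,
                                 PRON_DEM, PRON_OTHER, PRON_PERS, PRON_POSS,
                                 PRON_REFL, PRON_RELAT, UNKNOWN)
from .semantic_classification import (SemanticLexicons, containing_noun_phrase,
                                      defnp_ana_sem, pro_ana_sem)
from .standoff_io import ProteinMention
from .syntax_adapter import ParsedSentence, Token

__all__ = [
    "Anaphor",
    "AnaphorSelectionConfig",
    "RELAT", "DNP", "OTHER",
    "is_pleonastic_it",
    "classify_anaphor_type",
    "select_anaphors",
]

RELAT = "RELAT"
DNP = "DNP"
OTHER = "OTHER"

_PERSON_PRONOUNS = {"i", "we", "you", "me", "us", "my", "our", "your",
                    "he", "she", "him", "his", "her",
                    "myself", "ourselves", "yourself", "himself", "herself"}

_PLEONASTIC_VERBS = {"seem", "appear", "mean", "follow"}
_CAUSATIVE_VERBS = {"make", "find", "take"}
_MAX_GAP = 3  # bound on optional adjective/adverb slots in the patterns
_NP_LIKE_POS = {"DT", "PRP$", "JJ", "NN", "NNS", "NNP", "NNPS", "CD", "PRP"}


@dataclass(frozen=True)
class Anaphor:
    markable: Markable
    anaphor_type: str
    semantic_class: str = UNKNOWN

    @property
    def span(self):
        return self.markable.span

    @property
    def sentence_index(self) -> int:
        return self.markable.sentence_index


@dataclass(frozen=True)
class AnaphorSelectionConfig:
    enable_pro_ana_sem_filter: bool = True
    enable_defnp_ana_sem_filter: bool = True
    enable_pleonastic_filter: bool = True


def _skip_for_np(tokens: Sequence[Token], i: int) -> int:
    """If tokens[i] starts an optional 'for NP' group, return the index
    after it; otherwise return i unchanged."""
    if i < len(tokens) and tokens[i].lemma == "for":
        j = i + 1
        steps = 0
        while j < len(tokens) and tokens[j].pos in _NP_LIKE_POS and steps < 4:
            j += 1
            steps += 1
        if steps:
            return j
    return i


def is_pleonastic_it(sentence_tokens: Sequence[Token], it_token: Token) -> bool:
    """Match the four pleonastic-*it* surface patterns.

    1. ``It be [Adj|Adv|verb]* that``
    2. ``It be Adj [for NP] to VP``
    3. ``It [seems|appears|means|follows] [that]``
    4. ``NP [makes|finds|takes] it [Adj]* [for NP]* [to VP | Ving]``

    Matching runs over POS tags and lemmas; starred slots are bounded to a
    few tokens.
    """
    if it_token.lemma != "it":
        raise ValueError(f"{it_token.span.text!r} is not 'it'")
    toks = list(sentence_tokens)
    try:
        idx = next(i for i, t in enumerate(toks) if t.span == it_token.span)
    except StopIteration:
        raise ValueError("it_token not found in sentence_tokens") from None

    after = toks[idx + 1:]

    # Pattern 3: It seems/appears/means/follows [that]
    if after and after[0].lemma in _PLEONASTIC_VERBS:
        return True

    # Patterns 1 and 2: It be ...
    if after and after[0].lemma == "be":
        rest = after[1:]
        # Pattern 1: up to _MAX_GAP Adj/Adv/verb tokens then "that"
        for gap in range(0, _MAX_GAP + 1):
            if gap < len(rest) and rest[gap].lemma == "that":
                if all(r.pos[:2] in ("JJ", "RB", "VB") for r in rest[:gap]):
                    return True
        # Pattern 2: Adj [for NP] to VP
        if rest and rest[0].pos.startswith("JJ"):
            j = 1
            while j < len(rest) and rest[j].pos.startswith("JJ") and j <= _MAX_GAP:
                j += 1
            j = _skip_for_np(rest, j)
            if (j + 1 < len(rest) and rest[j].lemma == "to"
                    and rest[j + 1].pos.startswith("VB")):
                return True

    # Pattern 4: NP makes/finds/takes it [Adj]* [for NP]* [to VP | Ving]
    if idx >= 1 and toks[idx - 1].lemma in _CAUSATIVE_VERBS:
        j = 0
        while j < len(after) and after[j].pos.startswith("JJ") and j < _MAX_GAP:
            j += 1
        j = _skip_for_np(after, j)
        if j < len(after):
            if after[j].pos == "VBG":
                return True
            if (after[j].lemma == "to" and j + 1 < len(after)
                    and after[j + 1].pos.startswith("VB")):
                return True
    return False


def classify_anaphor_type(markable: Markable) -> str:
    """Map a markable's surface form to its anaphor-type label."""
    t = markable.syntactic_type
    if t == PRON_RELAT:
        return RELAT
    if t in (PRON_POSS, PRON_PERS, PRON_DEM, PRON_REFL):
        return t
    if t == PRON_OTHER:
        return OTHER
    if t == DEFNP:
        return DNP
    return OTHER


def _sentence_of(markable: Markable,
                 sentences: Sequence[ParsedSentence]) -> Optional[ParsedSentence]:
    for s in sentences:
        if s.index == markable.sentence_index:
            return s
    return None


def possessive_context_np(markable: Markable,
                          sentences: Sequence[ParsedSentence]):
    """The NP in which a possessive pronoun is the determiner, wrapped with
    its token sequence for keyword matching; None when unattached."""
    sent = _sentence_of(markable, sentences)
    if sent is None:
        return None
    chunk = containing_noun_phrase(markable.head, sent)
    if chunk is None:
        return None
    tokens = tuple(t for t in sent.tokens if chunk.span.contains(t.span))
    return SimpleNamespace(span=chunk.span, tokens=tokens)


def select_anaphors(markables: Sequence[Markable],
                    parsed_sentences: Sequence[ParsedSentence],
                    lexicons: SemanticLexicons = SemanticLexicons(),
                    config: AnaphorSelectionConfig = AnaphorSelectionConfig(),
                    proteins: Sequence[ProteinMention] = ()) -> list[Anaphor]:
    """Select anaphors from the markable set (a subset of it)."""
    anaphors: list[Anaphor] = []
    for m in markables:
        if m.is_pronoun:
            lemma = m.head.lemma
            if lemma in _PERSON_PRONOUNS:
                continue
            atype = classify_anaphor_type(m)
            if atype == RELAT:
                anaphors.append(Anaphor(m, RELAT, UNKNOWN))
                continue
            if lemma == "it" and config.enable_pleonastic_filter:
                sent = _sentence_of(m, parsed_sentences)
                if sent is not None and is_pleonastic_it(sent.tokens, m.head):
                    continue
            if atype == PRON_POSS:
                context = possessive_context_np(m, parsed_sentences)
                sem = pro_ana_sem(m, context, lexicons)
                if config.enable_pro_ana_sem_filter and sem == UNKNOWN:
                    continue
                anaphors.append(Anaphor(m.with_semantic_class(sem), atype, sem))
                continue
            anaphors.append(Anaphor(m, atype, UNKNOWN))
        elif m.syntactic_type == DEFNP:
            if any(m.span.contains(p.span) for p in proteins):
                continue  # direct protein reference, not anaphoric
            sem = defnp_ana_sem(m, lexicons)
            if config.enable_defnp_ana_sem_filter and sem == NON_PROTEIN:
                continue
            anaphors.append(Anaphor(m.with_semantic_class(sem), DNP, sem))
    return anaphors
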
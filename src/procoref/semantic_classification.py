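"""Protein / non-protein semantic classification of expressions.

Three rule sets, each tuned to what evidence is available for the kind of
expression it classifies:

* ANTE-SEM — nominal expressions (antecedent candidates): gold protein
  mentions are given as input to the task, so an NP whose head coincides
  with a mention, or whose head noun is "protein"/"gene" with a mention as
  premodifier ("the Tax protein"), is a protein reference; a coordinated NP
  is a protein reference if one of its constituents is.
* PRO-ANA-SEM — possessive pronoun anaphors: the NP in which *its*/*their*
  is the determiner is scanned for protein key words ("its heterodimeric
  *binding* partner"); a hit classifies the pronoun as a protein reference,
  otherwise its type stays unknown.
* DEFNP-ANA-SEM — definite NP anaphors: classified by a protein head-word
  list ("this transcription *factor*" → protein).

The default lexicons are deliberately small hand-built lists; both are
overridable through configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .markable_detection import (Markable, NON_PROTEIN, PROTEIN, UNKNOWN,
                                 _is_coordinated)
from .standoff_io import ProteinMention
from .syntax_adapter import ParsedSentence, Token, _singularize

__all__ = [
    "SemanticLexicons",
    "DEFAULT_PROTEIN_KEYWORDS",
    "DEFAULT_PROTEIN_HEADWORDS",
    "DEFAULT_PRONOUN_FAMILIES",
    "ante_sem",
    "pro_ana_sem",
    "defnp_ana_sem",
    "containing_noun_phrase",
]

# The 12-word protein key word list used by PRO-ANA-SEM.
DEFAULT_PROTEIN_KEYWORDS = frozenset({
    "binding", "expression", "interaction", "regulation",
    "phosphatase activity", "localization", "gene", "sequence", "region",
    "phosphorylation", "transactivation", "transcription",
})

# The protein head-word list used by DEFNP-ANA-SEM (eight words).
DEFAULT_PROTEIN_HEADWORDS = frozenset({
    "protein", "gene", "factor", "molecule", "element", "family",
    "inhibitor", "receptor",
})

DEFAULT_PRONOUN_FAMILIES: dict[str, frozenset[str]] = {
    "it": frozenset({"it", "its", "itself"}),
    "they": frozenset({"they", "their", "them", "themselves"}),
    "this": frozenset({"this", "that", "these", "those"}),
}

_POSSESSIVES = {"its", "their"}


@dataclass(frozen=True)
class SemanticLexicons:
    protein_keywords: frozenset[str] = DEFAULT_PROTEIN_KEYWORDS
    protein_headwords: frozenset[str] = DEFAULT_PROTEIN_HEADWORDS
    pronoun_families: Mapping[str, frozenset[str]] = field(
        default_factory=lambda: dict(DEFAULT_PRONOUN_FAMILIES))

    @classmethod
    def from_dict(cls, data: Mapping) -> "SemanticLexicons":
        kwargs = {}
        if "protein_keywords" in data:
            kwargs["protein_keywords"] = frozenset(
                k.lower() for k in data["protein_keywords"])
        if "protein_headwords" in data:
            kwargs["protein_headwords"] = frozenset(
                k.lower() for k in data["protein_headwords"])
        if "pronoun_families" in data:
            kwargs["pronoun_families"] = {
                name: frozenset(w.lower() for w in members)
                for name, members in data["pronoun_families"].items()}
        return cls(**kwargs)

    def family_of(self, pronoun_lemma: str) -> Optional[str]:
        for name, members in self.pronoun_families.items():
            if pronoun_lemma in members:
                return name
        return None


def ante_sem(markable: Markable,
             proteins: Sequence[ProteinMention],
             sentence: ParsedSentence | None = None) -> str:
    """Classify a nominal expression as PROTEIN or NON_PROTEIN.

    Fires PROTEIN when (a) the head word exactly coincides with a protein
    mention, (b) the head noun is "protein" or "gene" with a protein
    mention premodifier inside the NP, or (c) the NP is coordinated and one
    of its constituent nouns coincides with a protein mention.
    """
    if markable.is_pronoun:
        raise ValueError("ante_sem applies to nominal markables, not pronouns")
    contained = [p for p in proteins if markable.span.contains(p.span)]
    # (a) head word == protein mention
    for p in contained:
        if p.span == markable.head.span:
            return PROTEIN
    # (b) head noun "protein"/"gene" with a protein-mention premodifier
    if markable.head.lemma in ("protein", "gene"):
        for p in contained:
            if p.span.end <= markable.head.span.start:
                return PROTEIN
    # (c) coordinated NP with a protein constituent
    if _is_coordinated(markable.tokens):
        token_spans = {t.span for t in markable.tokens}
        if any(p.span in token_spans for p in contained):
            return PROTEIN
        if sentence is not None:
            for chunk in sentence.chunks:
                if (markable.span.contains(chunk.span)
                        and chunk.span != markable.span
                        and any(p.span == chunk.head.span for p in contained)):
                    return PROTEIN
    return NON_PROTEIN


def containing_noun_phrase(pronoun_token: Token,
                           sentence: ParsedSentence):
    """Smallest NP chunk in which the pronoun acts as determiner.

    Returns ``None`` when the pronoun heads no larger NP (e.g. it is not
    possessive, or the parser attached it nowhere).
    """
    candidates = [c for c in sentence.chunks
                  if c.is_noun_phrase
                  and c.span.contains(pronoun_token.span)
                  and c.span.length > pronoun_token.span.length]
    if not candidates:
        return None
    return min(candidates, key=lambda c: c.span.length)


def _np_matches_keyword(tokens: Sequence[Token], keywords) -> bool:
    lemmas = [t.lemma.lower() for t in tokens]
    surfaces = [t.span.text.lower() for t in tokens]
    for key in keywords:
        key_parts = key.lower().split()
        n = len(key_parts)
        for i in range(len(tokens) - n + 1):
            if lemmas[i:i + n] == key_parts or surfaces[i:i + n] == key_parts:
                return True
    return False


def pro_ana_sem(pronoun_markable: Markable,
                containing_np,
                lexicons: SemanticLexicons = SemanticLexicons()) -> str:
    """Classify a possessive pronoun by its context NP.

    PROTEIN iff the NP in which the pronoun is the determiner contains at
    least one protein key word (case-insensitive lemma match; multiword
    keys matched as token sequences).  Non-possessive pronouns, or
    possessives with no context NP, stay UNKNOWN.
    """
    if pronoun_markable.head.lemma not in _POSSESSIVES:
        return UNKNOWN
    if containing_np is None:
        return UNKNOWN
    tokens = getattr(containing_np, "tokens", None)
    if tokens is None:  # a Chunk: no token list of its own, caller supplies one
        raise TypeError("containing_np must carry a token sequence "
                        "(a Markable or an object with .tokens)")
    if _np_matches_keyword(tokens, lexicons.protein_keywords):
        return PROTEIN
    return UNKNOWN


def defnp_ana_sem(definite_np_markable: Markable,
                  lexicons: SemanticLexicons = SemanticLexicons()) -> str:
    """Classify a definite NP anaphor by its head word.

    PROTEIN iff the singular-normalized head word is in the protein
    head-word list ("these genes" → "gene" → PROTEIN).
    """
    head = _singularize(definite_np_markable.head.lemma.lower())
    if head in lexicons.protein_headwords:
        return PROTEIN
    return NON_PROTEIN
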
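"""Antecedent prediction.

Relative pronouns are resolved by the parser's attachment of the relative
clause (a fixed rule).  Every other anaphor is resolved by a pairwise
decision list applied over its candidate set:

1. NUM-AGREE  — the candidate that does not conflict in grammatical number
   with the anaphor is preferred (``unknown`` never conflicts);
2. SEM-CONS   — if the anaphor is a protein reference, a protein candidate
   is preferred;
3. DISC-PREF  — for anaphor types with far discourse preference, the
   farther candidate is preferred;
4. DEFAULT    — the closer candidate is preferred.

A rule decides only when exactly one of the two candidates satisfies its
condition; otherwise the next rule applies.  The default rule never ties,
so the tournament (nearest candidate as incumbent, challenged by each
farther candidate in turn) always yields a single antecedent.

Rule toggles reproduce the ablation presets ``rb-min`` (decision list
reduced to the default rule) through ``rb-full`` (all three rules on).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

from .anaphor_selection import (Anaphor, AnaphorSelectionConfig, DNP, RELAT,
                                select_anaphors)
from .antecedent_candidates import (CandidateConfig, CandidateSet,
                                    collect_candidates)
from .markable_detection import (Markable, PLURAL, PROTEIN, PRON_DEM,
                                 PRON_PERS, SINGULAR, detect_markables)
from .semantic_classification import SemanticLexicons, ante_sem
from .standoff_io import CoreferenceLink, Document
from .syntax_adapter import ParsedSentence, relative_argument

__all__ = [
    "RuleConfig",
    "Preference",
    "PredictionTrace",
    "PRESETS",
    "NEAR", "FAR",
    "resolve_relative",
    "prefer",
    "predict_antecedent",
    "resolve_document",
    "classify_markables",
]

logger = logging.getLogger(__name__)

NEAR = "near"
FAR = "far"

RULE_NUM_AGREE = "NUM-AGREE"
RULE_SEM_CONS = "SEM-CONS"
RULE_DISC_PREF = "DISC-PREF"
RULE_DEFAULT = "DEFAULT"

# Anaphor types given far discourse preference by default: discourse-old
# pronoun references (personal and demonstrative pronouns) tend to point
# past the nearest NP; everything else prefers the closer candidate.
DEFAULT_DISC_PREF_MAP: Mapping[str, str] = {
    PRON_PERS: FAR,
    PRON_DEM: FAR,
}


@dataclass(frozen=True)
class RuleConfig:
    enable_rule1_num_agree: bool = True
    enable_rule2_sem_cons: bool = True
    enable_rule3_disc_pref: bool = True
    disc_pref_map: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_DISC_PREF_MAP))
    window_size: int = 2

    @classmethod
    def preset(cls, name: str) -> "RuleConfig":
        try:
            return PRESETS[name.lower()]
        except KeyError:
            raise KeyError(
                f"unknown preset {name!r}; available: {sorted(PRESETS)}"
            ) from None


PRESETS: dict[str, RuleConfig] = {
    "rb-min": RuleConfig(False, False, False),
    "rb-min+1": RuleConfig(True, False, False),
    "rb-min+2": RuleConfig(False, True, False),
    "rb-min+3": RuleConfig(False, False, True),
    "rb-min+1,3": RuleConfig(True, False, True),
    "rb-full": RuleConfig(True, True, True),
}


@dataclass(frozen=True)
class Preference:
    winner: Markable
    deciding_rule: str


@dataclass
class PredictionTrace:
    anaphor: Anaphor
    candidates: tuple[Markable, ...]
    antecedent: Optional[Markable]
    decisions: list[tuple[Markable, Markable, Preference]] = field(
        default_factory=list)
    fixed_rule: bool = False


def _number_compatible(candidate: Markable, anaphor: Anaphor) -> bool:
    a, c = anaphor.markable.number, candidate.number
    known = {SINGULAR, PLURAL}
    return not (a in known and c in known and a != c)


def _is_farther(candidate: Markable, other: Markable) -> bool:
    return (candidate.span.end, candidate.span.start) < \
        (other.span.end, other.span.start)


def prefer(candidate_a: Markable, candidate_b: Markable,
           anaphor: Anaphor, config: RuleConfig = RuleConfig()) -> Preference:
    """Compare two candidates under the decision list; never ties."""
    if candidate_a.span == candidate_b.span:
        raise ValueError("prefer() requires two distinct candidates")

    if config.enable_rule1_num_agree:
        sat_a = _number_compatible(candidate_a, anaphor)
        sat_b = _number_compatible(candidate_b, anaphor)
        if sat_a != sat_b:
            return Preference(candidate_a if sat_a else candidate_b,
                              RULE_NUM_AGREE)

    if config.enable_rule2_sem_cons and anaphor.semantic_class == PROTEIN:
        sat_a = candidate_a.semantic_class == PROTEIN
        sat_b = candidate_b.semantic_class == PROTEIN
        if sat_a != sat_b:
            return Preference(candidate_a if sat_a else candidate_b,
                              RULE_SEM_CONS)

    if config.enable_rule3_disc_pref and \
            config.disc_pref_map.get(anaphor.anaphor_type, NEAR) == FAR:
        if _is_farther(candidate_a, candidate_b):
            return Preference(candidate_a, RULE_DISC_PREF)
        return Preference(candidate_b, RULE_DISC_PREF)

    # Default: the closer candidate is preferred.
    if _is_farther(candidate_a, candidate_b):
        return Preference(candidate_b, RULE_DEFAULT)
    return Preference(candidate_a, RULE_DEFAULT)


def predict_antecedent(anaphor: Anaphor, candidate_set: CandidateSet,
                       config: RuleConfig = RuleConfig(),
                       trace: Optional[PredictionTrace] = None
                       ) -> Optional[Markable]:
    """Tournament over the nearest-first candidate list; None iff empty."""
    candidates = candidate_set.candidates
    if not candidates:
        return None
    incumbent = candidates[0]
    for challenger in candidates[1:]:
        pref = prefer(incumbent, challenger, anaphor, config)
        if trace is not None:
            trace.decisions.append((incumbent, challenger, pref))
        incumbent = pref.winner
    return incumbent


def resolve_relative(anaphor: Anaphor, parsed_sentence: ParsedSentence
                     ) -> Optional[CoreferenceLink]:
    """Fixed rule: link a relative pronoun to its parser-attached argument."""
    if anaphor.anaphor_type != RELAT:
        raise ValueError("resolve_relative applies to RELAT anaphors only")
    chunk = relative_argument(parsed_sentence.edges, anaphor.markable.head)
    if chunk is None or chunk.span.start >= anaphor.span.start:
        return None
    return CoreferenceLink(anaphor.span, chunk.span)


def classify_markables(markables: Sequence[Markable],
                       document: Document,
                       sentences: Sequence[ParsedSentence]) -> list[Markable]:
    """Fill semantic classes of nominal markables with ANTE-SEM."""
    by_index = {s.index: s for s in sentences}
    out = []
    for m in markables:
        if m.is_pronoun:
            out.append(m)
        else:
            sem = ante_sem(m, document.proteins, by_index.get(m.sentence_index))
            out.append(m.with_semantic_class(sem))
    return out


def resolve_document(document: Document,
                     parsed_sentences: Sequence[ParsedSentence],
                     config: RuleConfig = RuleConfig(),
                     lexicons: SemanticLexicons = SemanticLexicons(),
                     selection_config: AnaphorSelectionConfig = AnaphorSelectionConfig(),
                     candidate_config: CandidateConfig | None = None,
                     traces: Optional[list[PredictionTrace]] = None
                     ) -> list[CoreferenceLink]:
    """Run the whole pipeline on one parsed document.

    Returns at most one link per anaphor.  Unparsed sentences contribute no
    markables and are skipped with a warning.
    """
    for s in parsed_sentences:
        if not s.parsed:
            logger.warning("%s: sentence %d unparsed; skipped",
                           document.doc_id, s.index)

    markables = classify_markables(detect_markables(parsed_sentences),
                                   document, parsed_sentences)
    anaphors = select_anaphors(markables, parsed_sentences, lexicons,
                               selection_config, document.proteins)

    # Pronouns never survive as candidates: they are either anaphors
    # themselves or were filtered as non-referential / non-protein.
    excluded = frozenset(m.span for m in markables if m.is_pronoun)
    if candidate_config is None:
        candidate_config = CandidateConfig(lexicons=lexicons)
    candidate_config = replace(candidate_config,
                               excluded_pronoun_spans=excluded)

    by_index = {s.index: s for s in parsed_sentences}
    links: list[CoreferenceLink] = []
    for anaphor in anaphors:
        if anaphor.anaphor_type == RELAT:
            sent = by_index.get(anaphor.sentence_index)
            link = resolve_relative(anaphor, sent) if sent else None
            if traces is not None:
                ante = None
                if link is not None:
                    ante = next((m for m in markables
                                 if m.span == link.antecedent), None)
                traces.append(PredictionTrace(anaphor, (), ante, fixed_rule=True))
            if link is not None:
                links.append(link)
            continue
        cset = collect_candidates(anaphor, markables, parsed_sentences,
                                  config.window_size, candidate_config)
        trace = PredictionTrace(anaphor, cset.candidates, None) \
            if traces is not None else None
        antecedent = predict_antecedent(anaphor, cset, config, trace)
        if trace is not None:
            trace.antecedent = antecedent
            traces.append(trace)
        if antecedent is not None:
            links.append(CoreferenceLink(anaphor.span, antecedent.span))
    return links
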
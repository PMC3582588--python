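"""Antecedent candidate selection.

For each anaphor, the candidates are the markables that precede it within a
sentence window (default 2: the anaphor's sentence plus the two before it),
minus

* pronouns that were themselves selected as anaphors, or filtered out at
  anaphor selection (a pleonastic *it* refers to nothing);
* pronouns from a different pronoun family than the anaphor (*this* is no
  candidate for *its*);
* markables ruled out by dependency relations whose arguments cannot
  corefer — the arguments of ``prep-arg12``/``poss-arg12`` (e.g. *two such
  truncated forms* can never be the antecedent of *the protein* in "two
  such truncated forms of the protein").

Candidates are ordered nearest-first (by end offset, descending), the
order in which the decision-list tournament consumes them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet, Iterable, Sequence

from .anaphor_selection import Anaphor
from .markable_detection import Markable, PROTEIN
from .semantic_classification import SemanticLexicons
from .standoff_io import TextSpan
from .syntax_adapter import DependencyEdge, ParsedSentence

__all__ = [
    "CandidateSet",
    "CandidateConfig",
    "DEFAULT_FILTERED_DEPENDENCY_LABELS",
    "collect_candidates",
    "dependency_filter",
    "pronoun_family_filter",
]

DEFAULT_FILTERED_DEPENDENCY_LABELS = frozenset({"poss-arg12", "prep-arg12"})


@dataclass(frozen=True)
class CandidateConfig:
    filtered_dependency_labels: FrozenSet[str] = DEFAULT_FILTERED_DEPENDENCY_LABELS
    lexicons: SemanticLexicons = field(default_factory=SemanticLexicons)
    hard_semantic_candidate_filter: bool = False
    excluded_pronoun_spans: FrozenSet[TextSpan] = frozenset()


@dataclass(frozen=True)
class CandidateSet:
    anaphor: Anaphor
    candidates: tuple[Markable, ...]  # nearest first

    def __len__(self) -> int:
        return len(self.candidates)


def dependency_filter(anaphor: Anaphor, candidate: Markable,
                      edges: Iterable[DependencyEdge],
                      filtered_labels=DEFAULT_FILTERED_DEPENDENCY_LABELS) -> bool:
    """True to keep the candidate, False to drop it.

    Dropped when the anaphor and the candidate sit on the two sides of a
    filtered dependency relation: the anaphor inside one argument while the
    candidate equals (or contains) the other argument.
    """
    a_span = anaphor.span
    for edge in edges:
        if edge.label not in filtered_labels:
            continue
        s1, s2 = edge.arg1.span, edge.arg2.span
        for inside, other in ((s1, s2), (s2, s1)):
            if inside.contains(a_span) and (
                    candidate.span == other or candidate.span.contains(other)):
                return False
    return True


def pronoun_family_filter(anaphor: Anaphor, candidate: Markable,
                          lexicons: SemanticLexicons = SemanticLexicons()
                          ) -> bool:
    """True to keep.  A pronoun candidate must share the anaphor pronoun's
    family (*its* ↔ {it, its, itself}); non-pronoun candidates, or anaphors
    whose family is unlisted, are untouched."""
    if not candidate.is_pronoun or not anaphor.markable.is_pronoun:
        return True
    fam_a = lexicons.family_of(anaphor.markable.head.lemma)
    if fam_a is None:
        return True
    fam_c = lexicons.family_of(candidate.head.lemma)
    return fam_c == fam_a


def collect_candidates(anaphor: Anaphor,
                       markables: Sequence[Markable],
                       parsed_sentences: Sequence[ParsedSentence],
                       window: int = 2,
                       config: CandidateConfig = CandidateConfig()
                       ) -> CandidateSet:
    """Collect and filter the antecedent candidates of one anaphor."""
    if window < 0:
        raise ValueError("window must be >= 0")
    sent_edges: tuple[DependencyEdge, ...] = ()
    for s in parsed_sentences:
        if s.index == anaphor.sentence_index:
            sent_edges = s.edges
            break

    kept: list[Markable] = []
    for m in markables:
        if m.span == anaphor.span:
            continue
        if not (m.span.end < anaphor.span.start):
            continue  # must fully precede the anaphor (no cataphora)
        if not (0 <= anaphor.sentence_index - m.sentence_index <= window):
            continue
        if m.is_pronoun:
            if m.span in config.excluded_pronoun_spans:
                continue
            if not pronoun_family_filter(anaphor, m, config.lexicons):
                continue
        if not dependency_filter(anaphor, m, sent_edges,
                                 config.filtered_dependency_labels):
            continue
        if (config.hard_semantic_candidate_filter
                and anaphor.semantic_class == PROTEIN
                and m.semantic_class != PROTEIN):
            continue
        kept.append(m)

    kept.sort(key=lambda m: (-m.span.end, -m.span.start))
    return CandidateSet(anaphor, tuple(kept))
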
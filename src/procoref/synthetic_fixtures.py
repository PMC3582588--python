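"""Synthetic annotated corpora and packaged worked examples.

Two sources of test data, both self-contained:

* :func:`packaged_examples` — the worked example documents from the
  biomedical abstracts the rules were developed against (identified by
  PMID), with hand-encoded gold parses, protein mentions, gold links and
  per-configuration expected antecedents.
* :func:`generate_corpus` — a template-based generator that emulates the
  statistical regularities the rules exploit: the anaphor-type mix of the
  training data, an antecedent-distance distribution placing ≥97% of links
  within two sentences, protein key-word cues in possessive NPs, and
  planted distractors (a nearer non-protein or number-conflicting NP) so
  the benefit of each decision-list rule is measurable.  Sentences are
  schematic English; every template carries its own tokens, chunks, heads
  and edges, so emitted gold parses are correct by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .standoff_io import (CoreferenceLink, Document, ProteinMention, TextSpan)
from .syntax_adapter import (Chunk, DependencyEdge, ParsedSentence, Token,
                             lemma_of)

__all__ = [
    "GeneratorConfig",
    "PackagedExample",
    "generate_corpus",
    "packaged_examples",
    "SentenceSpec",
    "DocumentBuilder",
]

_NO_SPACE_BEFORE = {",", ".", ";", ":", ")", "?", "!"}
_NO_SPACE_AFTER = {"("}


# ---------------------------------------------------------------------------
# Sentence / document builders (shared by fixtures and the generator)

@dataclass
class SentenceSpec:
    """One sentence as ``"word|POS"`` tokens plus chunk and edge specs.

    Chunks are ``(first_token, end_token_exclusive, head_token)`` or the
    same plus a flags dict (``{"subclause": True}``); edges are
    ``(label, arg, arg)`` with args ``("chunk", i)`` or ``("token", i)``.
    """

    tokens: list[str]
    chunks: list[tuple] = field(default_factory=list)
    edges: list[tuple] = field(default_factory=list)

    @classmethod
    def parse(cls, spec: str, chunks=(), edges=()) -> "SentenceSpec":
        return cls(spec.split(), list(chunks), list(edges))


def _detokenize(words: Sequence[str], offset: int
                ) -> tuple[str, list[tuple[int, int]]]:
    text = ""
    spans = []
    for w in words:
        if text and w not in _NO_SPACE_BEFORE and text[-1] not in _NO_SPACE_AFTER:
            text += " "
        spans.append((offset + len(text), offset + len(text) + len(w)))
        text += w
    return text, spans


def realize_sentence(spec: SentenceSpec, index: int, offset: int
                     ) -> ParsedSentence:
    words, poss = [], []
    for item in spec.tokens:
        word, pos = item.rsplit("|", 1)
        words.append(word)
        poss.append(pos)
    text, spans = _detokenize(words, offset)
    tokens = tuple(
        Token(TextSpan(s, e, w), pos, lemma_of(w, pos))
        for (s, e), w, pos in zip(spans, words, poss))

    sent_span = TextSpan(offset, offset + len(text), text)

    chunks = []
    for cspec in spec.chunks:
        i, j, head = cspec[:3]
        flags = cspec[3] if len(cspec) > 3 else {}
        span = TextSpan(tokens[i].span.start, tokens[j - 1].span.end,
                        text[tokens[i].span.start - offset:
                             tokens[j - 1].span.end - offset])
        chunks.append(Chunk(span, tokens[head],
                            flags.get("np", True), flags.get("subclause", False)))
    chunks = tuple(chunks)

    def resolve(arg):
        kind, idx = arg
        return chunks[idx] if kind == "chunk" else tokens[idx]

    edges = tuple(DependencyEdge(label, resolve(a1), resolve(a2))
                  for label, a1, a2 in spec.edges)
    return ParsedSentence(index, sent_span, tokens, chunks, edges)


class DocumentBuilder:
    """Assemble a document (text + parses + proteins + gold links) from
    sentence specs.  References into sentences use
    ``("token", sent, tok)``, ``("chunk", sent, chunk)`` or
    ``("span", sent, first_tok, end_tok_exclusive)``."""

    def __init__(self, doc_id: str):
        self.doc_id = doc_id
        self.sentences: list[ParsedSentence] = []
        self._protein_refs: list[tuple] = []
        self._link_refs: list[tuple] = []

    def add_sentence(self, spec: SentenceSpec) -> int:
        offset = 0
        if self.sentences:
            offset = self.sentences[-1].span.end + 1  # single joining space
        self.sentences.append(realize_sentence(spec, len(self.sentences), offset))
        return len(self.sentences) - 1

    def mark_protein(self, sent: int, token: int,
                     sub: Optional[tuple[int, int]] = None) -> None:
        self._protein_refs.append((sent, token, sub))

    def add_gold_link(self, anaphor_ref: tuple, antecedent_ref: tuple) -> None:
        self._link_refs.append((anaphor_ref, antecedent_ref))

    def span_of(self, ref: tuple) -> TextSpan:
        kind = ref[0]
        sent = self.sentences[ref[1]]
        if kind == "token":
            return sent.tokens[ref[2]].span
        if kind == "chunk":
            return sent.chunks[ref[2]].span
        if kind == "span":
            start = sent.tokens[ref[2]].span.start
            end = sent.tokens[ref[3] - 1].span.end
            text = self.text[start:end]
            return TextSpan(start, end, text)
        raise KeyError(kind)

    @property
    def text(self) -> str:
        parts = []
        pos = 0
        for s in self.sentences:
            parts.append(" " * (s.span.start - pos))
            parts.append(s.span.text)
            pos = s.span.end
        return "".join(parts)

    def build(self) -> tuple[Document, list[ParsedSentence]]:
        text = self.text
        proteins = []
        for n, (sent_i, tok_i, sub) in enumerate(self._protein_refs, start=1):
            span = self.sentences[sent_i].tokens[tok_i].span
            if sub is not None:
                start = span.start + sub[0]
                end = start + sub[1]
                span = TextSpan(start, end, text[start:end])
            proteins.append(ProteinMention(f"T{n}", span))
        links = [CoreferenceLink(self.span_of(a), self.span_of(b))
                 for a, b in self._link_refs]
        doc = Document(self.doc_id, text, proteins, links)
        return doc, self.sentences


# ---------------------------------------------------------------------------
# Packaged worked examples

@dataclass
class PackagedExample:
    name: str
    document: Document
    parses: list[ParsedSentence]
    # preset name -> {anaphor surface: expected antecedent surface or None}
    expected: Mapping[str, Mapping[str, Optional[str]]] = field(
        default_factory=dict)
    flags: frozenset[str] = frozenset()


def _table2_workflow_example() -> PackagedExample:
    b = DocumentBuilder("PMID-7964516")
    s1 = SentenceSpec.parse(
        "T|NN cell|NN hybridomas|NNS respond|VBP to|TO activation|NN "
        "signals|NNS by|IN undergoing|VBG apoptotic|JJ cell|NN death|NN ,|, "
        "and|CC this|DT is|VBZ likely|JJ to|TO represent|VB comparable|JJ "
        "events|NNS related|VBN to|TO tolerance|NN induction|NN in|IN "
        "immature|JJ and|CC mature|JJ T|NN cells|NNS in|IN vivo|NN .|.",
        chunks=[(0, 3, 2), (5, 7, 6), (9, 12, 11), (19, 25, 20),
                (26, 33, 30), (31, 33, 32)])
    s2 = SentenceSpec.parse(
        "Previous|JJ studies|NNS using|VBG antisense|JJ oligonucleotides|NNS "
        "implicated|VBD the|DT c-Myc|NN protein|NN in|IN the|DT "
        "phenomenon|NN of|IN activation-induced|JJ apoptosis|NN .|.",
        chunks=[(0, 5, 1), (3, 5, 4), (6, 9, 8), (10, 12, 11),
                (10, 15, 11), (13, 15, 14)],
        edges=[("prep-arg12", ("chunk", 3), ("chunk", 5))])
    s3 = SentenceSpec.parse(
        "This|DT role|NN for|IN c-Myc|NN in|IN apoptosis|NN is|VBZ now|RB "
        "confirmed|VBN in|IN studies|NNS using|VBG a|DT dominant|JJ "
        "negative|JJ form|NN of|IN its|PRP$ heterodimeric|JJ binding|NN "
        "partner|NN ,|, Max|NN ,|, which|WDT we|PRP show|VBP here|RB "
        "inhibits|VBZ activation-induced|JJ apoptosis|NN .|.",
        chunks=[(1, 2, 1), (1, 6, 1), (0, 6, 1), (3, 4, 3), (5, 6, 5),
                (10, 11, 10), (10, 31, 10, {"subclause": True}),
                (12, 16, 15), (12, 23, 15), (17, 21, 20), (22, 23, 22),
                (29, 31, 30)],
        edges=[("prep-arg12", ("chunk", 7), ("chunk", 9)),
               ("relative-arg", ("chunk", 10), ("token", 24)),
               ("poss-arg12", ("token", 17), ("chunk", 9))])
    b.add_sentence(s1)
    b.add_sentence(s2)
    b.add_sentence(s3)
    b.mark_protein(1, 7)   # c-Myc in S2
    b.mark_protein(2, 3)   # c-Myc in S3
    b.mark_protein(2, 22)  # Max
    b.add_gold_link(("token", 2, 17), ("chunk", 2, 3))   # its -> c-Myc
    b.add_gold_link(("token", 2, 24), ("chunk", 2, 10))  # which -> Max
    doc, parses = b.build()
    return PackagedExample(
        "PMID-7964516", doc, parses,
        expected={
            "rb-full": {"its": "c-Myc", "which": "Max"},
            "rb-min+1,3": {"its": "apoptosis", "which": "Max"},
            "rb-min": {"its": "studies", "which": "Max"},
        },
        flags=frozenset({"workflow-example"}))


def _irf1_example() -> PackagedExample:
    b = DocumentBuilder("PMID-10358173")
    s = SentenceSpec.parse(
        "Therefore|RB ,|, IRF-1|NN may|MD be|VB an|DT important|JJ "
        "contributor|NN to|TO IL-12|NN signaling|NN ,|, and|CC we|PRP "
        "speculate|VBP that|IN the|DT defective|JJ IL-12|NN responses|NNS "
        "seen|VBN in|IN IRF-1-/-|NN mice|NNS might|MD be|VB attributable|JJ "
        ",|, in|IN part|NN ,|, to|TO the|DT absence|NN of|IN this|DT "
        "transcription|NN factor|NN .|.",
        chunks=[(2, 3, 2), (5, 8, 7), (9, 11, 10), (16, 20, 19),
                (22, 24, 23), (29, 30, 29), (32, 34, 33), (32, 38, 33),
                (35, 38, 37)],
        edges=[("prep-arg12", ("chunk", 6), ("chunk", 8))])
    b.add_sentence(s)
    b.mark_protein(0, 2)    # IRF-1
    b.mark_protein(0, 9)    # IL-12
    b.mark_protein(0, 18)   # IL-12 (in "the defective IL-12 responses")
    b.add_gold_link(("chunk", 0, 8), ("chunk", 0, 0))
    doc, parses = b.build()
    return PackagedExample(
        "PMID-10358173", doc, parses,
        expected={
            "rb-full": {"this transcription factor": "IRF-1"},
            "rb-min+1,3": {"this transcription factor": "part"},
        })


def _ciita_example() -> PackagedExample:
    b = DocumentBuilder("PMID-10221658")
    s = SentenceSpec.parse(
        "This|DT ability|NN of|IN CIITA|NN to|TO facilitate|VB promoter|NN "
        "occupation|NN is|VBZ undissociable|JJ from|IN its|PRP$ "
        "transactivation|NN potential|NN .|.",
        chunks=[(0, 2, 1), (0, 8, 1), (3, 4, 3), (6, 8, 7), (11, 14, 13)],
        edges=[("prep-arg12", ("chunk", 0), ("chunk", 2)),
               ("poss-arg12", ("token", 11), ("chunk", 4))])
    b.add_sentence(s)
    b.mark_protein(0, 3)  # CIITA
    b.add_gold_link(("token", 0, 11), ("chunk", 0, 2))
    doc, parses = b.build()
    return PackagedExample(
        "PMID-10221658", doc, parses,
        expected={"rb-full": {"its": "CIITA"}})


def _bcl6_example() -> PackagedExample:
    b = DocumentBuilder("PMID-8692924")
    s = SentenceSpec.parse(
        "In|IN transient|JJ transfection|NN experiments|NNS ,|, BCL6|NN "
        "can|MD repress|VB transcription|NN from|IN promoters|NNS "
        "linked|VBN to|TO its|PRP$ DNA|NN target|NN sequence|NN and|CC "
        "this|DT activity|NN is|VBZ regulated|VBN .|.",
        chunks=[(1, 4, 3), (5, 6, 5), (8, 9, 8), (10, 11, 10),
                (13, 17, 16), (18, 20, 19)],
        edges=[("poss-arg12", ("token", 13), ("chunk", 4))])
    b.add_sentence(s)
    b.mark_protein(0, 5)  # BCL6
    b.add_gold_link(("token", 0, 13), ("chunk", 0, 1))
    doc, parses = b.build()
    return PackagedExample(
        "PMID-8692924", doc, parses,
        expected={"rb-full": {"its": "BCL6"}})


def _tat_example() -> PackagedExample:
    b = DocumentBuilder("PMID-9261367")
    s = SentenceSpec.parse(
        "Human|JJ immunodeficiency|NN virus|NN type|NN 1|CD (|( HIV-1|NN )|) "
        "Tat|NN ,|, an|DT early|JJ regulatory|JJ protein|NN that|WDT is|VBZ "
        "critical|JJ for|IN viral|JJ gene|NN expression|NN and|CC "
        "replication|NN ,|, transactivates|VBZ the|DT HIV-1|NN long|JJ "
        "terminal|JJ repeat|NN (|( LTR|NN )|) via|IN its|PRP$ binding|NN "
        "to|TO the|DT transactivation|NN response|NN element|NN (|( TAR|NN "
        ")|) .|.",
        chunks=[(0, 9, 8), (10, 14, 13),
                (10, 23, 13, {"subclause": True}),
                (18, 23, 20), (25, 33, 29), (34, 36, 35), (37, 44, 40)],
        edges=[("relative-arg", ("chunk", 1), ("token", 14)),
               ("poss-arg12", ("token", 34), ("chunk", 5))])
    b.add_sentence(s)
    b.mark_protein(0, 8)  # Tat
    b.add_gold_link(("token", 0, 34), ("chunk", 0, 0))
    doc, parses = b.build()
    return PackagedExample(
        "PMID-9261367", doc, parses,
        expected={"rb-full": {
            "its": "Human immunodeficiency virus type 1 (HIV-1) Tat"}})


def _otf1_example() -> PackagedExample:
    b = DocumentBuilder("PMID-1560002")
    s = SentenceSpec.parse(
        "In|IN contrast|NN ,|, OTF-1-enriched|JJ protein|NN fractions|NNS "
        "did|VBD not|RB affect|VB DRA|NN gene|NN transcription|NN "
        "although|IN it|PRP functionally|RB enhanced|VBD the|DT "
        "transcription|NN of|IN another|DT promoter|NN .|.",
        chunks=[(1, 2, 1), (3, 6, 5), (9, 12, 11), (16, 18, 17),
                (16, 21, 17), (19, 21, 20)],
        edges=[("prep-arg12", ("chunk", 3), ("chunk", 5))])
    b.add_sentence(s)
    b.mark_protein(0, 3, sub=(0, 5))  # "OTF-1" inside "OTF-1-enriched"
    b.add_gold_link(("token", 0, 13), ("chunk", 0, 1))
    doc, parses = b.build()
    return PackagedExample(
        "PMID-1560002", doc, parses,
        expected={},
        flags=frozenset({"number-agreement-violation", "anaphoric-it"}))


def _ebf_example() -> PackagedExample:
    b = DocumentBuilder("PMID-9252117")
    s = SentenceSpec.parse(
        "With|IN the|DT aim|NN of|IN identifying|VBG genetic|JJ targets|NNS "
        "for|IN these|DT transcription|NN factors|NNS ,|, we|PRP stably|RB "
        "transfected|VBD cDNAs|NNS encoding|VBG EBF|NN or|CC a|DT "
        "covalent|JJ homodimer|NN of|IN E47|NN ,|, individually|RB or|CC "
        "together|RB ,|, into|IN immature|JJ hematopoietic|JJ Ba/F3|NN "
        "cells|NNS ,|, which|WDT lack|VBP both|DT factors|NNS .|.",
        chunks=[(1, 3, 2), (5, 7, 6), (8, 11, 10), (15, 24, 15),
                (17, 18, 17), (19, 22, 21), (23, 24, 23), (30, 34, 33),
                (37, 39, 38)],
        edges=[("relative-arg", ("chunk", 7), ("token", 35)),
               ("prep-arg12", ("chunk", 5), ("chunk", 6))])
    b.add_sentence(s)
    b.mark_protein(0, 17)  # EBF
    b.mark_protein(0, 23)  # E47
    b.add_gold_link(("chunk", 0, 8), ("chunk", 0, 3))   # both factors -> cDNAs ...
    b.add_gold_link(("token", 0, 35), ("chunk", 0, 7))  # which -> ... cells
    doc, parses = b.build()
    return PackagedExample(
        "PMID-9252117", doc, parses,
        expected={"rb-full": {
            "both factors": "cDNAs encoding EBF or a covalent homodimer of E47"}},
        flags=frozenset({"premodifier-antecedent-proteins"}))


def _myeloid_example() -> PackagedExample:
    b = DocumentBuilder("PMID-9291089")
    s1 = SentenceSpec.parse(
        "In|IN granulocytic|JJ and|CC monocytic|JJ lineages|NNS ,|, "
        "transcription|NN factors|NNS from|IN several|JJ families|NNS "
        "are|VBP active|JJ ,|, including|VBG AML1/CBF|NN beta|NN ,|, "
        "C/EBP|NN ,|, Ets|NN ,|, c-Myb|NN ,|, HOX|NN ,|, and|CC MZF-1|NN "
        ".|.",
        # the coordinated NP over the protein list is deliberately absent:
        # this fixture reproduces a parse failure on coordination
        chunks=[(1, 5, 4), (6, 11, 7), (15, 17, 16), (18, 19, 18),
                (20, 21, 20), (22, 23, 22), (24, 25, 24), (27, 28, 27)])
    s2 = SentenceSpec.parse(
        "Few|NN of|IN these|DT factors|NNS are|VBP expressed|VBN "
        "exclusively|RB in|IN myeloid|JJ cells|NNS .|.",
        chunks=[(0, 1, 0), (2, 4, 3), (8, 10, 9)],
        edges=[("prep-arg12", ("chunk", 0), ("chunk", 1))])
    b.add_sentence(s1)
    b.add_sentence(s2)
    for tok in (16, 18, 20, 22, 24, 27):
        b.mark_protein(0, tok)
    # gold antecedent is the coordinated span the parser missed
    b.add_gold_link(("chunk", 1, 1), ("span", 0, 15, 28))
    doc, parses = b.build()
    return PackagedExample(
        "PMID-9291089", doc, parses,
        expected={"rb-full": {
            "these factors": "transcription factors from several families"}},
        flags=frozenset({"parse-error-on-coordination"}))


def packaged_examples() -> list[PackagedExample]:
    """All packaged worked-example documents with gold parses."""
    return [
        _table2_workflow_example(),
        _irf1_example(),
        _ciita_example(),
        _bcl6_example(),
        _tat_example(),
        _otf1_example(),
        _ebf_example(),
        _myeloid_example(),
    ]


# ---------------------------------------------------------------------------
# Synthetic corpus generator

# anaphor-type mix: training-data percentages over the six generated types
# (possessive 25.3, relative 18.6, demonstrative NP 15.2, demonstrative
# pronoun 13.6, the-definite NP 10.9, personal 9.6), renormalized.
_RAW_MIX = {
    "POSS": 25.3,
    "RELAT": 18.6,
    "DNP_DEM": 15.2,
    "DEM": 13.6,
    "DNP_THE": 10.9,
    "PERS": 9.6,
}
DEFAULT_ANAPHOR_TYPE_MIX = {k: v / sum(_RAW_MIX.values())
                            for k, v in _RAW_MIX.items()}

# sentence distance anaphor -> antecedent; 97% of links within 2 sentences
DEFAULT_DISTANCE_DISTRIBUTION = {0: 0.62, 1: 0.28, 2: 0.07, 3: 0.03}

_PROTEIN_NAMES = ["p53", "STAT3", "c-Myc", "IRF-1", "TRAF2", "BCL6",
                  "CIITA", "NF-kappaB", "E47", "Max", "OTF-1", "GATA-1"]
_CUE_KEYWORDS = ["binding", "expression", "regulation", "phosphorylation",
                 "transactivation", "localization", "interaction"]
_NON_CUE_NOUNS = ["reaction", "assembly", "turnover"]
_DNP_SING_HEADS = ["protein", "factor", "receptor"]
_DNP_PLUR_HEADS = ["genes", "factors"]


@dataclass(frozen=True)
class GeneratorConfig:
    n_documents: int = 120
    sentences_per_document: int = 6
    anaphor_type_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ANAPHOR_TYPE_MIX))
    antecedent_distance_distribution: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_DISTANCE_DISTRIBUTION))
    protein_density: float = 0.15
    keyword_cue_rate: float = 0.9
    distractor_rate: float = 0.6
    number_distractor_rate: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        for name, dist in (("anaphor_type_mix", self.anaphor_type_mix),
                           ("antecedent_distance_distribution",
                            self.antecedent_distance_distribution)):
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {total})")
            if any(p < 0 for p in dist.values()):
                raise ValueError(f"{name} has negative probabilities")
        if self.n_documents < 0 or self.sentences_per_document < 2:
            raise ValueError("invalid corpus dimensions")


# -- sentence templates ------------------------------------------------------

def _ante_sem_sing(p: str) -> SentenceSpec:
    # protein NP first, singular non-protein distractor after it
    return SentenceSpec.parse(
        f"The|DT {p}|NN protein|NN regulates|VBZ transcription|NN .|.",
        chunks=[(0, 3, 2), (4, 5, 4)])


def _ante_num_sing(p: str) -> SentenceSpec:
    # protein NP last: after number agreement removes plural pads, it wins
    return SentenceSpec.parse(
        f"Transcription|NN requires|VBZ the|DT {p}|NN protein|NN .|.",
        chunks=[(0, 1, 0), (2, 5, 4)])


def _ante_sem_plur(p: str, q: str, head: str = "proteins") -> SentenceSpec:
    return SentenceSpec.parse(
        f"The|DT {p}|NN and|CC {q}|NN {head}|NNS control|VBP cellular|JJ "
        "responses|NNS .|.",
        chunks=[(0, 5, 4), (1, 2, 1), (3, 4, 3), (6, 8, 7)])


def _ante_num_plur(p: str, q: str, head: str = "proteins") -> SentenceSpec:
    return SentenceSpec.parse(
        f"Cellular|JJ signaling|NN requires|VBZ the|DT {p}|NN and|CC "
        f"{q}|NN {head}|NNS .|.",
        chunks=[(0, 2, 1), (3, 8, 7), (4, 5, 4), (6, 7, 6)])


def _context_protein(r: str) -> SentenceSpec:
    return SentenceSpec.parse(
        f"The|DT {r}|NN protein|NN was|VBD described|VBN previously|RB .|.",
        chunks=[(0, 3, 2)])


def _pad_plural() -> SentenceSpec:
    return SentenceSpec.parse(
        "Earlier|JJ experiments|NNS confirmed|VBD these|DT "
        "observations|NNS .|.",
        chunks=[(0, 2, 1), (3, 5, 4)])


def _pad_singular() -> SentenceSpec:
    return SentenceSpec.parse(
        "The|DT earlier|JJ analysis|NN supported|VBD the|DT original|JJ "
        "hypothesis|NN .|.",
        chunks=[(0, 3, 2), (4, 7, 6)])


def _tail() -> SentenceSpec:
    return SentenceSpec.parse(
        "Subsequent|JJ work|NN extended|VBD earlier|JJ findings|NNS .|.",
        chunks=[(0, 2, 1), (3, 5, 4)])


@dataclass
class _Block:
    """Sentences of one anaphor block plus references for gold annotation."""
    sentences: list[SentenceSpec]
    protein_tokens: list[tuple[int, int]]      # (sentence offset, token)
    anaphor_ref: tuple                         # within-block reference
    antecedent_ref: tuple
    # sentence offset (within block) holding the antecedent
    antecedent_sentence: int
    anaphor_sentence: int


def _possessive_block(rng, p, q, plural: bool, distance: int,
                      difficulty: str, cue: bool) -> _Block:
    det = "Their" if plural else "Its"
    kw = str(rng.choice(_CUE_KEYWORDS)) if cue else str(rng.choice(_NON_CUE_NOUNS))
    if distance == 0:
        if plural:
            # coordinated antecedent with plural distractor after it
            s = SentenceSpec.parse(
                f"The|DT {p}|NN and|CC {q}|NN proteins|NNS modulate|VBP "
                f"cellular|JJ responses|NNS through|IN their|PRP$ {kw}|NN "
                "partners|NNS .|.",
                chunks=[(0, 5, 4), (1, 2, 1), (3, 4, 3), (6, 8, 7),
                        (9, 12, 11)],
                edges=[("poss-arg12", ("token", 9), ("chunk", 4))])
            return _Block([s], [(0, 1), (0, 3)], ("token", 0, 9),
                          ("chunk", 0, 0), 0, 0)
        if difficulty == "num":
            s = SentenceSpec.parse(
                f"The|DT {p}|NN protein|NN interacts|VBZ with|IN "
                f"cellular|JJ processes|NNS through|IN its|PRP$ {kw}|NN "
                "partner|NN .|.",
                chunks=[(0, 3, 2), (5, 7, 6), (8, 11, 10)],
                edges=[("poss-arg12", ("token", 8), ("chunk", 2))])
            return _Block([s], [(0, 1)], ("token", 0, 8), ("chunk", 0, 0),
                          0, 0)
        if difficulty == "sem":
            s = SentenceSpec.parse(
                f"The|DT {p}|NN protein|NN modulates|VBZ transcription|NN "
                f"through|IN its|PRP$ {kw}|NN partner|NN .|.",
                chunks=[(0, 3, 2), (4, 5, 4), (6, 9, 8)],
                edges=[("poss-arg12", ("token", 6), ("chunk", 2))])
            return _Block([s], [(0, 1)], ("token", 0, 6), ("chunk", 0, 0),
                          0, 0)
        s = SentenceSpec.parse(
            f"The|DT {p}|NN protein|NN binds|VBZ its|PRP$ {kw}|NN "
            "partner|NN .|.",
            chunks=[(0, 3, 2), (4, 7, 6)],
            edges=[("poss-arg12", ("token", 4), ("chunk", 1))])
        return _Block([s], [(0, 1)], ("token", 0, 4), ("chunk", 0, 0), 0, 0)

    # distance >= 1: antecedent sentence, pads, anaphor sentence
    if plural:
        ante = _ante_sem_plur(p, q) if difficulty == "sem" else \
            _ante_num_plur(p, q)
        gold_chunk = 0 if difficulty == "sem" else 1
        prot = [(0, 1), (0, 3)] if difficulty == "sem" else [(0, 4), (0, 6)]
        pad = _pad_singular
        head = "partners|NNS"
    else:
        ante = _ante_sem_sing(p) if difficulty == "sem" else _ante_num_sing(p)
        gold_chunk = 0 if difficulty == "sem" else 1
        prot = [(0, 1)] if difficulty == "sem" else [(0, 3)]
        pad = _pad_plural
        head = "partner|NN"
    ana = SentenceSpec.parse(
        f"{det}|PRP$ {kw}|NN {head} activates|VBZ downstream|JJ "
        "signaling|NN .|.",
        chunks=[(0, 3, 2), (4, 6, 5)],
        edges=[("poss-arg12", ("token", 0), ("chunk", 0))])
    sentences = [ante] + [pad() for _ in range(distance - 1)] + [ana]
    return _Block(sentences, prot, ("token", distance, 0),
                  ("chunk", 0, gold_chunk), 0, distance)


def _pronoun_block(rng, p, q, kind: str, plural: bool, distance: int,
                   difficulty: str) -> _Block:
    if kind == "PERS":
        surface = ("They|PRP activate|VBP" if plural
                   else "It|PRP activates|VBZ")
        ana = SentenceSpec.parse(
            f"{surface} downstream|JJ signaling|NN .|.",
            chunks=[(2, 4, 3)])
        pron_tok = 0
    else:  # DEM
        surface = ("These|DT sustain|VBP" if plural
                   else "This|DT sustains|VBZ")
        ana = SentenceSpec.parse(
            f"{surface} the|DT cellular|JJ response|NN .|.",
            chunks=[(2, 5, 4)])
        pron_tok = 0

    if distance == 0:
        verb = "activate|VBP" if plural else "activates|VBZ"
        pron = ("they|PRP" if plural else "it|PRP") if kind == "PERS" else \
            ("these|DT" if plural else "this|DT")
        if plural:
            if difficulty == "disc":
                s = SentenceSpec.parse(
                    f"The|DT {p}|NN and|CC {q}|NN proteins|NNS control|VBP "
                    f"cellular|JJ responses|NNS ,|, and|CC {pron} {verb} "
                    "downstream|JJ signaling|NN .|.",
                    chunks=[(0, 5, 4), (1, 2, 1), (3, 4, 3), (6, 8, 7),
                            (12, 14, 13)])
                return _Block([s], [(0, 1), (0, 3)], ("token", 0, 10),
                              ("chunk", 0, 0), 0, 0)
            s = SentenceSpec.parse(
                f"The|DT {p}|NN and|CC {q}|NN proteins|NNS are|VBP "
                f"activated|VBN ,|, and|CC {pron} {verb} downstream|JJ "
                "signaling|NN .|.",
                chunks=[(0, 5, 4), (1, 2, 1), (3, 4, 3), (11, 13, 12)])
            return _Block([s], [(0, 1), (0, 3)], ("token", 0, 9),
                          ("chunk", 0, 0), 0, 0)
        if difficulty == "disc":
            s = SentenceSpec.parse(
                f"The|DT {p}|NN protein|NN regulates|VBZ transcription|NN "
                f",|, and|CC {pron} {verb} downstream|JJ signaling|NN .|.",
                chunks=[(0, 3, 2), (4, 5, 4), (9, 11, 10)])
            return _Block([s], [(0, 1)], ("token", 0, 7), ("chunk", 0, 0),
                          0, 0)
        s = SentenceSpec.parse(
            f"The|DT {p}|NN protein|NN is|VBZ activated|VBN ,|, and|CC "
            f"{pron} {verb} downstream|JJ signaling|NN .|.",
            chunks=[(0, 3, 2), (9, 11, 10)])
        return _Block([s], [(0, 1)], ("token", 0, 7), ("chunk", 0, 0), 0, 0)

    if plural:
        ante = _ante_sem_plur(p, q)  # protein NP farthest, distractor after
        prot = [(0, 1), (0, 3)]
        pad = _pad_singular
    else:
        ante = _ante_sem_sing(p)
        prot = [(0, 1)]
        pad = _pad_plural
    sentences = [ante] + [pad() for _ in range(distance - 1)] + [ana]
    return _Block(sentences, prot, ("token", distance, pron_tok),
                  ("chunk", 0, 0), 0, distance)


def _dnp_block(rng, p, q, plural: bool, distance: int,
               difficulty: str) -> _Block:
    if plural:
        head = str(rng.choice(_DNP_PLUR_HEADS))
        ana = SentenceSpec.parse(
            f"These|DT {head}|NNS encode|VBP essential|JJ regulators|NNS .|.",
            chunks=[(0, 2, 1), (3, 5, 4)])
        ante_head = "genes" if head == "genes" else "proteins"
    else:
        head = str(rng.choice(_DNP_SING_HEADS))
        ana = SentenceSpec.parse(
            f"The|DT {head}|NN binds|VBZ nuclear|JJ DNA|NN .|.",
            chunks=[(0, 2, 1), (3, 5, 4)])
        ante_head = "protein"

    if distance == 0:
        if plural:
            s = SentenceSpec.parse(
                f"The|DT {p}|NN and|CC {q}|NN {ante_head}|NNS control|VBP "
                f"cellular|JJ responses|NNS ,|, and|CC these|DT {head}|NNS "
                "encode|VBP essential|JJ regulators|NNS .|.",
                chunks=[(0, 5, 4), (1, 2, 1), (3, 4, 3), (6, 8, 7),
                        (10, 12, 11), (13, 15, 14)])
            return _Block([s], [(0, 1), (0, 3)], ("chunk", 0, 4),
                          ("chunk", 0, 0), 0, 0)
        if difficulty == "num":
            s = SentenceSpec.parse(
                f"The|DT {p}|NN protein|NN associates|VBZ with|IN "
                f"cellular|JJ processes|NNS ,|, and|CC the|DT {head}|NN "
                "binds|VBZ nuclear|JJ DNA|NN .|.",
                chunks=[(0, 3, 2), (5, 7, 6), (9, 11, 10), (12, 14, 13)])
            return _Block([s], [(0, 1)], ("chunk", 0, 2), ("chunk", 0, 0),
                          0, 0)
        s = SentenceSpec.parse(
            f"The|DT {p}|NN protein|NN regulates|VBZ transcription|NN ,|, "
            f"and|CC the|DT {head}|NN binds|VBZ nuclear|JJ DNA|NN .|.",
            chunks=[(0, 3, 2), (4, 5, 4), (7, 9, 8), (10, 12, 11)])
        return _Block([s], [(0, 1)], ("chunk", 0, 2), ("chunk", 0, 0), 0, 0)

    if plural:
        if difficulty == "sem":
            ante = _ante_sem_plur(p, q, ante_head)
            gold_chunk, prot = 0, [(0, 1), (0, 3)]
        else:
            ante = _ante_num_plur(p, q, ante_head)
            gold_chunk, prot = 1, [(0, 4), (0, 6)]
        pad = _pad_singular
    else:
        if difficulty == "sem":
            ante = _ante_sem_sing(p)
            gold_chunk, prot = 0, [(0, 1)]
        else:
            ante = _ante_num_sing(p)
            gold_chunk, prot = 1, [(0, 3)]
        pad = _pad_plural
    sentences = [ante] + [pad() for _ in range(distance - 1)] + [ana]
    return _Block(sentences, prot, ("chunk", distance, 0),
                  ("chunk", 0, gold_chunk), 0, distance)


def _relat_block(rng, p) -> _Block:
    s = SentenceSpec.parse(
        f"The|DT {p}|NN protein|NN ,|, which|WDT mediates|VBZ "
        "transcription|NN ,|, is|VBZ essential|JJ .|.",
        chunks=[(0, 3, 2), (6, 7, 6)],
        edges=[("relative-arg", ("chunk", 0), ("token", 4))])
    return _Block([s], [(0, 1)], ("token", 0, 4), ("chunk", 0, 0), 0, 0)


def _sample(rng, dist: Mapping) -> object:
    keys = list(dist.keys())
    probs = np.array([dist[k] for k in keys], dtype=float)
    return keys[int(rng.choice(len(keys), p=probs / probs.sum()))]


def generate_document(rng: np.random.Generator, config: GeneratorConfig,
                      doc_id: str) -> tuple[Document, list[ParsedSentence]]:
    """One document = one anaphor block plus optional context and tail."""
    atype = str(_sample(rng, config.anaphor_type_mix))
    distance = 0 if atype == "RELAT" else int(
        _sample(rng, config.antecedent_distance_distribution))
    p, q = (str(n) for n in rng.choice(_PROTEIN_NAMES, size=2, replace=False))

    u = rng.random()
    if u < config.distractor_rate:
        difficulty = "sem"
    elif u < config.distractor_rate + config.number_distractor_rate:
        difficulty = "num"
    else:
        difficulty = "easy"

    plural = bool(rng.random() < 0.35) and atype != "RELAT"

    if atype == "POSS":
        cue = bool(rng.random() < config.keyword_cue_rate)
        block = _possessive_block(rng, p, q, plural, distance, difficulty, cue)
    elif atype in ("PERS", "DEM"):
        block = _pronoun_block(rng, p, q, atype, plural, distance,
                               "disc" if difficulty != "easy" else "easy")
    elif atype in ("DNP_THE", "DNP_DEM"):
        block = _dnp_block(rng, p, q, plural or atype == "DNP_DEM",
                           distance, difficulty)
    elif atype == "RELAT":
        block = _relat_block(rng, p)
    else:
        raise ValueError(f"unknown anaphor type {atype!r}")

    b = DocumentBuilder(doc_id)
    base = 0
    # optional context sentence with an unrelated protein, placed before the
    # antecedent (kept out of discourse-preference blocks by construction)
    if atype in ("POSS", "DNP_THE", "DNP_DEM") and \
            rng.random() < config.protein_density:
        r = str(rng.choice([n for n in _PROTEIN_NAMES if n not in (p, q)]))
        b.add_sentence(_context_protein(r))
        b.mark_protein(0, 1)
        base = 1
    for spec in block.sentences:
        b.add_sentence(spec)
    for sent_off, tok in block.protein_tokens:
        b.mark_protein(base + sent_off, tok)
    ana = (block.anaphor_ref[0], base + block.anaphor_ref[1],
           *block.anaphor_ref[2:])
    ante = (block.antecedent_ref[0], base + block.antecedent_ref[1],
            *block.antecedent_ref[2:])
    b.add_gold_link(ana, ante)
    while len(b.sentences) < config.sentences_per_document:
        b.add_sentence(_tail())
    return b.build()


def generate_corpus(config: GeneratorConfig = GeneratorConfig()
                    ) -> list[tuple[Document, list[ParsedSentence]]]:
    """Generate a corpus; the same config (incl. seed) yields a byte-
    identical corpus."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    return [generate_document(rng, config, f"synth-{i:04d}")
            for i in range(config.n_documents)]
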
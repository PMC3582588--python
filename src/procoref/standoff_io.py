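"""BioNLP-ST standoff annotation I/O.

Documents come as triples of files sharing a basename:

* ``doc.txt`` — the raw text (UTF-8).
* ``doc.a1`` — given protein mentions, one term line each::

      T1<TAB>Protein 10 13<TAB>p65

* ``doc.a2`` (optional) — coreferential expressions plus coreference
  relations::

      T12<TAB>Exp 120 145<TAB>this transcription factor
      R1<TAB>Coref Anaphora:T12 Antecedent:T3

Offsets are 0-based, half-open, over the text decoded as UTF-8.  The third
column of a term line must equal ``text[start:end]``; any mismatch, dangling
term reference or malformed line raises :class:`StandoffParseError` naming
the file and line.

Protein coreference links — the unit of the shared task's primary metric —
are not stored in the files: they are derived from expression-level links by
:func:`derive_protein_links` (an anaphor is linked to every protein mention
contained in its antecedent expression).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "TextSpan",
    "ProteinMention",
    "CoreferenceLink",
    "ProteinCorefLink",
    "Document",
    "StandoffParseError",
    "read_standoff",
    "write_predictions",
    "derive_protein_links",
]


class StandoffParseError(ValueError):
    """Malformed or inconsistent standoff annotation."""

    def __init__(self, message: str, path: str | os.PathLike | None = None,
                 line_no: int | None = None):
        loc = ""
        if path is not None:
            loc = f"{path}"
            if line_no is not None:
                loc += f":{line_no}"
            loc = f" [{loc}]"
        super().__init__(message + loc)
        self.path = str(path) if path is not None else None
        self.line_no = line_no


@dataclass(frozen=True, order=True)
class TextSpan:
    """A character span ``[start, end)`` with its surface string."""

    start: int
    end: int
    text: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start},{self.end})")

    def contains(self, other: "TextSpan") -> bool:
        return self.start <= other.start and other.end <= self.end

    def overlaps(self, other: "TextSpan") -> bool:
        return self.start < other.end and other.start < self.end

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ProteinMention:
    """A given (gold) protein name, e.g. an .a1 ``Protein`` term."""

    id: str
    span: TextSpan
    type: str = "Protein"


@dataclass(frozen=True)
class CoreferenceLink:
    """An anaphor → antecedent expression pair; the antecedent precedes."""

    anaphor: TextSpan
    antecedent: TextSpan


@dataclass(frozen=True)
class ProteinCorefLink:
    """An anaphor → antecedent-protein pair (the primary evaluation unit)."""

    anaphor: TextSpan
    protein_id: str


@dataclass
class Document:
    """Text plus protein mentions plus (optionally) gold coreference links."""

    doc_id: str
    text: str
    proteins: list[ProteinMention] = field(default_factory=list)
    gold_links: list[CoreferenceLink] = field(default_factory=list)

    def protein_by_id(self, term_id: str) -> ProteinMention:
        for p in self.proteins:
            if p.id == term_id:
                return p
        raise KeyError(term_id)


def _validate_span(span: TextSpan, text: str, path=None, line_no=None) -> None:
    if span.end > len(text):
        raise StandoffParseError(
            f"span [{span.start},{span.end}) outside text of length {len(text)}",
            path, line_no)
    actual = text[span.start:span.end]
    if actual != span.text:
        raise StandoffParseError(
            f"span text mismatch: annotation {span.text!r} vs text {actual!r}",
            path, line_no)


def _parse_term_line(line: str, text: str, path, line_no) -> tuple[str, str, TextSpan]:
    parts = line.rstrip("\n").split("\t")
    if len(parts) != 3:
        raise StandoffParseError(
            f"expected 3 tab-separated columns, got {len(parts)}", path, line_no)
    term_id, type_and_offsets, surface = parts
    fields = type_and_offsets.split(" ")
    if len(fields) != 3:
        raise StandoffParseError(
            f"expected 'Type start end', got {type_and_offsets!r}", path, line_no)
    term_type, s, e = fields
    try:
        start, end = int(s), int(e)
    except ValueError:
        raise StandoffParseError(f"non-integer offsets in {type_and_offsets!r}",
                                 path, line_no) from None
    if not (0 <= start < end):
        raise StandoffParseError(f"invalid offsets {start} {end}", path, line_no)
    span = TextSpan(start, end, surface)
    _validate_span(span, text, path, line_no)
    return term_id, term_type, span


def read_standoff(txt_path: str | os.PathLike,
                  a1_path: str | os.PathLike,
                  a2_path: str | os.PathLike | None = None) -> Document:
    """Read a standoff triple into a :class:`Document`.

    ``a2_path`` may be ``None`` (no gold coreference) or point to a missing
    file only if ``None`` is passed; relations are resolved from term ids
    (looked up in both .a1 and .a2 terms) to text spans.
    """
    txt_path = Path(txt_path)
    text = txt_path.read_text(encoding="utf-8")
    doc_id = txt_path.stem

    proteins: list[ProteinMention] = []
    seen_ids: set[str] = set()
    terms: dict[str, TextSpan] = {}
    for line_no, line in enumerate(
            Path(a1_path).read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip():
            continue
        term_id, term_type, span = _parse_term_line(line, text, a1_path, line_no)
        if term_id in seen_ids:
            raise StandoffParseError(f"duplicate term id {term_id}", a1_path, line_no)
        seen_ids.add(term_id)
        terms[term_id] = span
        proteins.append(ProteinMention(term_id, span, term_type))

    gold_links: list[CoreferenceLink] = []
    if a2_path is not None:
        relations: list[tuple[str, str, int]] = []
        for line_no, line in enumerate(
                Path(a2_path).read_text(encoding="utf-8").splitlines(), start=1):
            if not line.strip():
                continue
            if line.startswith("T"):
                term_id, _type, span = _parse_term_line(line, text, a2_path, line_no)
                if term_id in seen_ids:
                    raise StandoffParseError(f"duplicate term id {term_id}",
                                             a2_path, line_no)
                seen_ids.add(term_id)
                terms[term_id] = span
            elif line.startswith("R"):
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 2:
                    raise StandoffParseError("malformed relation line",
                                             a2_path, line_no)
                rel = parts[1].split(" ")
                if len(rel) != 3 or not rel[0]:
                    raise StandoffParseError(f"malformed relation {parts[1]!r}",
                                             a2_path, line_no)
                args = dict(a.split(":", 1) for a in rel[1:] if ":" in a)
                if set(args) != {"Anaphora", "Antecedent"}:
                    raise StandoffParseError(
                        f"relation needs Anaphora and Antecedent args, got {rel[1:]}",
                        a2_path, line_no)
                relations.append((args["Anaphora"], args["Antecedent"], line_no))
            else:
                raise StandoffParseError(f"unrecognized line {line[:40]!r}",
                                         a2_path, line_no)
        for ana_id, ante_id, line_no in relations:
            for tid in (ana_id, ante_id):
                if tid not in terms:
                    raise StandoffParseError(f"dangling term reference {tid}",
                                             a2_path, line_no)
            gold_links.append(CoreferenceLink(terms[ana_id], terms[ante_id]))

    return Document(doc_id, text, proteins, gold_links)


def write_predictions(document: Document,
                      links: Sequence[CoreferenceLink],
                      a2_path: str | os.PathLike) -> None:
    """Write coreference links as an .a2 file.

    Output is deterministic: expression terms are sorted by start offset
    (then end), each distinct span emitted once, with ids continuing after
    the document's .a1 term ids; relations are sorted by anaphor offset.
    All spans are validated against the text before anything is written.
    """
    spans: set[TextSpan] = set()
    for link in links:
        for span in (link.anaphor, link.antecedent):
            _validate_span(span, document.text)
            spans.add(span)

    next_id = 1 + max((int(p.id[1:]) for p in document.proteins
                       if p.id[:1] == "T" and p.id[1:].isdigit()), default=0)
    span_to_id: dict[TextSpan, str] = {}
    lines: list[str] = []
    for span in sorted(spans, key=lambda s: (s.start, s.end)):
        tid = f"T{next_id}"
        next_id += 1
        span_to_id[span] = tid
        lines.append(f"{tid}\tExp {span.start} {span.end}\t{span.text}")

    ordered = sorted(set(links),
                     key=lambda l: (l.anaphor.start, l.anaphor.end,
                                    l.antecedent.start, l.antecedent.end))
    for i, link in enumerate(ordered, start=1):
        lines.append(f"R{i}\tCoref Anaphora:{span_to_id[link.anaphor]} "
                     f"Antecedent:{span_to_id[link.antecedent]}")

    Path(a2_path).write_text("".join(line + "\n" for line in lines),
                             encoding="utf-8")


def derive_protein_links(gold_links: Iterable[CoreferenceLink],
                         proteins: Sequence[ProteinMention]
                         ) -> list[ProteinCorefLink]:
    """Derive protein coreference links from expression-level links.

    For every link whose antecedent span contains one or more protein
    mentions, one ``ProteinCorefLink`` is emitted per contained mention;
    links whose antecedent contains no protein yield nothing.  Duplicates
    are removed, order follows first appearance.
    """
    out: list[ProteinCorefLink] = []
    seen: set[ProteinCorefLink] = set()
    for link in gold_links:
        for protein in proteins:
            if link.antecedent.contains(protein.span):
                pl = ProteinCorefLink(link.anaphor, protein.id)
                if pl not in seen:
                    seen.add(pl)
                    out.append(pl)
    return out
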
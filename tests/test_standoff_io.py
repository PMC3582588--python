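import pytest

from procoref.standoff_io import (CoreferenceLink, Document, ProteinMention,
                                  StandoffParseError, TextSpan,
                                  derive_protein_links, read_standoff,
                                  write_predictions)


def _write_doc(tmp_path, text, a1_lines, a2_lines=None):
    (tmp_path / "doc.txt").write_text(text, encoding="utf-8")
    (tmp_path / "doc.a1").write_text("".join(l + "\n" for l in a1_lines),
                                     encoding="utf-8")
    a2 = None
    if a2_lines is not None:
        a2 = tmp_path / "doc.a2"
        a2.write_text("".join(l + "\n" for l in a2_lines), encoding="utf-8")
    return tmp_path / "doc.txt", tmp_path / "doc.a1", a2


def test_read_term_line(tmp_path):
    txt, a1, _ = _write_doc(tmp_path, "p65 binds DNA.",
                            ["T1\tProtein 0 3\tp65"])
    doc = read_standoff(txt, a1)
    assert doc.proteins == [ProteinMention("T1", TextSpan(0, 3, "p65"))]
    assert doc.gold_links == []


def test_read_resolves_relations_to_spans(tmp_path):
    text = "The p65 protein is active. It binds DNA."
    txt, a1, a2 = _write_doc(
        tmp_path, text,
        ["T1\tProtein 4 7\tp65"],
        ["T2\tExp 0 15\tThe p65 protein",
         "T3\tExp 27 29\tIt",
         "R1\tCoref Anaphora:T3 Antecedent:T2"])
    doc = read_standoff(txt, a1, a2)
    assert doc.gold_links == [CoreferenceLink(TextSpan(27, 29, "It"),
                                              TextSpan(0, 15, "The p65 protein"))]


@pytest.mark.parametrize("bad_line, hint", [
    ("T1\tProtein 0 99\tp65", "outside text"),
    ("T1\tProtein 0 3\txxx", "mismatch"),
    ("T1\tProtein 0\tp65", "Type start end"),
    ("T1 Protein 0 3 p65", "column"),
])
def test_malformed_a1_raises_with_location(tmp_path, bad_line, hint):
    txt, a1, _ = _write_doc(tmp_path, "p65 binds DNA.", [bad_line])
    with pytest.raises(StandoffParseError, match=hint) as exc_info:
        read_standoff(txt, a1)
    assert "a1" in str(exc_info.value)


def test_dangling_relation_reference(tmp_path):
    txt, a1, a2 = _write_doc(
        tmp_path, "p65 binds DNA.",
        ["T1\tProtein 0 3\tp65"],
        ["R1\tCoref Anaphora:T9 Antecedent:T1"])
    with pytest.raises(StandoffParseError, match="dangling"):
        read_standoff(txt, a1, a2)


def test_write_read_round_trip_is_fixed_point(tmp_path, table2):
    doc = table2.document
    out = tmp_path / "pred.a2"
    write_predictions(doc, doc.gold_links, out)
    txt = tmp_path / "doc.txt"
    txt.write_text(doc.text, encoding="utf-8")
    a1 = tmp_path / "doc.a1"
    a1.write_text("".join(
        f"{p.id}\t{p.type} {p.span.start} {p.span.end}\t{p.span.text}\n"
        for p in doc.proteins), encoding="utf-8")
    reread = read_standoff(txt, a1, out)
    assert set(reread.gold_links) == set(doc.gold_links)
    # writing the re-read links reproduces the same bytes
    out2 = tmp_path / "pred2.a2"
    write_predictions(reread, reread.gold_links, out2)
    assert out.read_bytes() == out2.read_bytes()


def test_write_empty_and_single_link(tmp_path):
    doc = Document("d", "A binds B.", [])
    out = tmp_path / "o.a2"
    write_predictions(doc, [], out)
    assert out.read_text() == ""
    link = CoreferenceLink(TextSpan(8, 9, "B"), TextSpan(0, 1, "A"))
    write_predictions(doc, [link], out)
    lines = out.read_text().splitlines()
    assert sum(l.startswith("T") for l in lines) == 2
    assert sum(l.startswith("R") for l in lines) == 1


def test_write_shared_antecedent_term_emitted_once(tmp_path):
    text = "p65 binds X. It acts. It moves."
    doc = Document("d", text, [])
    ante = TextSpan(0, 3, "p65")
    links = [CoreferenceLink(TextSpan(13, 15, "It"), ante),
             CoreferenceLink(TextSpan(22, 24, "It"), ante)]
    out = tmp_path / "o.a2"
    write_predictions(doc, links, out)
    term_lines = [l for l in out.read_text().splitlines() if l.startswith("T")]
    assert len(term_lines) == 3  # two anaphors + one shared antecedent


def test_write_invalid_span_fails_before_writing(tmp_path):
    doc = Document("d", "short", [])
    out = tmp_path / "o.a2"
    bad = [CoreferenceLink(TextSpan(0, 99, "x"), TextSpan(0, 1, "s"))]
    with pytest.raises(StandoffParseError):
        write_predictions(doc, bad, out)
    assert not out.exists()


class TestDeriveProteinLinks:
    text = "NF-kappa B p65 is excluded. This transcription factor acts."
    p65 = ProteinMention("T1", TextSpan(11, 14, "p65"))
    ante = TextSpan(0, 14, "NF-kappa B p65")
    ana = TextSpan(28, 54, "This transcription factor")

    def test_antecedent_protein_extracted(self):
        links = derive_protein_links(
            [CoreferenceLink(self.ana, self.ante)], [self.p65])
        assert [(l.anaphor, l.protein_id) for l in links] == [(self.ana, "T1")]

    def test_antecedent_without_protein_yields_nothing(self):
        no_prot_ante = TextSpan(15, 26, "is excluded")
        assert derive_protein_links(
            [CoreferenceLink(self.ana, no_prot_ante)], [self.p65]) == []

    def test_empty_links(self):
        assert derive_protein_links([], [self.p65]) == []

    def test_multi_protein_antecedent_emits_one_link_each(self):
        extra = ProteinMention("T2", TextSpan(0, 8, "NF-kappa"))
        links = derive_protein_links(
            [CoreferenceLink(self.ana, self.ante)], [self.p65, extra])
        assert {l.protein_id for l in links} == {"T1", "T2"}
        assert all(l.anaphor == self.ana for l in links)

    def test_every_protein_inside_source_antecedent(self, small_corpus):
        for doc, _ in small_corpus:
            links = derive_protein_links(doc.gold_links, doc.proteins)
            by_id = {p.id: p for p in doc.proteins}
            for link in links:
                ante_spans = [g.antecedent for g in doc.gold_links
                              if g.anaphor == link.anaphor]
                assert any(a.contains(by_id[link.protein_id].span)
                           for a in ante_spans)
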
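import pytest

from procoref.antecedent_candidates import (CandidateConfig, collect_candidates,
                                            dependency_filter,
                                            pronoun_family_filter)
from procoref.synthetic_fixtures import SentenceSpec, realize_sentence
from procoref.markable_detection import detect_markables
from procoref.anaphor_selection import select_anaphors

# the Step 3 row for "its": every preceding markable inside window 2 except
# anaphoric/filtered pronouns and dependency-excluded NPs
TABLE2_ITS_CANDIDATES = {
    "T cell hybridomas", "activation signals", "apoptotic cell death",
    "comparable events related to tolerance induction",
    "immature and mature T cells in vivo", "in vivo",
    "Previous studies using antisense oligonucleotides",
    "antisense oligonucleotides", "the c-Myc protein",
    "the phenomenon of activation-induced apoptosis",
    "activation-induced apoptosis", "This role for c-Myc in apoptosis",
    "c-Myc", "apoptosis", "studies",
}


def _its_candidates(table2_state, table2, window=2):
    markables, anaphors = table2_state
    its = next(a for a in anaphors if a.span.text == "its")
    excluded = frozenset(m.span for m in markables if m.is_pronoun)
    config = CandidateConfig(excluded_pronoun_spans=excluded)
    return collect_candidates(its, markables, table2.parses, window, config)


class TestCollectCandidates:
    def test_table2_its_candidate_row(self, table2_state, table2):
        cset = _its_candidates(table2_state, table2)
        assert {c.span.text for c in cset.candidates} == TABLE2_ITS_CANDIDATES

    def test_excludes_dominant_negative_form_and_this(self, table2_state,
                                                      table2):
        got = {c.span.text for c in _its_candidates(table2_state,
                                                    table2).candidates}
        assert not any("dominant negative form" in t for t in got)
        assert "this" not in got

    def test_nearest_first_order(self, table2_state, table2):
        cset = _its_candidates(table2_state, table2)
        ends = [c.span.end for c in cset.candidates]
        assert ends == sorted(ends, reverse=True)

    def test_window_zero_same_sentence_only(self, table2_state, table2):
        cset = _its_candidates(table2_state, table2, window=0)
        assert all(c.sentence_index == 2 for c in cset.candidates)
        assert {c.span.text for c in cset.candidates} == \
            {"This role for c-Myc in apoptosis", "c-Myc", "apoptosis",
             "studies"}

    def test_window_monotone(self, table2_state, table2):
        prev: set = set()
        for w in (0, 1, 2, 3):
            cur = {c.span for c in
                   _its_candidates(table2_state, table2, w).candidates}
            assert prev <= cur
            prev = cur

    def test_candidates_precede_anaphor(self, table2_state, table2):
        markables, anaphors = table2_state
        for a in anaphors:
            cset = collect_candidates(a, markables, table2.parses)
            assert all(c.span.end < a.span.start for c in cset.candidates)

    def test_negative_window_rejected(self, table2_state, table2):
        markables, anaphors = table2_state
        with pytest.raises(ValueError):
            collect_candidates(anaphors[0], markables, table2.parses, -1)


class TestDependencyFilter:
    @pytest.fixture()
    def truncated_forms(self):
        sent = realize_sentence(SentenceSpec.parse(
            "two|CD such|JJ truncated|JJ forms|NNS of|IN the|DT protein|NN "
            "were|VBD found|VBN .|.",
            chunks=[(0, 4, 3), (5, 7, 6)],
            edges=[("prep-arg12", ("chunk", 0), ("chunk", 1))]), 0, 0)
        return sent

    def test_prep_argument_cannot_be_antecedent(self, truncated_forms):
        sent = truncated_forms
        markables = detect_markables([sent])
        anaphors = select_anaphors(markables, [sent])
        the_protein = next(a for a in anaphors
                           if a.span.text == "the protein")
        forms = next(m for m in markables
                     if m.span.text == "two such truncated forms")
        assert dependency_filter(the_protein, forms, sent.edges) is False
        cset = collect_candidates(the_protein, markables, [sent])
        assert forms.span not in {c.span for c in cset.candidates}

    def test_unrelated_candidate_kept(self, table2_state, table2):
        markables, anaphors = table2_state
        its = next(a for a in anaphors if a.span.text == "its")
        c_myc = next(m for m in markables if m.span.text == "c-Myc")
        assert dependency_filter(its, c_myc, table2.parses[2].edges) is True


class TestPronounFamilyFilter:
    def test_cross_family_pronoun_dropped(self, table2_state):
        markables, anaphors = table2_state
        its = next(a for a in anaphors if a.span.text == "its")
        this = next(m for m in markables if m.span.text == "this")
        assert pronoun_family_filter(its, this) is False

    def test_same_family_kept(self, table2_state):
        markables, anaphors = table2_state
        its = next(a for a in anaphors if a.span.text == "its")
        # synthesize an "it" markable from the "this" one for the family check
        import dataclasses
        this = next(m for m in markables if m.span.text == "this")
        from procoref.syntax_adapter import Token
        it_tok = Token(this.head.span, "PRP", "it")
        it = dataclasses.replace(this, head=it_tok, tokens=(it_tok,))
        assert pronoun_family_filter(its, it) is True

    def test_non_pronoun_candidate_not_applicable(self, table2_state):
        markables, anaphors = table2_state
        its = next(a for a in anaphors if a.span.text == "its")
        c_myc = next(m for m in markables if m.span.text == "c-Myc")
        assert pronoun_family_filter(its, c_myc) is True
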
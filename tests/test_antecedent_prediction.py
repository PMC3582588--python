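import functools
import itertools

import pytest

from procoref.anaphor_selection import RELAT
from procoref.antecedent_candidates import CandidateConfig, collect_candidates
from procoref.antecedent_prediction import (PRESETS, RuleConfig,
                                            predict_antecedent, prefer,
                                            resolve_document, resolve_relative)
from procoref.pipeline import PipelineConfig, resolve_with_config
from tests.conftest import pipeline_state


def _candidate_set(example, anaphor_text):
    markables, anaphors = pipeline_state(example)
    anaphor = next(a for a in anaphors if a.span.text == anaphor_text)
    excluded = frozenset(m.span for m in markables if m.is_pronoun)
    return anaphor, collect_candidates(
        anaphor, markables, example.parses, 2,
        CandidateConfig(excluded_pronoun_spans=excluded))


class TestPrefer:
    @pytest.mark.parametrize("preset", sorted(PRESETS))
    def test_asymmetry(self, table2, preset):
        config = PRESETS[preset]
        anaphor, cset = _candidate_set(table2, "its")
        for a, b in itertools.combinations(cset.candidates, 2):
            assert prefer(a, b, anaphor, config).winner == \
                prefer(b, a, anaphor, config).winner

    def test_identical_candidates_rejected(self, table2):
        anaphor, cset = _candidate_set(table2, "its")
        c = cset.candidates[0]
        with pytest.raises(ValueError):
            prefer(c, c, anaphor)

    def test_semantic_rule_decides_for_protein_anaphor(self, table2):
        anaphor, cset = _candidate_set(table2, "its")
        by_text = {c.span.text: c for c in cset.candidates}
        pref = prefer(by_text["apoptosis"], by_text["c-Myc"], anaphor)
        assert pref.winner.span.text == "c-Myc"
        assert pref.deciding_rule == "SEM-CONS"

    def test_number_rule_decides(self, table2):
        anaphor, cset = _candidate_set(table2, "its")
        by_text = {c.span.text: c for c in cset.candidates}
        pref = prefer(by_text["studies"], by_text["apoptosis"], anaphor)
        assert pref.winner.span.text == "apoptosis"
        assert pref.deciding_rule == "NUM-AGREE"

    def test_default_prefers_closer(self, table2):
        anaphor, cset = _candidate_set(table2, "its")
        by_text = {c.span.text: c for c in cset.candidates}
        pref = prefer(by_text["c-Myc"], by_text["the c-Myc protein"], anaphor)
        assert pref.winner.span.text == "c-Myc"
        assert pref.deciding_rule == "DEFAULT"


class TestPredictAntecedent:
    def test_rb_min_returns_nearest(self, table2):
        anaphor, cset = _candidate_set(table2, "its")
        got = predict_antecedent(anaphor, cset, PRESETS["rb-min"])
        assert got == cset.candidates[0]

    def test_rb_full_table2_prediction(self, table2):
        anaphor, cset = _candidate_set(table2, "its")
        got = predict_antecedent(anaphor, cset, PRESETS["rb-full"])
        assert got.span.text == "c-Myc"

    def test_empty_candidate_set_none(self, table2):
        anaphor, cset = _candidate_set(table2, "its")
        empty = type(cset)(anaphor, ())
        assert predict_antecedent(anaphor, empty) is None

    def test_single_candidate_regardless_of_rules(self, table2):
        anaphor, cset = _candidate_set(table2, "its")
        single = type(cset)(anaphor, cset.candidates[:1])
        for preset in PRESETS.values():
            assert predict_antecedent(anaphor, single, preset) == \
                cset.candidates[0]

    @pytest.mark.parametrize("preset", sorted(PRESETS))
    def test_tournament_matches_pairwise_sort(self, examples, preset):
        """The incumbent/challenger tournament picks the same winner as an
        exhaustive comparison sort by the same decision list."""
        config = PRESETS[preset]
        for ex in examples.values():
            _, anaphors = pipeline_state(ex)
            for a in anaphors:
                if a.anaphor_type == RELAT:
                    continue
                anaphor, cset = _candidate_set(ex, a.span.text)
                if len(cset.candidates) < 2:
                    continue

                def cmp(x, y):
                    return -1 if prefer(x, y, anaphor, config).winner == x else 1

                best = sorted(cset.candidates,
                              key=functools.cmp_to_key(cmp))[0]
                assert predict_antecedent(anaphor, cset, config) == best


class TestResolveRelative:
    def test_attached(self, table2):
        _, anaphors = pipeline_state(table2)
        which = next(a for a in anaphors if a.anaphor_type == RELAT)
        link = resolve_relative(which, table2.parses[2])
        assert link.antecedent.text == "Max"

    def test_unattached_returns_none(self, table2):
        _, anaphors = pipeline_state(table2)
        which = next(a for a in anaphors if a.anaphor_type == RELAT)
        import dataclasses
        stripped = dataclasses.replace(table2.parses[2], edges=())
        assert resolve_relative(which, stripped) is None

    def test_non_relat_rejected(self, table2):
        _, anaphors = pipeline_state(table2)
        its = next(a for a in anaphors if a.span.text == "its")
        with pytest.raises(ValueError):
            resolve_relative(its, table2.parses[2])


class TestResolveDocument:
    def test_antecedent_precedes_anaphor(self, examples, small_corpus):
        pairs = [(ex.document, ex.parses) for ex in examples.values()]
        pairs += [(d, p) for d, p in small_corpus[:10]]
        for doc, parses in pairs:
            for link in resolve_document(doc, parses):
                assert link.antecedent.start < link.anaphor.start

    def test_at_most_one_link_per_anaphor(self, small_corpus):
        for doc, parses in small_corpus[:10]:
            links = resolve_document(doc, parses)
            anaphors = [l.anaphor for l in links]
            assert len(anaphors) == len(set(anaphors))

    def test_deterministic(self, table2):
        a = resolve_document(table2.document, table2.parses)
        b = resolve_document(table2.document, table2.parses)
        assert a == b

    def test_no_anaphors_empty(self):
        from procoref.synthetic_fixtures import (SentenceSpec,
                                                 DocumentBuilder)
        b = DocumentBuilder("d")
        b.add_sentence(SentenceSpec.parse(
            "STAT3|NN binds|VBZ DNA|NN .|.", chunks=[(0, 1, 0), (2, 3, 2)]))
        doc, parses = b.build()
        assert resolve_document(doc, parses) == []

    def test_presets_differ_only_where_rules_decided(self, examples):
        """rb-min and rb-full disagree exactly on anaphors whose rb-full
        tournament used SEM-CONS or DISC-PREF."""
        for ex in examples.values():
            traces = []
            full = {l.anaphor: l.antecedent
                    for l in resolve_with_config(
                        ex.document, ex.parses,
                        PipelineConfig(preset="rb-full"), traces=traces)}
            minimal = {l.anaphor: l.antecedent
                       for l in resolve_with_config(
                           ex.document, ex.parses,
                           PipelineConfig(preset="rb-min"))}
            assert set(full) == set(minimal)
            rules_used = {
                t.anaphor.span: {p.deciding_rule for _, _, p in t.decisions}
                for t in traces}
            for anaphor, antecedent in full.items():
                if minimal[anaphor] != antecedent:
                    assert rules_used[anaphor] & \
                        {"NUM-AGREE", "SEM-CONS", "DISC-PREF"}

    @pytest.mark.parametrize("pmid, preset, anaphor, antecedent", [
        ("PMID-10358173", "rb-full", "this transcription factor", "IRF-1"),
        ("PMID-10358173", "rb-min+1,3", "this transcription factor", "part"),
        ("PMID-7964516", "rb-full", "its", "c-Myc"),
        ("PMID-7964516", "rb-min+1,3", "its", "apoptosis"),
        ("PMID-10221658", "rb-full", "its", "CIITA"),
        ("PMID-8692924", "rb-full", "its", "BCL6"),
    ])
    def test_discussion_examples(self, examples, pmid, preset, anaphor,
                                 antecedent):
        ex = examples[pmid]
        links = resolve_with_config(ex.document, ex.parses,
                                    PipelineConfig(preset=preset))
        got = {l.anaphor.text: l.antecedent.text for l in links}
        assert got[anaphor] == antecedent
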
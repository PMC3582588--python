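import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from procoref.evaluation import (MentionPartition, anaphor_surface_type,
                                 b_cubed, blanc, ceaf, muc,
                                 score_protein_links,
                                 score_protein_links_by_type)
from procoref.standoff_io import ProteinCorefLink, TextSpan
from tests._oracles import (b_cubed_oracle, blanc_oracle, ceaf_oracle,
                            muc_oracle, set_partitions)


def span(i, text="x"):
    return TextSpan(10 * i, 10 * i + len(text), text)


def plink(i, protein="P1"):
    return ProteinCorefLink(span(i), protein)


class TestProteinLinkScore:
    def test_perfect_response(self):
        gold = [plink(1)]
        assert score_protein_links(gold, gold).f_score == 1.0

    def test_wrong_protein_not_credited(self):
        assert score_protein_links([plink(1, "P10")],
                                   [plink(1, "P4")]).correct == 0

    def test_count_arithmetic(self):
        gold = [plink(1), plink(2), plink(3)]
        response = [plink(1), plink(9)]
        triple = score_protein_links(gold, response)
        assert triple.recall == pytest.approx(1 / 3)
        assert triple.precision == pytest.approx(1 / 2)
        assert triple.f_score == pytest.approx(2 / 5)

    def test_each_gold_link_credited_once(self):
        gold = [plink(1)]
        # two overlapping response anaphors both matching the same gold link
        response = [ProteinCorefLink(TextSpan(10, 12, "xy"), "P1"),
                    ProteinCorefLink(TextSpan(11, 13, "yz"), "P1")]
        triple = score_protein_links(gold, response)
        assert triple.correct == 1 and triple.response_total == 2

    def test_strict_vs_lenient_spans(self):
        gold = [ProteinCorefLink(TextSpan(0, 5, "gappy"), "P1")]
        response = [ProteinCorefLink(TextSpan(2, 5, "ppy"), "P1")]
        assert score_protein_links(gold, response, "lenient").correct == 1
        assert score_protein_links(gold, response, "strict").correct == 0

    def test_by_type_buckets(self):
        gold = [ProteinCorefLink(TextSpan(0, 3, "its"), "P1"),
                ProteinCorefLink(TextSpan(10, 15, "which"), "P2"),
                ProteinCorefLink(TextSpan(20, 31, "the protein"), "P3")]
        table = score_protein_links_by_type(gold, gold)
        for bucket in ("PRON", "DNP", "RELAT", "ALL"):
            assert table[bucket].f_score == 1.0
            assert table[bucket].gold_total == (3 if bucket == "ALL" else 1)

    def test_surface_typing(self):
        assert anaphor_surface_type("its") == "PRON"
        assert anaphor_surface_type("which") == "RELAT"
        assert anaphor_surface_type("this factor") == "DNP"


def P(*chains):
    return MentionPartition.from_chains(chains)


class TestMUC:
    def test_perfect(self):
        key = P("AB", "C")
        assert muc(key, key).f_score == 1.0

    def test_split_chain(self):
        triple = muc(P("ABC"), P("AB", "C"))
        assert triple.recall == pytest.approx(0.5)
        assert triple.precision == pytest.approx(1.0)
        assert triple.f_score == pytest.approx(2 / 3)

    def test_all_singleton_response_zero_recall(self):
        assert muc(P("ABC"), P("A", "B", "C")).recall == 0.0

    def test_all_singleton_key_flagged(self):
        triple = muc(P("A", "B"), P("AB"))
        assert triple.recall == 0.0 and triple.degenerate


class TestBCubed:
    def test_split_chain(self):
        triple = b_cubed(P("ABC"), P("AB", "C"))
        assert triple.recall == pytest.approx(5 / 9)
        assert triple.precision == pytest.approx(1.0)

    def test_empty_mention_set_rejected(self):
        with pytest.raises(ValueError):
            b_cubed(P(), P())


class TestCEAF:
    def test_perfect(self):
        key = P("AB", "CD")
        for variant in ("mention", "entity"):
            assert ceaf(key, key, variant).f_score == 1.0

    def test_mention_variant_symmetric_on_same_universe(self):
        key, resp = P("ABC", "D"), P("AB", "CD")
        triple = ceaf(key, resp, "mention")
        assert triple.recall == pytest.approx(triple.precision)

    def test_unknown_variant(self):
        with pytest.raises(ValueError):
            ceaf(P("AB"), P("AB"), "chain")


class TestBLANC:
    def test_perfect(self):
        key = P("AB", "C")
        assert blanc(key, key).f_score == pytest.approx(1.0)

    def test_merge_all(self):
        triple = blanc(P("AB", "C"), P("ABC"))
        # coref side: R=1, P=1/3; non-coref side: R=0, P undefined -> 0
        assert triple.recall == pytest.approx((1.0 + 0.0) / 2)
        assert triple.precision == pytest.approx((1 / 3 + 0.0) / 2)

    def test_swap_exchanges_precision_and_recall(self):
        key, resp = P("ABC", "D"), P("AB", "CD")
        fwd, rev = blanc(key, resp), blanc(resp, key)
        assert fwd.recall == pytest.approx(rev.precision)
        assert fwd.precision == pytest.approx(rev.recall)

    def test_no_coref_pairs_in_key_flagged(self):
        triple = blanc(P("A", "B"), P("AB"))
        assert triple.degenerate


class TestOracleAgreement:
    """Spot-check scorer/oracle agreement; the exhaustive sweep over all
    partition pairs of <=6 mentions runs in the acceptance suite."""

    @pytest.mark.parametrize("n", [3, 4])
    def test_all_pairs_small(self, n):
        parts = [MentionPartition.from_chains(p)
                 for p in set_partitions(list(range(n)))]
        for key in parts:
            for resp in parts:
                self._check(key, resp)

    def test_random_pairs_n6(self):
        rng = np.random.default_rng(0)
        parts = [MentionPartition.from_chains(p)
                 for p in set_partitions(list(range(6)))]
        for _ in range(60):
            key, resp = (parts[int(rng.integers(len(parts)))] for _ in "kr")
            self._check(key, resp)

    @staticmethod
    def _check(key, resp):
        for impl, oracle in [
                (muc, muc_oracle), (b_cubed, b_cubed_oracle),
                (blanc, blanc_oracle)]:
            got = impl(key, resp)
            r, p, f = oracle(key, resp)
            assert got.recall == pytest.approx(r, abs=1e-9)
            assert got.precision == pytest.approx(p, abs=1e-9)
            assert got.f_score == pytest.approx(f, abs=1e-9)
        for variant in ("mention", "entity"):
            got = ceaf(key, resp, variant)
            r, p, f = ceaf_oracle(key, resp, variant)
            assert got.recall == pytest.approx(r, abs=1e-9)
            assert got.precision == pytest.approx(p, abs=1e-9)
        for scorer in (muc, b_cubed, blanc):
            t = scorer(key, resp)
            assert 0.0 <= t.recall <= 1.0 and 0.0 <= t.precision <= 1.0


@st.composite
def partition_pairs(draw, max_mentions=7):
    """A (key, response) pair of partitions over the same mention set."""
    n = draw(st.integers(min_value=1, max_value=max_mentions))
    def labels():
        return draw(st.lists(st.integers(0, max_mentions),
                             min_size=n, max_size=n))
    def to_partition(lab):
        groups: dict = {}
        for m, l in enumerate(lab):
            groups.setdefault(l, []).append(m)
        return MentionPartition.from_chains(groups.values())
    return to_partition(labels()), to_partition(labels())


@settings(deadline=None, derandomize=True, max_examples=200)
@given(partition_pairs())
def test_scorer_invariants(pair):
    key, resp = pair
    for scorer in (muc, b_cubed, blanc,
                   lambda k, r: ceaf(k, r, "mention"),
                   lambda k, r: ceaf(k, r, "entity")):
        t = scorer(key, resp)
        assert 0.0 <= t.recall <= 1.0
        assert 0.0 <= t.precision <= 1.0
        assert 0.0 <= t.f_score <= 1.0
        perfect = scorer(key, key)
        if not perfect.degenerate:
            assert perfect.f_score == pytest.approx(1.0)
    # same mention universe: CEAF-M recall equals precision
    m = ceaf(key, resp, "mention")
    assert m.recall == pytest.approx(m.precision)
    # swapping key and response swaps precision and recall (for BLANC only
    # when neither direction drops a degenerate side)
    for scorer in (muc, b_cubed, blanc):
        fwd, rev = scorer(key, resp), scorer(resp, key)
        if scorer is blanc and (fwd.degenerate or rev.degenerate):
            continue
        assert fwd.recall == pytest.approx(rev.precision)
        assert fwd.precision == pytest.approx(rev.recall)


def test_muc_harshest_b3_most_lenient_on_near_miss():
    """Documented tendency on a response that recovers few links of many
    short chains: MUC penalizes hardest, B³ is most lenient."""
    key = P("AB", "CD", "EF", "GH")
    resp = P("AB", "C", "D", "E", "F", "G", "H")
    assert muc(key, resp).f_score < blanc(key, resp).f_score
    assert blanc(key, resp).f_score < b_cubed(key, resp).f_score
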
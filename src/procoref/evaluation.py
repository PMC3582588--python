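"""Coreference evaluation.

The primary metric is protein-link based: a response link is correct when
it pairs the right anaphor with the right antecedent protein, each gold
link creditable at most once (maximum bipartite matching).  Anaphor spans
match exactly in strict mode or by overlap in lenient mode (default, the
usual boundary leniency of shared-task scoring).

For comparison, the five standard partition-based coreference scorers are
implemented over mention partitions: MUC (link-based), B³ (per-mention),
CEAF-M and CEAF-E (optimal one-to-one chain alignment via the Kuhn-Munkres
algorithm), and BLANC (Rand-index style, averaging coreferent and
non-coreferent pair scores).

Dialect choices (documented, switchable where sensible): key singletons
participate in B³/CEAF/BLANC but contribute nothing to MUC denominators;
mentions absent from the other side earn no credit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .standoff_io import ProteinCorefLink

__all__ = [
    "ScoreTriple",
    "MentionPartition",
    "score_protein_links",
    "score_protein_links_by_type",
    "muc",
    "b_cubed",
    "ceaf",
    "blanc",
    "anaphor_surface_type",
]


@dataclass(frozen=True)
class ScoreTriple:
    recall: float
    precision: float
    f_score: float
    gold_total: int = 0
    response_total: int = 0
    correct: float = 0.0
    degenerate: bool = False

    @classmethod
    def from_counts(cls, correct: float, gold_total: float,
                    response_total: float, degenerate: bool = False
                    ) -> "ScoreTriple":
        r = correct / gold_total if gold_total else 0.0
        p = correct / response_total if response_total else 0.0
        f = 2 * p * r / (p + r) if (p + r) else 0.0
        return cls(r, p, f, int(gold_total), int(response_total), correct,
                   degenerate)

    def as_percent(self) -> tuple[float, float, float]:
        return (100 * self.recall, 100 * self.precision, 100 * self.f_score)


# ---------------------------------------------------------------------------
# Protein coreference links (the task's primary metric)

def _links_match(gold: ProteinCorefLink, response: ProteinCorefLink,
                 match_mode: str) -> bool:
    if gold.protein_id != response.protein_id:
        return False
    if match_mode == "strict":
        return gold.anaphor == response.anaphor
    if match_mode == "lenient":
        return gold.anaphor.overlaps(response.anaphor)
    raise ValueError(f"unknown match_mode {match_mode!r}")


def score_protein_links(gold: Sequence[ProteinCorefLink],
                        response: Sequence[ProteinCorefLink],
                        match_mode: str = "lenient") -> ScoreTriple:
    """Recall/precision/F over protein coreference links.

    ``correct`` is the size of a maximum bipartite matching between gold
    and response under the match relation, so each gold link is credited
    at most once even when several response links overlap it.
    """
    gold = list(dict.fromkeys(gold))
    response = list(dict.fromkeys(response))
    if not gold or not response:
        return ScoreTriple.from_counts(0, len(gold), len(response))
    weight = np.zeros((len(gold), len(response)))
    for i, g in enumerate(gold):
        for j, r in enumerate(response):
            if _links_match(g, r, match_mode):
                weight[i, j] = 1.0
    rows, cols = linear_sum_assignment(weight, maximize=True)
    correct = int(weight[rows, cols].sum())
    return ScoreTriple.from_counts(correct, len(gold), len(response))


_PRONOUN_SURFACES = {"it", "its", "itself", "they", "their", "them",
                     "themselves", "this", "that", "these", "those",
                     "both", "either"}
_RELATIVE_SURFACES = {"which", "who", "whom"}


def anaphor_surface_type(surface: str) -> str:
    """PRON / RELAT / DNP bucket of an anaphor span for reporting.

    Surface-based (no parse needed for gold links); bare "that" counts as
    relative only when the report has no other evidence, so it is bucketed
    with the pronouns here.
    """
    w = surface.strip().lower()
    if w in _RELATIVE_SURFACES:
        return "RELAT"
    if w in _PRONOUN_SURFACES:
        return "PRON"
    return "DNP"


def score_protein_links_by_type(gold: Sequence[ProteinCorefLink],
                                response: Sequence[ProteinCorefLink],
                                match_mode: str = "lenient"
                                ) -> dict[str, ScoreTriple]:
    """Per-anaphor-type breakdown (PRON / DNP / RELAT) plus ALL."""
    out: dict[str, ScoreTriple] = {}
    for bucket in ("PRON", "DNP", "RELAT"):
        g = [l for l in gold if anaphor_surface_type(l.anaphor.text) == bucket]
        r = [l for l in response
             if anaphor_surface_type(l.anaphor.text) == bucket]
        out[bucket] = score_protein_links(g, r, match_mode)
    out["ALL"] = score_protein_links(gold, response, match_mode)
    return out


# ---------------------------------------------------------------------------
# Mention partitions and the five standard scorers

@dataclass(frozen=True)
class MentionPartition:
    mentions: frozenset
    chains: tuple[frozenset, ...]

    def __post_init__(self):
        union: set = set()
        total = 0
        for chain in self.chains:
            union |= chain
            total += len(chain)
        if union != set(self.mentions) or total != len(self.mentions):
            raise ValueError("chains must partition the mention set")

    @classmethod
    def from_chains(cls, chains: Iterable[Iterable[Hashable]]
                    ) -> "MentionPartition":
        frozen = tuple(frozenset(c) for c in chains if c)
        mentions = frozenset(itertools.chain.from_iterable(frozen))
        return cls(mentions, frozen)

    @classmethod
    def from_links(cls, links: Iterable[tuple[Hashable, Hashable]],
                   mentions: Iterable[Hashable] = ()) -> "MentionPartition":
        """Build the partition induced by coreference links (union-find);
        extra ``mentions`` become singletons."""
        parent: dict = {}

        def find(x):
            parent.setdefault(x, x)
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a, b in links:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
        for m in mentions:
            find(m)
        groups: dict = {}
        for m in parent:
            groups.setdefault(find(m), set()).add(m)
        return cls.from_chains(groups.values())

    def chain_of(self, mention) -> frozenset:
        for chain in self.chains:
            if mention in chain:
                return chain
        return frozenset()


def _muc_side(numer_partition: MentionPartition,
              denom_chains: Sequence[frozenset]) -> tuple[float, float]:
    """Σ(|S| - |p(S)|) and Σ(|S| - 1) over chains S of one side."""
    num = 0.0
    den = 0.0
    for chain in denom_chains:
        # pieces the chain splits into under the other partition; mentions
        # absent from the other side each form their own piece
        pieces = set()
        absent = 0
        for m in chain:
            other = numer_partition.chain_of(m)
            if other:
                pieces.add(other)
            else:
                absent += 1
        num += len(chain) - (len(pieces) + absent)
        den += len(chain) - 1
    return num, den


def muc(key: MentionPartition, response: MentionPartition) -> ScoreTriple:
    """Link-based MUC score.

    Recall counts, per key chain, the links the response preserves
    (chain size minus the number of response pieces the chain splits
    into); precision is the symmetric count over response chains.
    Singleton chains carry no links and drop out of both denominators; an
    all-singleton key leaves recall undefined, reported as 0 and flagged.
    """
    r_num, r_den = _muc_side(response, key.chains)
    p_num, p_den = _muc_side(key, response.chains)
    degenerate = r_den == 0 or p_den == 0
    r = r_num / r_den if r_den else 0.0
    p = p_num / p_den if p_den else 0.0
    f = 2 * p * r / (p + r) if (p + r) else 0.0
    return ScoreTriple(r, p, f, int(r_den), int(p_den), r_num, degenerate)


def b_cubed(key: MentionPartition, response: MentionPartition) -> ScoreTriple:
    """B³: per-mention precision/recall averaged uniformly over mentions."""
    if not key.mentions and not response.mentions:
        raise ValueError("b_cubed requires a non-empty mention set")
    recalls = []
    for m in key.mentions:
        k, r = key.chain_of(m), response.chain_of(m)
        recalls.append(len(k & r) / len(k))
    precisions = []
    for m in response.mentions:
        k, r = key.chain_of(m), response.chain_of(m)
        precisions.append(len(k & r) / len(r))
    rec = sum(recalls) / len(recalls) if recalls else 0.0
    prec = sum(precisions) / len(precisions) if precisions else 0.0
    f = 2 * prec * rec / (prec + rec) if (prec + rec) else 0.0
    return ScoreTriple(rec, prec, f, len(recalls), len(precisions),
                       sum(recalls))


def _phi(k: frozenset, r: frozenset, variant: str) -> float:
    inter = len(k & r)
    if variant == "mention":
        return float(inter)
    if variant == "entity":
        return 2.0 * inter / (len(k) + len(r)) if (k or r) else 0.0
    raise ValueError(f"unknown CEAF variant {variant!r}")


def ceaf(key: MentionPartition, response: MentionPartition,
         variant: str = "mention") -> ScoreTriple:
    """CEAF: optimal one-to-one chain alignment maximizing total similarity.

    ``variant="mention"`` uses φ(K,R)=|K∩R| (CEAF-M); ``variant="entity"``
    uses φ4(K,R)=2|K∩R|/(|K|+|R|) (CEAF-E).  The alignment is the
    Kuhn-Munkres assignment over the chain-similarity matrix.
    """
    kc, rc = key.chains, response.chains
    total = 0.0
    if kc and rc:
        sim = np.zeros((len(kc), len(rc)))
        for i, k in enumerate(kc):
            for j, r in enumerate(rc):
                sim[i, j] = _phi(k, r, variant)
        rows, cols = linear_sum_assignment(sim, maximize=True)
        total = float(sim[rows, cols].sum())
    r_den = sum(_phi(k, k, variant) for k in kc)
    p_den = sum(_phi(r, r, variant) for r in rc)
    return ScoreTriple.from_counts(total, r_den, p_den)


def _coref_pair_counts(key: MentionPartition, response: MentionPartition
                       ) -> tuple[float, float, float, float]:
    """(|C_k|, |C_r|, |C_k ∩ C_r|, total pairs over the mention universe)."""
    def n_pairs(n: int) -> float:
        return n * (n - 1) / 2

    ck = sum(n_pairs(len(c)) for c in key.chains)
    cr = sum(n_pairs(len(c)) for c in response.chains)
    both = sum(n_pairs(len(k & r))
               for k in key.chains for r in response.chains)
    universe = len(key.mentions | response.mentions)
    return ck, cr, both, n_pairs(universe)


def blanc(key: MentionPartition, response: MentionPartition) -> ScoreTriple:
    """BLANC: Rand-index style average over coreferent and non-coreferent
    mention pairs.

    Each side (coref / non-coref) gets its own R/P/F; BLANC R, P and F are
    the arithmetic means over the sides the key defines.  A side with no
    key pairs is left out (degenerate, flagged); a response side with no
    pairs scores precision 0.
    """
    ck, cr, both_c, total = _coref_pair_counts(key, response)
    nk = total - ck
    nr = total - cr
    both_n = total - ck - cr + both_c

    sides = []
    degenerate = False
    for key_pairs, resp_pairs, agree in ((ck, cr, both_c), (nk, nr, both_n)):
        if key_pairs == 0:
            degenerate = True
            continue
        r = agree / key_pairs
        p = agree / resp_pairs if resp_pairs else 0.0
        f = 2 * p * r / (p + r) if (p + r) else 0.0
        sides.append((r, p, f))
    if not sides:
        return ScoreTriple(0.0, 0.0, 0.0, 0, 0, 0.0, True)
    rec = sum(s[0] for s in sides) / len(sides)
    prec = sum(s[1] for s in sides) / len(sides)
    f = sum(s[2] for s in sides) / len(sides)
    return ScoreTriple(rec, prec, f, int(ck + nk), int(cr + nr), both_c,
                       degenerate)
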
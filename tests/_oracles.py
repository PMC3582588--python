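"""Independent brute-force reference implementations of the coreference
scorers, used only to cross-check the package's scorers.

Deliberately different computational routes:

* MUC    — explicit link graphs and DFS connected components;
* B³     — pairwise same-chain identity counting per mention;
* CEAF   — exhaustive search over all injective chain mappings;
* BLANC  — explicit enumeration of every unordered mention pair.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Iterator

from procoref.evaluation import MentionPartition


def _f(p: float, r: float) -> float:
    return 2 * p * r / (p + r) if (p + r) else 0.0


def _components(members: Iterable, partition: MentionPartition) -> int:
    """Connected components of the graph on ``members`` whose edges join
    mentions sharing a chain in ``partition`` (DFS)."""
    members = list(members)
    chain_of = {}
    for m in members:
        chain_of[m] = None
        for chain in partition.chains:
            if m in chain:
                chain_of[m] = chain
                break
    seen: set = set()
    comps = 0
    for start in members:
        if start in seen:
            continue
        comps += 1
        stack = [start]
        while stack:
            m = stack.pop()
            if m in seen:
                continue
            seen.add(m)
            for other in members:
                if other not in seen and chain_of[m] is not None \
                        and chain_of[other] is chain_of[m]:
                    stack.append(other)
    return comps


def muc_oracle(key: MentionPartition, response: MentionPartition):
    def side(chains, other):
        num = sum(len(c) - _components(c, other) for c in chains)
        den = sum(len(c) - 1 for c in chains)
        return num, den

    rn, rd = side(key.chains, response)
    pn, pd = side(response.chains, key)
    r = rn / rd if rd else 0.0
    p = pn / pd if pd else 0.0
    return r, p, _f(p, r)


def b_cubed_oracle(key: MentionPartition, response: MentionPartition):
    def chain_mate(partition, a, b):
        return any(a in c and b in c for c in partition.chains)

    recalls = []
    for m in key.mentions:
        key_mates = [x for x in key.mentions if chain_mate(key, m, x)]
        agree = sum(1 for x in key_mates if chain_mate(response, m, x))
        recalls.append(agree / len(key_mates))
    precisions = []
    for m in response.mentions:
        resp_mates = [x for x in response.mentions if chain_mate(response, m, x)]
        agree = sum(1 for x in resp_mates if chain_mate(key, m, x))
        precisions.append(agree / len(resp_mates))
    r = sum(recalls) / len(recalls) if recalls else 0.0
    p = sum(precisions) / len(precisions) if precisions else 0.0
    return r, p, _f(p, r)


def ceaf_oracle(key: MentionPartition, response: MentionPartition,
                variant: str):
    def phi(k, r):
        inter = len(k & r)
        if variant == "mention":
            return float(inter)
        return 2.0 * inter / (len(k) + len(r))

    kc, rc = list(key.chains), list(response.chains)
    best = 0.0
    if kc and rc:
        small, large, flipped = (kc, rc, False) if len(kc) <= len(rc) \
            else (rc, kc, True)
        for mapping in itertools.permutations(large, len(small)):
            total = sum(phi(b, a) if flipped else phi(a, b)
                        for a, b in zip(small, mapping))
            best = max(best, total)
    r_den = sum(phi(c, c) for c in kc)
    p_den = sum(phi(c, c) for c in rc)
    r = best / r_den if r_den else 0.0
    p = best / p_den if p_den else 0.0
    return r, p, _f(p, r)


def blanc_oracle(key: MentionPartition, response: MentionPartition):
    universe = sorted(key.mentions | response.mentions)
    coref_k, coref_r = set(), set()
    noncoref_k, noncoref_r = set(), set()
    for a, b in itertools.combinations(universe, 2):
        pair = (a, b)
        (coref_k if any(a in c and b in c for c in key.chains)
         else noncoref_k).add(pair)
        (coref_r if any(a in c and b in c for c in response.chains)
         else noncoref_r).add(pair)
    sides = []
    for kp, rp in ((coref_k, coref_r), (noncoref_k, noncoref_r)):
        if not kp:
            continue
        agree = len(kp & rp)
        r = agree / len(kp)
        p = agree / len(rp) if rp else 0.0
        sides.append((r, p, _f(p, r)))
    if not sides:
        return 0.0, 0.0, 0.0
    n = len(sides)
    return (sum(s[0] for s in sides) / n, sum(s[1] for s in sides) / n,
            sum(s[2] for s in sides) / n)


def set_partitions(items: list) -> Iterator[list[list]]:
    """All set partitions of ``items`` (restricted-growth enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partial in set_partitions(rest):
        for i in range(len(partial)):
            yield partial[:i] + [[first] + partial[i]] + partial[i + 1:]
        yield [[first]] + partial


def all_partition_pairs(n: int):
    """All (key, response) partition pairs over mentions 0..n-1."""
    items = list(range(n))
    parts = [MentionPartition.from_chains(p) for p in set_partitions(items)]
    for key in parts:
        for response in parts:
            yield key, response
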
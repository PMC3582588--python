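# Methods

## Task and model

The resolver targets anaphoric coreference to proteins in biomedical
text: given a document with gold protein mentions (standoff `.a1`
terms), link each anaphoric expression — a pronoun or definite noun
phrase — to a preceding expression, and derive from each link the
*antecedent proteins* it transmits (every protein mention contained in
the antecedent expression). Cataphora, appositions, indefinite-NP and
proper-name anaphors, and sentential antecedents are out of scope: the
rules neither select such anaphors nor propose such antecedents (a
demonstrative pronoun with a sentential antecedent may still pass
anaphor selection, but its resolved antecedent then contains no protein
and the protein-link metric ignores it).

Resolution is deterministic and purely rule-based. For relative
pronouns, the parser's relative-clause attachment is the antecedent — a
deliberate wholesale trust in the parse; when the parser found no
attachment the anaphor is left unresolved. All other anaphors are
resolved over a filtered candidate list by an ordered pairwise decision
list: number agreement, protein semantic constraint, discourse (far)
preference, then default closeness. A rule decides a pairwise comparison
only when exactly one candidate satisfies its condition; the default
rule cannot tie, so a nearest-first incumbent/challenger tournament
yields a unique antecedent. The tournament equals an exhaustive
comparison sort whenever the induced relation is transitive on the
instance (asserted on all packaged fixtures); in intransitive corner
cases the tournament's nearest-first visit order is the defined
semantics.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `window` | 2 sentences | candidates come from the anaphor's sentence and the two before it; in the training data of the original task ~97% of protein links fall inside this window, and wider windows only add distractors |
| `protein_keywords` | 12 nouns (binding, expression, interaction, regulation, phosphatase activity, localization, gene, sequence, region, phosphorylation, transactivation, transcription) | PRO-ANA-SEM: a possessive whose context NP contains one of these is a protein reference |
| `protein_headwords` | 8 nouns (protein, gene, factor, molecule, element, family, inhibitor, receptor) | DEFNP-ANA-SEM: definite NPs with other head words are dropped as anaphors. The source analysis announces "top seven" head words but enumerates eight; all eight ship |
| `filtered_dependency_labels` | `prep-arg12`, `poss-arg12` | argument pairs of these relations cannot corefer |
| `pronoun_families` | {it, its, itself}, {they, their, them, themselves}, {this, that, these, those} | candidate pronouns outside the anaphor's family are dropped; only the *it* family is canonical, the others are a conservative extension and configurable |
| `disc_pref_map` | far for personal and demonstrative pronouns, near otherwise | which anaphor types invert the closeness default under rule 3; exposed in configuration because no authoritative enumeration exists — the rule is known to help pronoun-type anaphors, so those get far preference |
| `match_mode` | lenient | protein-link scoring accepts overlapping anaphor spans; `strict` requires equality |

Presets `rb-min`, `rb-min+1`, `rb-min+2`, `rb-min+3`, `rb-min+1,3`,
`rb-full` toggle rules 1–3; the anaphor-selection filter ablations
(without PRO-ANA-SEM and/or DEFNP-ANA-SEM) are a separate switch.

## Design choices where the design was open

* **Definite NPs containing a gold protein mention are not anaphors.**
  They are direct protein references ("the c-Myc protein"); treating
  them as anaphors would both contradict the worked workflow example and
  flood the response with spurious links. They remain candidates.
* **Number semantics**: `unknown` number never conflicts (real data
  violates agreement often enough that a hard constraint would hurt
  recall); coordinated NPs are plural.
* **Rule 2 abstains entirely** (for both candidates) when the anaphor is
  not a protein reference, rather than preferring non-protein
  candidates.
* **The default rule is fixed to closer-preference**; the alternative
  reading in which the default itself flips with anaphor type is
  subsumed by `disc_pref_map`.
* **Pleonastic patterns** are matched over lemmas and POS with optional
  slots bounded at 3 tokens (the pattern definitions give no gap
  bounds).
* **Pronoun candidates in practice**: every pronoun is either selected
  as an anaphor or filtered as non-referential/non-protein, and both
  groups are excluded from candidate sets, so the pronoun-family filter
  acts as a defensive layer for non-default selection configurations.
* **Ties in head-word deduplication** (equal-length chunks) go to the
  earlier chunk; any stable rule would do, stability is the point.
* **Offsets** are 0-based half-open over the UTF-8 decoded text, the
  usual standoff convention.
* **Multi-protein antecedents** emit one protein link per contained
  mention, preserving recall under the matching-based scorer.

## Syntax backends

The rules need only tokens + POS + lemmas, NP chunks with heads, a
subordinate-clause flag, and three dependency families. Tests use
hand-written gold-parse fixtures exclusively (line-delimited JSON, one
validated record per sentence). A small heuristic backend ("simple":
regex tokenizer, lexicon/suffix tagger, greedy NP chunking, `X of Y` and
`NP , which` edges) is bundled for plain-text convenience; it is not a
wide-coverage parser and its parse errors propagate to resolution
exactly as real parser errors would (one packaged fixture deliberately
reproduces a coordination parse failure and the spurious antecedent it
causes). A sentence a backend fails on is marked unparsed and
contributes nothing.

## Scorers

`score_protein_links` credits each gold link at most once via maximum
bipartite matching (Kuhn–Munkres through
`scipy.optimize.linear_sum_assignment`, also used for the CEAF
alignment). The partition scorers use the standard definitions; dialect
choices are: key singletons participate in B³/CEAF/BLANC and vanish from
MUC denominators; mentions absent from the other partition earn no
credit; BLANC averages the coreferent and non-coreferent pair sides,
drops a side with no key pairs (flagged `degenerate`), and scores an
empty response side as precision 0. The test suite checks all five
scorers against independent brute-force oracles (explicit link graphs,
per-mention loops, exhaustive chain bijections, full pair enumeration)
on every key/response partition pair over up to six mentions, to 1e-9.
No byte-for-byte agreement with any particular reference scorer
release is claimed — definitional agreement is.

## Synthetic corpus: what it emulates, and what it does not

`generate_corpus` builds documents from schematic sentence templates
that carry their own correct parses. Controlled properties:

* anaphor-type mix following the training-data distribution over the six
  generated types (possessive 25.3 : relative 18.6 : demonstrative NP
  15.2 : demonstrative pronoun 13.6 : the-definite NP 10.9 : personal
  9.6, renormalized);
* antecedent distance distribution 0.62/0.28/0.07/0.03 over 0–3
  sentences, placing ≥97% of links within the window (relatives are
  always same-sentence);
* protein key-word cues in possessive context NPs at rate 0.9, so
  PRO-ANA-SEM has both hits and misses;
* planted distractors: with probability 0.6 a nearer non-protein
  candidate that only the semantic rule overcomes, with probability 0.25
  a number-conflicting distractor that rule 1 removes, else an easy
  block; personal/demonstrative-pronoun blocks place the true antecedent
  farthest so the discourse rule is what fixes them;
* occasional context sentences with unrelated proteins (rate 0.15).

One document carries one anaphor block (default 120 documents per
corpus); each template was chosen once, as the simplest English-like
construction exercising the targeted rule. The generator is *idealized*:
parses are perfect, cue words are unambiguous, wrong answers rarely
contain proteins (so precision sits near 100%), and there is no
annotation noise. Passing the ordering property
F(rb-full) ≥ F(rb-min+1,3) ≥ F(rb-min) on this corpus therefore shows
that the implementation exploits each signal as designed — not that the
absolute F-scores transfer to real corpora, where parse errors, number
violations and non-anaphoric definites dominate the error budget.

## Problem sizes

The test suite and `scripts/acceptance.py` use 120–200 generated
documents per corpus property, 1000 documents for the type-mix check,
800 for the window statistic, and the full partition enumeration up to
n = 6 mentions (tests) / n = 5 (acceptance script); these sizes give
stable statistics for every property checked while keeping runs
interactive.

## Known limitations

* Anaphor types without selection rules (appositions, indefinite NPs,
  proper-name anaphora; ~5% of real anaphors) are never proposed.
* Number-agreement violations in real text ("protein fractions … it")
  defeat rule 1 by design; the corresponding fixture documents the
  failure.
* Relative-pronoun resolution is exactly as good as the parse.
* The head-word and key-word lexicons are small hand lists; automatic
  acquisition from a term corpus is not implemented.
* Chains are not propagated: each anaphor is resolved independently, and
  predicted links do not update candidate semantics.
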
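"""Top-level pipeline: configuration, directory processing, reporting.

Ties resolution, evaluation and simulation together behind one declarative
configuration object.  The ablation presets instantiate the rule
combinations used when measuring each preference rule's contribution
(``rb-min`` … ``rb-full``), plus the anaphor-selection filter ablations
(``rb-full`` without PRO-ANA-SEM and/or DEFNP-ANA-SEM).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import yaml

from .anaphor_selection import AnaphorSelectionConfig
from .antecedent_candidates import CandidateConfig
from .antecedent_prediction import (PredictionTrace, RuleConfig,
                                    resolve_document)
from .evaluation import (MentionPartition, ScoreTriple, b_cubed, blanc, ceaf,
                         muc, score_protein_links, score_protein_links_by_type)
from .semantic_classification import SemanticLexicons
from .standoff_io import (CoreferenceLink, Document, derive_protein_links,
                          read_standoff, write_predictions)
from .syntax_adapter import ParsedSentence, load_gold_parse, parse_document

__all__ = [
    "PipelineConfig",
    "FILTER_ABLATIONS",
    "resolve_with_config",
    "corpus_protein_score",
    "corpus_protein_score_by_type",
    "ablation_table",
    "partition_scores",
    "run",
]

logger = logging.getLogger(__name__)

# anaphor-selection filter ablations, by preset suffix
FILTER_ABLATIONS: Mapping[str, AnaphorSelectionConfig] = {
    "": AnaphorSelectionConfig(),
    "w/o-pro-ana-sem": AnaphorSelectionConfig(enable_pro_ana_sem_filter=False),
    "w/o-defnp-ana-sem": AnaphorSelectionConfig(
        enable_defnp_ana_sem_filter=False),
    "w/o-both-sem": AnaphorSelectionConfig(
        enable_pro_ana_sem_filter=False, enable_defnp_ana_sem_filter=False),
}


@dataclass(frozen=True)
class PipelineConfig:
    preset: str = "rb-full"
    window: int = 2
    filter_ablation: str = ""          # key into FILTER_ABLATIONS
    match_mode: str = "lenient"
    backend: Optional[str] = None      # parser backend; None = fixtures only
    lexicons: SemanticLexicons = field(default_factory=SemanticLexicons)
    hard_semantic_candidate_filter: bool = False
    keep_going: bool = False
    log_level: str = "WARNING"

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if "lexicons" in data:
            data["lexicons"] = SemanticLexicons.from_dict(data.pop("lexicons"))
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def rule_config(self) -> RuleConfig:
        return dataclasses.replace(RuleConfig.preset(self.preset),
                                   window_size=self.window)

    def selection_config(self) -> AnaphorSelectionConfig:
        return FILTER_ABLATIONS[self.filter_ablation]

    def candidate_config(self) -> CandidateConfig:
        return CandidateConfig(
            lexicons=self.lexicons,
            hard_semantic_candidate_filter=self.hard_semantic_candidate_filter)


def resolve_with_config(document: Document,
                        parses: Sequence[ParsedSentence],
                        config: PipelineConfig = PipelineConfig(),
                        traces: Optional[list[PredictionTrace]] = None
                        ) -> list[CoreferenceLink]:
    return resolve_document(document, parses,
                            config=config.rule_config(),
                            lexicons=config.lexicons,
                            selection_config=config.selection_config(),
                            candidate_config=config.candidate_config(),
                            traces=traces)


# ---------------------------------------------------------------------------
# Corpus-level scoring

class _Accumulator:
    def __init__(self):
        self.correct = 0.0
        self.gold = 0
        self.response = 0

    def add(self, triple: ScoreTriple) -> None:
        self.correct += triple.correct
        self.gold += triple.gold_total
        self.response += triple.response_total

    def triple(self) -> ScoreTriple:
        return ScoreTriple.from_counts(self.correct, self.gold, self.response)


def corpus_protein_score(pairs: Iterable[tuple[Document,
                                               Sequence[ParsedSentence]]],
                         config: PipelineConfig = PipelineConfig()
                         ) -> ScoreTriple:
    """Micro-averaged protein-link score of a configuration on a corpus:
    per-document matching, counts pooled across documents."""
    acc = _Accumulator()
    for doc, parses in pairs:
        gold = derive_protein_links(doc.gold_links, doc.proteins)
        response = derive_protein_links(
            resolve_with_config(doc, parses, config), doc.proteins)
        acc.add(score_protein_links(gold, response, config.match_mode))
    return acc.triple()


def corpus_protein_score_by_type(pairs, config: PipelineConfig = PipelineConfig()
                                 ) -> dict[str, ScoreTriple]:
    accs = {k: _Accumulator() for k in ("PRON", "DNP", "RELAT", "ALL")}
    for doc, parses in pairs:
        gold = derive_protein_links(doc.gold_links, doc.proteins)
        response = derive_protein_links(
            resolve_with_config(doc, parses, config), doc.proteins)
        for bucket, triple in score_protein_links_by_type(
                gold, response, config.match_mode).items():
            accs[bucket].add(triple)
    return {k: a.triple() for k, a in accs.items()}


def ablation_table(pairs: Sequence[tuple[Document, Sequence[ParsedSentence]]],
                   presets: Sequence[str] = ("rb-min", "rb-min+1", "rb-min+2",
                                             "rb-min+3", "rb-min+1,3",
                                             "rb-full"),
                   base_config: PipelineConfig = PipelineConfig()
                   ) -> dict[str, ScoreTriple]:
    """Protein-link R/P/F of each rule preset on the same corpus."""
    table = {}
    for preset in presets:
        cfg = dataclasses.replace(base_config, preset=preset)
        table[preset] = corpus_protein_score(pairs, cfg)
    return table


def partition_scores(gold_docs: Sequence[Document],
                     response_links: Mapping[str, Sequence[CoreferenceLink]]
                     ) -> dict[str, ScoreTriple]:
    """MUC / B³ / CEAF-M / CEAF-E / BLANC over document-scoped partitions.

    Mentions are (doc_id, start, end) triples; chains are the transitive
    closures of the expression links; response-only mentions enter the
    response partition as the links dictate.
    """
    key_links, resp_links, mentions = [], [], set()
    for doc in gold_docs:
        for link in doc.gold_links:
            a = (doc.doc_id, link.anaphor.start, link.anaphor.end)
            b = (doc.doc_id, link.antecedent.start, link.antecedent.end)
            key_links.append((a, b))
            mentions.update((a, b))
        for link in response_links.get(doc.doc_id, ()):
            a = (doc.doc_id, link.anaphor.start, link.anaphor.end)
            b = (doc.doc_id, link.antecedent.start, link.antecedent.end)
            resp_links.append((a, b))
            mentions.update((a, b))
    key = MentionPartition.from_links(key_links, mentions)
    response = MentionPartition.from_links(resp_links, mentions)
    return {
        "muc": muc(key, response),
        "b3": b_cubed(key, response),
        "ceaf-m": ceaf(key, response, "mention"),
        "ceaf-e": ceaf(key, response, "entity"),
        "blanc": blanc(key, response),
    }


# ---------------------------------------------------------------------------
# Directory-level run

def _load_document(txt_path: Path, with_gold: bool
                   ) -> tuple[Document, Optional[Path]]:
    a1 = txt_path.with_suffix(".a1")
    a2 = txt_path.with_suffix(".a2")
    doc = read_standoff(txt_path, a1, a2 if with_gold and a2.exists() else None)
    parse = txt_path.with_suffix(".parse.jsonl")
    return doc, parse if parse.exists() else None


def run(config: PipelineConfig, input_dir, output_dir) -> dict:
    """Resolve every document triple in ``input_dir``; write one .a2 per
    document into ``output_dir``; score against gold when gold .a2 files
    are present.  Returns a report dict; raises on the first document
    error unless ``config.keep_going``."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(),
                                      logging.WARNING))
    input_dir, output_dir = Path(input_dir), Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)

    scored_pairs = []
    errors: list[str] = []
    n_docs = 0
    for txt_path in sorted(input_dir.glob("*.txt")):
        try:
            doc, parse_path = _load_document(txt_path, with_gold=True)
            if parse_path is not None:
                parses = load_gold_parse(parse_path)
            elif config.backend is not None:
                parses = parse_document(doc, config.backend)
            else:
                raise FileNotFoundError(
                    f"no parse fixture {txt_path.stem}.parse.jsonl and no "
                    "--backend given; supply one of the two")
            links = resolve_with_config(doc, parses, config)
            write_predictions(doc, links, output_dir / f"{txt_path.stem}.a2")
            n_docs += 1
            if doc.gold_links:
                scored_pairs.append((doc, parses))
        except Exception as exc:
            if not config.keep_going:
                raise
            errors.append(f"{txt_path.name}: {exc}")
            logger.error("%s: %s", txt_path.name, exc)

    report: dict = {"documents": n_docs, "errors": errors}
    if scored_pairs:
        report["scores"] = corpus_protein_score_by_type(scored_pairs, config)
        report["ablation"] = ablation_table(scored_pairs,
                                            base_config=config)
    return report


def format_report(report: dict) -> str:
    lines = [f"documents resolved: {report['documents']}"]
    if report.get("errors"):
        lines.append(f"errors: {len(report['errors'])}")
    if "scores" in report:
        lines.append("")
        lines.append(f"{'type':<8}{'R':>8}{'P':>8}{'F':>8}")
        for bucket in ("PRON", "DNP", "RELAT", "ALL"):
            r, p, f = report["scores"][bucket].as_percent()
            lines.append(f"{bucket:<8}{r:>8.1f}{p:>8.1f}{f:>8.1f}")
    if "ablation" in report:
        lines.append("")
        lines.append(f"{'preset':<12}{'R':>8}{'P':>8}{'F':>8}")
        for preset, triple in report["ablation"].items():
            r, p, f = triple.as_percent()
            lines.append(f"{preset:<12}{r:>8.1f}{p:>8.1f}{f:>8.1f}")
    return "\n".join(lines)
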
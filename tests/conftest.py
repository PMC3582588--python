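import pytest

from procoref.anaphor_selection import select_anaphors
from procoref.antecedent_prediction import classify_markables
from procoref.markable_detection import detect_markables
from procoref.synthetic_fixtures import (GeneratorConfig, generate_corpus,
                                         packaged_examples)


@pytest.fixture(scope="session")
def examples():
    """Packaged worked-example documents, by PMID name."""
    return {ex.name: ex for ex in packaged_examples()}


@pytest.fixture(scope="session")
def table2(examples):
    """The three-sentence workflow example document."""
    return examples["PMID-7964516"]


@pytest.fixture(scope="session")
def small_corpus():
    return generate_corpus(GeneratorConfig(n_documents=40, seed=7))


def pipeline_state(example):
    """(classified markables, selected anaphors) of a packaged example."""
    markables = classify_markables(detect_markables(example.parses),
                                   example.document, example.parses)
    anaphors = select_anaphors(markables, example.parses,
                               proteins=example.document.proteins)
    return markables, anaphors


@pytest.fixture(scope="session")
def table2_state(table2):
    return pipeline_state(table2)
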
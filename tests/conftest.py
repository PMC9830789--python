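import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from clinneg.corpus import (
    AnnotatedDocument,
    EntityAnnotation,
    NegationLabel,
    RecordCategory,
)
from clinneg.rules import TriggerCategory, TriggerEntry, TriggerLexicon, compile_lexicon


@pytest.fixture(scope="session")
def default_lexicon() -> TriggerLexicon:
    return TriggerLexicon.default()


@pytest.fixture
def english_lexicon() -> TriggerLexicon:
    return compile_lexicon(
        [
            TriggerEntry("no signs of", TriggerCategory.NEGATION_FORWARD),
            TriggerEntry("but", TriggerCategory.TERMINATION),
        ]
    )


@pytest.fixture
def tiny_corpus() -> list[AnnotatedDocument]:
    doc1 = AnnotatedDocument(
        doc_id="d1",
        text="geen flebargie vandaag. controle over een week.",
        category=RecordCategory.GENERAL_PRACTITIONER,
        entities=(
            EntityAnnotation(5, 14, "flebargie", gold_label=NegationLabel.NEGATED),
        ),
    )
    doc2 = AnnotatedDocument(
        doc_id="d2",
        text="milde velatose bij controle.",
        category=RecordCategory.RADIOLOGY_REPORT,
        entities=(
            EntityAnnotation(6, 14, "velatose", gold_label=NegationLabel.NOT_NEGATED),
        ),
    )
    return [doc1, doc2]


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240905)
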
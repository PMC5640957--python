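"""Shared fixtures: small hand-built dictionaries and corpora.

Everything is generated in memory or in tmp_path; no data files ship
with the package.
"""

from __future__ import annotations

import numpy as np
import pytest

from bionorm.corpus import Document, EntityType, Mention
from bionorm.dictionary import Concept, DictionarySource, EntityDictionary
from bionorm.embedding import VectorSet
from bionorm.simulate import FixtureSpec


@pytest.fixture
def c7_dictionary() -> EntityDictionary:
    """A two-concept disease dictionary around complement component 7
    deficiency and a near-miss immunodeficiency concept."""
    return EntityDictionary(
        [
            Concept(
                concept_id="OMIM:610102",
                preferred_name="COMPLEMENT COMPONENT 7 DEFICIENCY",
                synonyms={"C7 deficiency", "C7D"},
                source=DictionarySource.MEDIC,
            ),
            Concept(
                concept_id="MESH:D007153",
                preferred_name="Immunologic Deficiency Syndromes",
                synonyms={"antibody deficiency syndrome"},
                source=DictionarySource.MEDIC,
            ),
        ]
    )


@pytest.fixture
def vws_dictionary() -> EntityDictionary:
    """Van der Woude syndrome with its 'lip pits' synonym."""
    return EntityDictionary(
        [
            Concept(
                concept_id="OMIM:119300",
                preferred_name="Van der Woude syndrome",
                synonyms={"lip pits"},
            )
        ]
    )


@pytest.fixture
def vws_sentence() -> str:
    return "Affected males and females are equally likely to transmit VWS."


@pytest.fixture
def vws_mention(vws_sentence: str) -> Mention:
    start = vws_sentence.index("VWS")
    return Mention(
        doc_id="4019732",
        start=start,
        end=start + 3,
        surface="VWS",
        entity_type=EntityType.DISEASE,
        gold_concept_ids={"OMIM:119300"},
    )


@pytest.fixture
def two_doc_corpus() -> list[Document]:
    """Two documents, three mentions (cancer x2, tumor), two concepts."""
    d1 = Document(doc_id="1", title="cancer genomics.", abstract="We study cancer.")
    d1.mentions = [
        Mention("1", 0, 6, "cancer", EntityType.DISEASE, {"MESH:X"}),
        Mention("1", 26, 32, "cancer", EntityType.DISEASE, {"MESH:X"}),
    ]
    d2 = Document(doc_id="2", title="a tumor case.", abstract="The tumor regressed.")
    d2.mentions = [Mention("2", 2, 7, "tumor", EntityType.DISEASE, {"MESH:Y"})]
    for d in (d1, d2):
        d.validate_offsets()
    return [d1, d2]


@pytest.fixture
def tiny_vectors() -> VectorSet:
    """Four hand-placed 3-dimensional vectors for ranking tests."""
    matrix = np.array(
        [
            [1.0, 0.0, 0.0],  # alpha
            [0.9, 0.1, 0.0],  # beta (close to alpha)
            [0.0, 1.0, 0.0],  # gamma
            [0.0, 0.0, 1.0],  # delta
        ],
        dtype=np.float32,
    )
    return VectorSet(["alpha", "beta", "gamma", "delta"], matrix)


@pytest.fixture(scope="session")
def small_spec() -> FixtureSpec:
    """A fast fixture spec for unit tests (not the study conditions)."""
    return FixtureSpec(
        n_concepts=5,
        n_train_docs=8,
        n_test_docs=6,
        n_unlabeled_docs=12,
        context_vocab_size=80,
        seed=7,
    )
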
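"""Abbreviation resolution, mention vectorization and candidate ranking."""

from __future__ import annotations

import numpy as np
import pytest

from bionorm.corpus import Document, Mention
from bionorm.dictionary import Concept, EntityDictionary
from bionorm.embedding import VectorSet, cosine
from bionorm.normalize import (
    AbbreviationDictionary,
    NormalizationModel,
    concept_level,
    normalize_corpus,
    resolve_abbreviation,
    vectorize_mention,
)


@pytest.fixture
def abbreviations() -> AbbreviationDictionary:
    table = AbbreviationDictionary()
    table.add("10000001", "VWS", "Van der Woude syndrome")
    table.add("1", "AS", "Angelman Syndrome")
    table.add("2", "AS", "Ankylosing Spondylitis")
    return table


class TestAbbreviations:
    def test_document_scoped_hit(self, abbreviations) -> None:
        mention = Mention("10000001", 0, 3, "VWS")
        assert resolve_abbreviation(mention, abbreviations) == "Van der Woude syndrome"

    def test_ambiguous_global_short_form_unchanged(self, abbreviations) -> None:
        mention = Mention("999", 0, 2, "AS")  # no doc-scoped entry, two long forms
        assert resolve_abbreviation(mention, abbreviations) == "AS"

    def test_unknown_surface_unchanged(self, abbreviations) -> None:
        mention = Mention("1", 0, 3, "XYZ")
        assert resolve_abbreviation(mention, abbreviations) == "XYZ"

    def test_unique_global_fallback(self, abbreviations) -> None:
        mention = Mention("999", 0, 3, "VWS")
        assert resolve_abbreviation(mention, abbreviations) == "Van der Woude syndrome"

    def test_tsv_round_trip(self, tmp_path, abbreviations) -> None:
        path = tmp_path / "abbrev.tsv"
        with open(path, "w", encoding="utf-8") as handle:
            abbreviations.to_tsv(handle)
        loaded = AbbreviationDictionary.from_tsv(path)
        assert loaded.entries == abbreviations.entries


class TestVectorizeMention:
    def test_single_in_vocabulary_token_is_verbatim(self, tiny_vectors) -> None:
        np.testing.assert_allclose(
            vectorize_mention("alpha", tiny_vectors), tiny_vectors["alpha"]
        )

    def test_oov_token_contributes_zero_with_full_divisor(self, tiny_vectors) -> None:
        v = vectorize_mention("alpha zzz", tiny_vectors)
        np.testing.assert_allclose(
            v, np.asarray(tiny_vectors["alpha"], dtype=np.float64) / 2.0
        )

    def test_all_oov_mention_is_zero_vector(self, tiny_vectors) -> None:
        assert not vectorize_mention("zzz qqq", tiny_vectors).any()

    def test_empty_surface_is_error(self, tiny_vectors) -> None:
        with pytest.raises(ValueError):
            vectorize_mention("...", tiny_vectors)


def _model(tiny_vectors: VectorSet) -> NormalizationModel:
    dictionary = EntityDictionary(
        [
            Concept("C:A", "alpha"),
            Concept("C:B", "beta"),
            Concept("C:G", "gamma"),
            Concept("C:D", "delta"),
        ]
    )
    return NormalizationModel(tiny_vectors, dictionary, include_stemmed=False)


class TestRanking:
    def test_descending_scores_and_contiguous_ranks(self, tiny_vectors) -> None:
        model = _model(tiny_vectors)
        result = model.rank_candidates("alpha zzz", k=4)  # not an exact match
        assert not result.exact_match
        scores = [c.score for c in result.candidates]
        assert scores == sorted(scores, reverse=True)
        assert [c.rank for c in result.candidates] == list(
            range(1, len(result.candidates) + 1)
        )
        assert result.candidates[0].concept_id == "C:A"

    def test_matches_brute_force_cosine(self, tiny_vectors) -> None:
        model = _model(tiny_vectors)
        query = "beta zzz"
        result = model.rank_candidates(query, k=4)
        mention_vec = vectorize_mention(query, tiny_vectors)
        expected = sorted(
            (
                (cosine(mention_vec, tiny_vectors[t]), t)
                for t in ("alpha", "beta", "gamma", "delta")
            ),
            key=lambda pair: (-pair[0], pair[1]),
        )
        assert [c.name for c in result.candidates] == [t for _, t in expected]
        for cand, (score, _) in zip(result.candidates, expected):
            assert cand.score == pytest.approx(score, abs=1e-6)

    def test_k_larger_than_index_returns_full_index(self, tiny_vectors) -> None:
        model = _model(tiny_vectors)
        result = model.rank_candidates("alpha zzz", k=100)
        assert len(result.candidates) == 4

    def test_exact_match_shortcuts_similarity(self, tiny_vectors) -> None:
        model = _model(tiny_vectors)
        result = model.rank_candidates("alpha", k=4)
        assert result.exact_match
        assert [c.score for c in result.candidates] == [1.0]
        assert {c.concept_id for c in result.candidates} == {"C:A"}

    def test_all_oov_mention_yields_empty_with_diagnostic(self, tiny_vectors) -> None:
        model = _model(tiny_vectors)
        result = model.rank_candidates("zzz qqq", k=3)
        assert result.candidates == []
        assert "vocabulary" in result.diagnostic

    def test_tie_break_is_lexicographic(self) -> None:
        matrix = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]], dtype=np.float32)
        vectors = VectorSet(["aa", "bb", "cc"], matrix)
        dictionary = EntityDictionary(
            [Concept("C:1", "bb"), Concept("C:2", "aa"), Concept("C:3", "cc")]
        )
        model = NormalizationModel(vectors, dictionary, include_stemmed=False)
        result = model.rank_candidates("aa zzz", k=3)
        assert [c.name for c in result.candidates][:2] == ["aa", "bb"]

    def test_stemmed_forms_appear_in_index(self, tiny_vectors) -> None:
        dictionary = EntityDictionary([Concept("C:A", "alpha deficiency")])
        model = NormalizationModel(tiny_vectors, dictionary)
        displays = {e.display for e in model.name_index}
        assert "alpha_deficiency" in displays
        assert "alpha_defici" in displays


class TestNormalizeCorpus:
    def test_exact_match_flagged(self, tiny_vectors) -> None:
        model = _model(tiny_vectors)
        doc = Document("1", "alpha seen.", "")
        doc.mentions = [Mention("1", 0, 5, "alpha", gold_concept_ids={"C:A"})]
        records = normalize_corpus([doc], model)
        assert len(records) == 1 and records[0].exact_match

    def test_abbreviation_then_exact_match(self, tiny_vectors, abbreviations) -> None:
        abbreviations.add("7", "AL", "alpha")
        model = NormalizationModel(
            tiny_vectors,
            EntityDictionary([Concept("C:A", "alpha")]),
            abbreviations,
            include_stemmed=False,
        )
        doc = Document("7", "AL seen.", "")
        doc.mentions = [Mention("7", 0, 2, "AL", gold_concept_ids={"C:A"})]
        records = normalize_corpus([doc], model)
        assert records[0].exact_match
        assert records[0].result.resolved_surface == "alpha"

    def test_empty_corpus(self, tiny_vectors) -> None:
        assert normalize_corpus([], _model(tiny_vectors)) == []

    def test_disabling_abbreviations_is_pure_pretransform(self, tiny_vectors) -> None:
        """For mentions absent from the abbreviation table, predictions
        are identical with and without the table."""
        dictionary = EntityDictionary([Concept("C:A", "alpha"), Concept("C:B", "beta")])
        table = AbbreviationDictionary()
        table.add("1", "ZZ", "beta")
        with_table = NormalizationModel(tiny_vectors, dictionary, table,
                                        include_stemmed=False)
        without = NormalizationModel(tiny_vectors, dictionary, include_stemmed=False)
        doc = Document("1", "gamma seen.", "")
        doc.mentions = [Mention("1", 0, 5, "gamma")]
        first = normalize_corpus([doc], with_table)[0]
        second = normalize_corpus([doc], without)[0]
        assert [c.name for c in first.candidates] == [c.name for c in second.candidates]


def test_concept_level_keeps_best_name_per_concept(tiny_vectors) -> None:
    model = _model(tiny_vectors)
    result = model.rank_candidates("alpha zzz", k=4)
    collapsed = concept_level(result.candidates)
    assert len(collapsed) == len({c.concept_id for c in result.candidates})
    assert [c.rank for c in collapsed] == list(range(1, len(collapsed) + 1))
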
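"""Synonym/stem/underscore substitution and the unlabeled-text groups."""

from __future__ import annotations

from collections import Counter

import pytest

from bionorm.augment import (
    AugmentationConfig,
    UnlabeledGroup,
    build_unlabeled_group,
    expand_sentence,
    inject_dictionary_entries,
)
from bionorm.dictionary import Concept, EntityDictionary
from bionorm.simulate import make_corpora, make_dictionary

NO_STEM = AugmentationConfig(use_stem_variants=False)


class TestExpandSentence:
    def test_vws_rewrites_in_listed_order(
        self, vws_sentence, vws_mention, vws_dictionary
    ) -> None:
        out = expand_sentence(vws_sentence, [vws_mention], vws_dictionary, NO_STEM)
        prefix = "Affected males and females are equally likely to transmit "
        assert out == [
            vws_sentence,
            prefix + "Van der Woude syndrome.",
            prefix + "Van_der_Woude_syndrome.",
            prefix + "lip pits.",
            prefix + "lip_pits.",
        ]

    def test_no_applicable_rule_returns_original_only(self) -> None:
        d = EntityDictionary([Concept("X:1", "cancer")])
        config = AugmentationConfig(
            use_synonyms=False, use_stem_variants=False, use_underscore_join=False
        )
        out = expand_sentence("a cancer case.", ["cancer"], d, config)
        assert out == ["a cancer case."]

    def test_cap_truncates_total_output(self) -> None:
        d = EntityDictionary(
            [
                Concept("A:1", "aa disease", synonyms={"a1 syn", "a2 syn"}),
                Concept("B:1", "bb disease", synonyms={"b1 syn", "b2 syn"}),
            ]
        )
        config = AugmentationConfig(
            use_stem_variants=False,
            use_underscore_join=False,
            max_expansions_per_sentence=3,
        )
        out = expand_sentence(
            "both aa disease and bb disease.", ["aa disease", "bb disease"], d, config
        )
        assert len(out) == 3
        assert out[0] == "both aa disease and bb disease."

    def test_unknown_mention_is_error(self, vws_dictionary) -> None:
        with pytest.raises(ValueError, match="absent"):
            expand_sentence("nothing here.", ["absent"], vws_dictionary)

    def test_unresolvable_mention_gets_only_surface_variants(self) -> None:
        d = EntityDictionary([Concept("X:1", "unrelated disease")])
        out = expand_sentence("severe lung cancer seen.", ["lung cancer"], d)
        assert "severe lung_cancer seen." in out
        # no dictionary synonym applies
        assert not any("unrelated" in s for s in out)

    def test_text_outside_mention_span_never_changes(
        self, vws_sentence, vws_mention, vws_dictionary
    ) -> None:
        out = expand_sentence(vws_sentence, [vws_mention], vws_dictionary)
        head = vws_sentence[: vws_sentence.index("VWS")]
        assert all(s.startswith(head) for s in out)

    def test_deterministic(self, vws_sentence, vws_mention, vws_dictionary) -> None:
        first = expand_sentence(vws_sentence, [vws_mention], vws_dictionary)
        second = expand_sentence(vws_sentence, [vws_mention], vws_dictionary)
        assert first == second


class TestInjectDictionaryEntries:
    def test_only_unseen_names_injected(self) -> None:
        d = EntityDictionary(
            [
                Concept("A:1", "alpha pox"),
                Concept("B:1", "beta pox"),
                Concept("C:1", "gamma pox"),
            ]
        )
        sentences = ["we saw alpha_pox yesterday"]
        out = inject_dictionary_entries(sentences, d)
        assert len(out) == len(sentences) + 2
        assert "beta pox beta_pox" in out
        assert "gamma pox gamma_pox" in out

    def test_empty_dictionary_leaves_stream_unchanged(self) -> None:
        out = inject_dictionary_entries(["a b"], EntityDictionary())
        assert out == ["a b"]

    def test_all_names_seen_leaves_stream_unchanged(self) -> None:
        d = EntityDictionary([Concept("A:1", "alpha pox")])
        out = inject_dictionary_entries(["alpha_pox seen"], d)
        assert out == ["alpha_pox seen"]


@pytest.fixture(scope="module")
def corpora(small_spec):
    dictionary = make_dictionary(small_spec)
    _, _, unlabeled, _ = make_corpora(small_spec, dictionary)
    return dictionary, unlabeled


class TestUnlabeledGroups:
    def test_group_inclusion_chain(self, corpora) -> None:
        dictionary, unlabeled = corpora
        groups = {
            g: build_unlabeled_group(unlabeled, dictionary, g)
            for g in UnlabeledGroup
        }

        def token_multiset(sentences):
            return Counter(t for s in sentences for t in s.split())

        all_tokens = token_multiset(groups[UnlabeledGroup.ALL_ABSTRACTS])
        entity = token_multiset(groups[UnlabeledGroup.ENTITY_ABSTRACTS])
        evidence = token_multiset(groups[UnlabeledGroup.EVIDENCE_SENTENCES])
        assert evidence <= entity <= all_tokens
        modified = groups[UnlabeledGroup.MODIFIED_EVIDENCE_SENTENCES]
        assert set(groups[UnlabeledGroup.EVIDENCE_SENTENCES]) <= set(modified)
        assert len(modified) >= len(groups[UnlabeledGroup.EVIDENCE_SENTENCES])

    def test_entity_abstract_filter(self, corpora) -> None:
        dictionary, unlabeled = corpora
        import dataclasses

        no_mentions = [
            dataclasses.replace(doc, mentions=[]) for doc in unlabeled[:1]
        ]
        mixed = no_mentions + list(unlabeled[1:2])
        kept = build_unlabeled_group(
            mixed, dictionary, UnlabeledGroup.ENTITY_ABSTRACTS
        )
        from bionorm.corpus import split_sentences

        assert len(kept) == len(split_sentences(unlabeled[1]))

    def test_groups_requiring_mentions_fail_without_any(self, corpora) -> None:
        dictionary, unlabeled = corpora
        import dataclasses

        bare = [dataclasses.replace(doc, mentions=[]) for doc in unlabeled]
        with pytest.raises(ValueError, match="mention"):
            build_unlabeled_group(bare, dictionary, UnlabeledGroup.EVIDENCE_SENTENCES)
        # ALL_ABSTRACTS is fine without mentions
        assert build_unlabeled_group(bare, dictionary, UnlabeledGroup.ALL_ABSTRACTS)


def test_config_cap_validation() -> None:
    with pytest.raises(ValueError):
        AugmentationConfig(max_expansions_per_sentence=0)
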
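"""Training-data augmentation: synonym substitution, stemming variants,
underscore joining, dictionary-entry injection, and the four
unlabeled-text groups.

The normalization model's premise is that a mention and its dictionary
synonyms share contexts. Augmentation makes that literal: for every
mention in a sentence, new sentences are emitted in which the mention is
replaced by each dictionary synonym of its concept(s), by the
underscore-joined single-token form of each name, and by per-token Porter
stem variants. Dictionary names never seen in the training text are
injected as minimal sentences so that every concept name receives a
vector.

Unlabeled text is organized into four nested groups: all abstracts,
abstracts containing at least one recognized entity ("entity
abstracts"), sentences containing at least one entity ("evidence
sentences"), and evidence sentences plus their substitution rewrites
("modified evidence sentences").
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from .corpus import Document, Mention, Sentence, split_sentences
from .dictionary import EntityDictionary
from .stemming import stem_name
from .text import tokenize, underscore_join


@dataclass(frozen=True)
class AugmentationConfig:
    use_synonyms: bool = True
    use_stem_variants: bool = True
    use_underscore_join: bool = True
    inject_dictionary_entries: bool = True
    max_expansions_per_sentence: int = 50

    def __post_init__(self) -> None:
        if self.max_expansions_per_sentence < 1:
            raise ValueError("max_expansions_per_sentence must be >= 1")


class UnlabeledGroup(Enum):
    ALL_ABSTRACTS = "all_abstracts"
    ENTITY_ABSTRACTS = "entity_abstracts"
    EVIDENCE_SENTENCES = "evidence_sentences"
    MODIFIED_EVIDENCE_SENTENCES = "modified_evidence_sentences"


def stem_variants(token: str, lexicon: Iterable[str]) -> set[str]:
    """The Porter stem of ``token`` plus every lexicon token sharing that
    stem."""
    from .stemming import porter_stem

    stem = porter_stem(token)
    out = {stem}
    out.update(w for w in lexicon if porter_stem(w) == stem)
    return out


def _name_forms(name: str, config: AugmentationConfig) -> list[str]:
    """Substitution forms of a replacement name, in deterministic order:
    plain, underscore-joined, stemmed, stemmed underscore-joined."""
    forms = [name]
    if config.use_underscore_join:
        joined = underscore_join(name)
        if joined != name:
            forms.append(joined)
    if config.use_stem_variants:
        stemmed = stem_name(name)
        if stemmed not in forms:
            forms.append(stemmed)
        if config.use_underscore_join:
            joined_stem = underscore_join(stemmed)
            if joined_stem not in forms:
                forms.append(joined_stem)
    return forms


def _resolve_concepts(
    surface: str,
    gold_ids: set[str] | None,
    dictionary: EntityDictionary | None,
) -> list[str]:
    """Concept IDs whose synonyms substitute for this mention: the gold
    IDs when available (training corpus), exact-match lookup otherwise
    (unlabeled data). Ambiguity expands with the union of all matches."""
    if gold_ids:
        return sorted(cid for cid in gold_ids if dictionary and cid in dictionary)
    if dictionary is not None:
        return sorted(dictionary.lookup_exact(surface))
    return []


def expand_sentence(
    sentence: str,
    mentions: Sequence[str | Mention],
    dictionary: EntityDictionary | None,
    config: AugmentationConfig | None = None,
) -> list[str]:
    """Rewrite a sentence once per applicable substitution per mention.

    The original sentence is always first; duplicates are removed
    preserving first occurrence; the output is truncated at
    ``max_expansions_per_sentence`` sentences in total. One substitution
    per generated sentence (no cross-product over mentions). Text outside
    the mention span is never altered.
    """
    config = config or AugmentationConfig()
    out = [sentence]
    seen = {sentence}

    for item in mentions:
        if isinstance(item, Mention):
            surface, gold = item.surface, item.gold_concept_ids
        else:
            surface, gold = item, None
        if surface not in sentence:
            raise ValueError(
                f"mention {surface!r} does not occur in sentence {sentence!r}"
            )

        replacements: list[str] = []
        if config.use_synonyms:
            for cid in _resolve_concepts(surface, gold, dictionary):
                concept = dictionary[cid]
                for name in concept.names():
                    if name == surface:
                        continue
                    replacements.extend(_name_forms(name, config))
        # Variants of the mention surface itself.
        if config.use_underscore_join:
            joined = underscore_join(surface)
            if joined != surface:
                replacements.append(joined)
        if config.use_stem_variants:
            stemmed = stem_name(surface)
            if stemmed != surface:
                replacements.append(stemmed)
                if config.use_underscore_join:
                    joined_stem = underscore_join(stemmed)
                    if joined_stem != stemmed:
                        replacements.append(joined_stem)

        for repl in replacements:
            rewritten = sentence.replace(surface, repl, 1)
            if rewritten not in seen:
                seen.add(rewritten)
                out.append(rewritten)

    return out[: config.max_expansions_per_sentence]


def expand_sentence_stream(
    sentences: Iterable[Sentence],
    dictionary: EntityDictionary | None,
    config: AugmentationConfig | None = None,
) -> list[str]:
    """Apply :func:`expand_sentence` over a sentence stream, returning
    plain sentence strings (originals first within each sentence)."""
    out: list[str] = []
    for sent in sentences:
        out.extend(expand_sentence(sent.text, sent.mentions, dictionary, config))
    return out


def inject_dictionary_entries(
    training_sentences: Sequence[str],
    dictionary: EntityDictionary,
    seen_tokens: set[str] | None = None,
) -> list[str]:
    """Append a minimal sentence for every dictionary name whose
    underscore-joined form is absent from the training vocabulary.

    The injected sentence contains the name's tokens and its
    underscore-joined form so both receive vectors. Names already seen
    are not re-injected.
    """
    if seen_tokens is None:
        seen_tokens = set()
        for sent in training_sentences:
            seen_tokens.update(sent.split())
    out = list(training_sentences)
    for name, _cid in dictionary.iter_names():
        joined = underscore_join(name)
        if joined in seen_tokens:
            continue
        out.append(name if joined == name else f"{name} {joined}")
        seen_tokens.add(joined)
    return out


def build_unlabeled_group(
    abstracts: Sequence[Document],
    dictionary: EntityDictionary | None,
    group: UnlabeledGroup,
    config: AugmentationConfig | None = None,
) -> list[str]:
    """Build one of the four unlabeled-text groups as sentence strings.

    Groups other than ALL_ABSTRACTS require recognized mentions on the
    abstracts (possibly produced by dictionary exact matching upstream).
    """
    if group is not UnlabeledGroup.ALL_ABSTRACTS:
        if not any(doc.mentions for doc in abstracts):
            raise ValueError(
                f"group {group.value} requires recognized mentions, "
                "but no abstract carries any"
            )
    if group is UnlabeledGroup.MODIFIED_EVIDENCE_SENTENCES and dictionary is None:
        raise ValueError("modified evidence sentences require an entity dictionary")

    if group is UnlabeledGroup.ALL_ABSTRACTS:
        return [s.text for doc in abstracts for s in split_sentences(doc)]
    if group is UnlabeledGroup.ENTITY_ABSTRACTS:
        return [
            s.text
            for doc in abstracts
            if doc.mentions
            for s in split_sentences(doc)
        ]

    evidence = [
        s for doc in abstracts for s in split_sentences(doc) if s.mentions
    ]
    if group is UnlabeledGroup.EVIDENCE_SENTENCES:
        return [s.text for s in evidence]
    return expand_sentence_stream(evidence, dictionary, config)


def tokenize_sentences(sentences: Iterable[str]) -> list[str]:
    """Render sentences as space-separated token lines, ready for
    embedding training."""
    return [" ".join(tokenize(s)) for s in sentences if tokenize(s)]
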
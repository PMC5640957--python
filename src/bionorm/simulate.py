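"""Synthetic dictionaries, corpora and abbreviation tables with
controlled statistical structure.

The generator emulates the shape of a normalization study — an entity
dictionary, a gold-annotated training/test corpus, unlabeled abstracts
with recognized-but-unnormalized mentions, and a document-scoped
abbreviation table — without any download. Its central knob is
``context_overlap``: the probability that a context word in a sentence
mentioning concept *c* is drawn from *c*'s private topic vocabulary
rather than from a shared Zipf-distributed background vocabulary. At
high overlap, names of the same concept share contexts and embedding
similarity can recover held-out synonyms; at zero overlap there is no
topical signal and similarity ranking should be at chance.

Every concept has multi-word names built from globally unique
pseudo-word tokens, plus (when ``abbreviation_rate > 0``) an acronym
synonym. Each concept additionally has held-out *variant* surfaces —
informal aliases built from fresh tokens that appear in no dictionary
name and nowhere in the training corpus. Variants occur only in the
unlabeled text, as recognized-but-unnormalized mentions (each form
``variant_occurrences`` times), so their sole link to the concept is
shared topical context: with high overlap the embedding model can
normalize them, with zero overlap nothing can. Test documents use
variant surfaces at rate ``oov_rate`` (exercising the similarity path);
the remaining test mentions are dictionary names resolved by the
exact-match shortcut. Generation is a pure function of the spec: one
seeded generator per call, no global state.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .corpus import Document, EntityType, Mention, write_pubtator
from .dictionary import Concept, DictionarySource, EntityDictionary, write_generic_tsv
from .normalize import AbbreviationDictionary

_CONSONANTS = "bcdfgklmnprstvz"
_VOWELS = "aeiou"

#: Generic head nouns used in dictionary names and held-out variants.
_NAME_HEADS = ("syndrome", "disease", "deficiency", "illness", "ailment")
_VARIANT_HEADS = ("disorder", "condition")


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic data set."""

    n_concepts: int = 20
    synonyms_per_concept: int = 3
    n_train_docs: int = 40
    n_test_docs: int = 30
    n_unlabeled_docs: int = 100
    mentions_per_doc: float = 3.0
    sentences_per_doc: int = 4
    context_vocab_size: int = 500
    topic_words_per_concept: int = 8
    context_words_per_sentence: int = 8
    context_overlap: float = 0.8
    abbreviation_rate: float = 0.1
    oov_rate: float = 0.3
    variant_occurrences: int = 4
    seed: int = 42

    def __post_init__(self) -> None:
        for name in ("context_overlap", "abbreviation_rate", "oov_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        for name in (
            "n_concepts", "n_train_docs", "n_test_docs", "n_unlabeled_docs",
            "sentences_per_doc", "context_vocab_size",
            "topic_words_per_concept", "context_words_per_sentence",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.synonyms_per_concept < 0:
            raise ValueError("synonyms_per_concept must be >= 0")
        if self.variant_occurrences < 0:
            raise ValueError("variant_occurrences must be >= 0")

    def replace(self, **kwargs) -> "FixtureSpec":
        from dataclasses import replace as _replace

        return _replace(self, **kwargs)


@dataclass
class _ConceptRecord:
    concept_id: str
    tokens: list[str]
    preferred: str
    synonyms: list[str]
    acronym: str | None
    variants: list[str]  # informal aliases: fresh tokens, unlabeled text only
    topic: list[str]

    def dictionary_names(self) -> list[str]:
        return [self.preferred, *self.synonyms]

    def non_acronym_names(self) -> list[str]:
        return [n for n in self.dictionary_names() if n != self.acronym]


def _make_word(rng: np.random.Generator, registry: set[str], n_syllables: int = 3) -> str:
    while True:
        word = "".join(
            _CONSONANTS[rng.integers(len(_CONSONANTS))]
            + _VOWELS[rng.integers(len(_VOWELS))]
            for _ in range(n_syllables)
        )
        if word not in registry:
            registry.add(word)
            return word


def _concepts(spec: FixtureSpec) -> list[_ConceptRecord]:
    rng = np.random.default_rng([spec.seed, 0])
    registry: set[str] = set(_NAME_HEADS) | set(_VARIANT_HEADS)
    records: list[_ConceptRecord] = []
    for i in range(spec.n_concepts):
        w = [_make_word(rng, registry) for _ in range(4)]
        preferred = f"{w[0]} {w[1]} {_NAME_HEADS[0]}"
        candidates = [
            f"{w[0]} {w[2]} {_NAME_HEADS[1]}",
            f"{w[1]} {w[3]} {_NAME_HEADS[2]}",
            f"{w[2]} {w[3]} {_NAME_HEADS[3]}",
            f"{w[0]} {w[3]} {_NAME_HEADS[4]}",
        ]
        acronym: str | None = None
        synonyms = candidates[: spec.synonyms_per_concept]
        if spec.abbreviation_rate > 0 and spec.synonyms_per_concept >= 1:
            acronym = f"{w[0][0]}{w[1][0]}S{i}".upper()
            synonyms = candidates[: spec.synonyms_per_concept - 1] + [acronym]
        # Informal aliases from fresh tokens: no lexical link to any
        # dictionary name, so only context can normalize them.
        x = [_make_word(rng, registry) for _ in range(4)]
        variants = [
            f"{x[0]} {x[1]}",
            f"{x[2]} {x[3]} {_VARIANT_HEADS[i % len(_VARIANT_HEADS)]}",
        ]
        topic = [_make_word(rng, registry) for _ in range(spec.topic_words_per_concept)]
        records.append(
            _ConceptRecord(
                concept_id=f"FIX:{i:04d}",
                tokens=w,
                preferred=preferred,
                synonyms=synonyms,
                acronym=acronym,
                variants=variants,
                topic=topic,
            )
        )
    return records


def make_dictionary(spec: FixtureSpec) -> EntityDictionary:
    """The fixture's entity dictionary: ``n_concepts`` concepts with
    multi-word preferred names and ``synonyms_per_concept`` synonyms
    (one an acronym when ``abbreviation_rate > 0``); all names globally
    unique and exact-match resolvable."""
    dictionary = EntityDictionary()
    for rec in _concepts(spec):
        dictionary.add(
            Concept(
                concept_id=rec.concept_id,
                preferred_name=rec.preferred,
                synonyms=set(rec.synonyms),
                source=DictionarySource.GENERIC,
            )
        )
    return dictionary


class _Background:
    """Shared Zipf-distributed context vocabulary."""

    def __init__(self, spec: FixtureSpec, rng: np.random.Generator) -> None:
        registry: set[str] = set(_NAME_HEADS) | set(_VARIANT_HEADS)
        word_rng = np.random.default_rng([spec.seed, 99])
        self.words = [
            "bg" + _make_word(word_rng, registry)
            for _ in range(spec.context_vocab_size)
        ]
        ranks = np.arange(1, spec.context_vocab_size + 1, dtype=np.float64)
        self.probs = (1.0 / ranks) / np.sum(1.0 / ranks)
        self._rng = rng

    def draw(self) -> str:
        return self.words[int(self._rng.choice(len(self.words), p=self.probs))]


def _build_sentence(
    rng: np.random.Generator,
    spec: FixtureSpec,
    background: _Background,
    concept: _ConceptRecord | None,
    mention_surface: str | None,
) -> tuple[str, int | None]:
    """One sentence as text; returns (text, mention char offset)."""
    words: list[str] = []
    for _ in range(spec.context_words_per_sentence):
        if concept is not None and rng.random() < spec.context_overlap:
            words.append(concept.topic[int(rng.integers(len(concept.topic)))])
        else:
            words.append(background.draw())
    offset: int | None = None
    if mention_surface is not None:
        pos = int(rng.integers(0, len(words) + 1))
        prefix = " ".join(words[:pos])
        offset = len(prefix) + (1 if prefix else 0)
        words = words[:pos] + [mention_surface] + words[pos:]
    return " ".join(words) + ".", offset


def _pick_surface(
    rng: np.random.Generator,
    spec: FixtureSpec,
    rec: _ConceptRecord,
    *,
    kind: str,
) -> tuple[str, bool]:
    """Choose a mention surface; returns (surface, is_acronym)."""
    if kind == "test" and rng.random() < spec.oov_rate:
        return rec.variants[int(rng.integers(len(rec.variants)))], False
    if (
        kind in {"train", "test"}
        and rec.acronym is not None
        and rng.random() < spec.abbreviation_rate
    ):
        return rec.acronym, True
    names = rec.non_acronym_names()
    return names[int(rng.integers(len(names)))], False


def _make_document(
    rng: np.random.Generator,
    spec: FixtureSpec,
    background: _Background,
    records: list[_ConceptRecord],
    doc_id: str,
    *,
    kind: str,  # "train" | "test" | "unlabeled"
    abbreviations: AbbreviationDictionary,
    plan: "deque[tuple[int, str]] | None" = None,
) -> Document:
    n_sent = spec.sentences_per_doc
    n_mentions = min(n_sent, max(1, int(rng.poisson(spec.mentions_per_doc))))
    mention_slots = sorted(rng.choice(n_sent, size=n_mentions, replace=False).tolist())

    sentence_texts: list[str] = []
    pending: list[tuple[int, str, str, bool]] = []  # (sent idx, surface, cid, acronym?)
    local_offsets: list[int] = []
    for s in range(n_sent):
        if s in mention_slots:
            if plan:
                rec_index, surface = plan.popleft()
                rec, is_acr = records[rec_index], False
            else:
                rec = records[int(rng.integers(len(records)))]
                surface, is_acr = _pick_surface(rng, spec, rec, kind=kind)
            text, off = _build_sentence(rng, spec, background, rec, surface)
            pending.append((s, surface, rec.concept_id, is_acr))
            local_offsets.append(off if off is not None else 0)
            if is_acr:
                abbreviations.add(doc_id, surface, rec.preferred)
        else:
            text, _ = _build_sentence(rng, spec, background, None, None)
        sentence_texts.append(text)

    title = sentence_texts[0]
    abstract = " ".join(sentence_texts[1:])
    doc = Document(doc_id=doc_id, title=title, abstract=abstract)

    # Sentence start offsets within title + " " + abstract.
    starts: list[int] = []
    cursor = 0
    for text in sentence_texts:
        starts.append(cursor)
        cursor += len(text) + 1
    for (s, surface, cid, _is_acr), off in zip(pending, local_offsets):
        start = starts[s] + off
        gold = set() if kind == "unlabeled" else {cid}
        doc.mentions.append(
            Mention(
                doc_id=doc_id,
                start=start,
                end=start + len(surface),
                surface=surface,
                entity_type=EntityType.DISEASE,
                gold_concept_ids=gold,
            )
        )
    doc.validate_offsets()
    return doc


def make_corpora(
    spec: FixtureSpec, dictionary: EntityDictionary
) -> tuple[list[Document], list[Document], list[Document], AbbreviationDictionary]:
    """Generate (training docs, test docs, unlabeled docs, abbreviation
    dictionary) for a dictionary produced by :func:`make_dictionary`
    from the same spec."""
    records = _concepts(spec)
    for rec in records:
        if rec.concept_id not in dictionary:
            raise ValueError(
                "dictionary does not match spec (was it built by "
                f"make_dictionary on the same spec?): missing {rec.concept_id}"
            )
    rng = np.random.default_rng([spec.seed, 1])
    background = _Background(spec, rng)
    abbreviations = AbbreviationDictionary()

    # Unlabeled mention plan: every variant form appears exactly
    # variant_occurrences times (truncated if the docs run out of
    # slots); remaining slots carry random dictionary names.
    variant_plan = [
        (i, variant)
        for i, rec in enumerate(records)
        for variant in rec.variants
        for _ in range(spec.variant_occurrences)
    ]
    rng.shuffle(variant_plan)
    plan: deque[tuple[int, str]] = deque(variant_plan)

    train = [
        _make_document(rng, spec, background, records, f"{10000 + i}",
                       kind="train", abbreviations=abbreviations)
        for i in range(spec.n_train_docs)
    ]
    test = [
        _make_document(rng, spec, background, records, f"{20000 + i}",
                       kind="test", abbreviations=abbreviations)
        for i in range(spec.n_test_docs)
    ]
    unlabeled = [
        _make_document(rng, spec, background, records, f"{30000 + i}",
                       kind="unlabeled", abbreviations=abbreviations, plan=plan)
        for i in range(spec.n_unlabeled_docs)
    ]
    return train, test, unlabeled, abbreviations


def heldout_variants(spec: FixtureSpec) -> dict[str, str]:
    """Map informal-alias surface -> concept ID. These surfaces are
    absent from the dictionary and the training corpus; they occur only
    in unlabeled text (handy for tests)."""
    return {
        variant: rec.concept_id
        for rec in _concepts(spec)
        for variant in rec.variants
    }


def write_fixture_set(spec: FixtureSpec, outdir: str | Path) -> dict[str, Path]:
    """Write the full fixture set in the pipeline's own file formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dictionary = make_dictionary(spec)
    train, test, unlabeled, abbreviations = make_corpora(spec, dictionary)
    paths = {
        "dictionary": outdir / "dictionary.tsv",
        "train": outdir / "train.pubtator",
        "test": outdir / "test.pubtator",
        "unlabeled": outdir / "unlabeled.pubtator",
        "abbreviations": outdir / "abbreviations.tsv",
    }
    with open(paths["dictionary"], "w", encoding="utf-8") as handle:
        write_generic_tsv(dictionary, handle)
    for key, docs in (("train", train), ("test", test), ("unlabeled", unlabeled)):
        with open(paths[key], "w", encoding="utf-8") as handle:
            write_pubtator(docs, handle)
    with open(paths["abbreviations"], "w", encoding="utf-8") as handle:
        abbreviations.to_tsv(handle)
    return paths
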
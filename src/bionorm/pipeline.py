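"""End-to-end wiring: augment -> train -> normalize -> evaluate.

Six training regimes are supported, differing only in which text feeds
the embedding trainer:

* ``SL_ONLY_TRAINING`` — the (augmented) training corpus alone;
* ``SSL_ALL_ABSTRACTS`` — training corpus + every unlabeled sentence;
* ``SSL_ENTITY_ABSTRACTS`` — + sentences of abstracts containing at
  least one recognized entity;
* ``SSL_EVIDENCES`` — + only sentences containing an entity;
* ``SSL_MODIFIED_EVIDENCES`` — + evidence sentences and their
  synonym/stem/underscore rewrites (the best-performing regime);
* ``SSL_ONLY_MODIFIED_EVIDENCES`` — modified evidence sentences without
  the training corpus.

In every regime the training corpus itself (when used) is augmented the
same way, and dictionary names missing from the text are injected so
each concept name has a vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

from .augment import (
    AugmentationConfig,
    UnlabeledGroup,
    build_unlabeled_group,
    expand_sentence_stream,
    inject_dictionary_entries,
    tokenize_sentences,
)
from .corpus import Document, iter_sentences
from .dictionary import EntityDictionary
from .embedding import EmbeddingParams, VectorSet, train_embeddings
from .evaluate import EvalResult, evaluation_curve
from .normalize import (
    AbbreviationDictionary,
    NormalizationModel,
    PredictionRecord,
    normalize_corpus,
)

logger = logging.getLogger("bionorm")


class Regime(Enum):
    SL_ONLY_TRAINING = "sl_only_training"
    SSL_ALL_ABSTRACTS = "ssl_all_abstracts"
    SSL_ENTITY_ABSTRACTS = "ssl_entity_abstracts"
    SSL_EVIDENCES = "ssl_evidences"
    SSL_MODIFIED_EVIDENCES = "ssl_modified_evidences"
    SSL_ONLY_MODIFIED_EVIDENCES = "ssl_only_modified_evidences"


_REGIME_GROUP = {
    Regime.SSL_ALL_ABSTRACTS: UnlabeledGroup.ALL_ABSTRACTS,
    Regime.SSL_ENTITY_ABSTRACTS: UnlabeledGroup.ENTITY_ABSTRACTS,
    Regime.SSL_EVIDENCES: UnlabeledGroup.EVIDENCE_SENTENCES,
    Regime.SSL_MODIFIED_EVIDENCES: UnlabeledGroup.MODIFIED_EVIDENCE_SENTENCES,
    Regime.SSL_ONLY_MODIFIED_EVIDENCES: UnlabeledGroup.MODIFIED_EVIDENCE_SENTENCES,
}


def build_training_corpus(
    regime: Regime,
    train_docs: Sequence[Document],
    unlabeled_docs: Sequence[Document],
    dictionary: EntityDictionary,
    config: AugmentationConfig | None = None,
) -> list[str]:
    """Assemble the embedding-training text for one regime as
    space-separated token lines."""
    config = config or AugmentationConfig()
    sentences: list[str] = []

    if regime is not Regime.SSL_ONLY_MODIFIED_EVIDENCES:
        sentences.extend(
            expand_sentence_stream(iter_sentences(train_docs), dictionary, config)
        )

    group = _REGIME_GROUP.get(regime)
    if group is not None:
        sentences.extend(
            build_unlabeled_group(unlabeled_docs, dictionary, group, config)
        )

    lines = tokenize_sentences(sentences)
    if config.inject_dictionary_entries:
        lines = inject_dictionary_entries(lines, dictionary)
    return lines


@dataclass
class ExperimentResult:
    regime: Regime
    vector_set: VectorSet
    records: list[PredictionRecord]
    curve: list[EvalResult]
    n_training_sentences: int

    def at_rank(self, threshold: int) -> EvalResult:
        return self.curve[threshold - 1]


def run_experiment(
    train_docs: Sequence[Document],
    test_docs: Sequence[Document],
    unlabeled_docs: Sequence[Document],
    dictionary: EntityDictionary,
    *,
    regime: Regime = Regime.SSL_MODIFIED_EVIDENCES,
    embedding: EmbeddingParams | None = None,
    augmentation: AugmentationConfig | None = None,
    abbreviations: AbbreviationDictionary | None = None,
    top_k: int = 10,
    max_threshold: int = 10,
) -> ExperimentResult:
    """Train one regime and evaluate it on the test documents."""
    embedding = embedding or EmbeddingParams()
    lines = build_training_corpus(
        regime, train_docs, unlabeled_docs, dictionary, augmentation
    )
    logger.info("[train] regime=%s sentences=%d", regime.value, len(lines))
    vector_set = train_embeddings(lines, embedding)
    logger.info("[train] vocabulary=%d tokens", len(vector_set))
    model = NormalizationModel(vector_set, dictionary, abbreviations)
    records = normalize_corpus(test_docs, model, k=top_k)
    logger.info("[normalize] mentions=%d", len(records))
    aliases = {alt: cid for cid, c in dictionary.concepts.items() for alt in c.alt_ids}
    curve = evaluation_curve(records, max_threshold, aliases or None)
    return ExperimentResult(
        regime=regime,
        vector_set=vector_set,
        records=records,
        curve=curve,
        n_training_sentences=len(lines),
    )


# ---------------------------------------------------------------------------
# File-driven pipeline (the CLI's `run` subcommand)

@dataclass
class RunConfig:
    """Validated configuration of a file-driven pipeline run."""

    dictionary: Path
    corpus: Path  # training corpus (PubTator)
    test_corpus: Path
    output_dir: Path
    unlabeled: Path | None = None
    abbreviations: Path | None = None
    regime: Regime = Regime.SSL_MODIFIED_EVIDENCES
    embedding: EmbeddingParams = field(default_factory=EmbeddingParams)
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    top_k: int = 10
    max_threshold: int = 10

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path, encoding="utf-8") as handle:
            raw = dict(yaml.safe_load(handle) or {})
        paths = raw.get("paths", {})

        def req(key: str) -> Path:
            if key not in paths:
                raise ValueError(f"{path}: missing required path {key!r}")
            return Path(paths[key])

        def opt(key: str) -> Path | None:
            return Path(paths[key]) if key in paths else None

        emb = raw.get("embedding", {})
        seed = int(raw.get("seed", 42))
        config = cls(
            dictionary=req("dictionary"),
            corpus=req("corpus"),
            test_corpus=req("test_corpus"),
            output_dir=Path(paths.get("output_dir", "bionorm_out")),
            unlabeled=opt("unlabeled"),
            abbreviations=opt("abbreviations"),
            regime=Regime(raw.get("regime", Regime.SSL_MODIFIED_EVIDENCES.value)),
            embedding=EmbeddingParams(
                algorithm=emb.get("algorithm", "cbow"),
                window=int(emb.get("window", 8)),
                dimension=int(emb.get("dimension", 200)),
                min_count=int(emb.get("min_count", 1)),
                epochs=int(emb.get("epochs", 5)),
                seed=seed,
            ),
            augmentation=AugmentationConfig(
                **{
                    k: raw["augmentation"][k]
                    for k in (
                        "use_synonyms",
                        "use_stem_variants",
                        "use_underscore_join",
                        "inject_dictionary_entries",
                        "max_expansions_per_sentence",
                    )
                    if k in raw.get("augmentation", {})
                }
            ),
            top_k=int(raw.get("top_k", 10)),
            max_threshold=int(raw.get("max_threshold", 10)),
        )
        config.validate()
        return config

    def validate(self) -> None:
        for name in ("dictionary", "corpus", "test_corpus", "unlabeled", "abbreviations"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"{name} path does not exist: {value}")
        if self.regime is not Regime.SL_ONLY_TRAINING and self.unlabeled is None:
            raise ValueError(f"regime {self.regime.value} requires an unlabeled corpus")


def run_pipeline(config: RunConfig) -> ExperimentResult:
    """Execute augment -> train -> normalize -> evaluate from files,
    writing vectors, predictions and the evaluation curve to the output
    directory."""
    from .corpus import read_pubtator
    from .dictionary import load_generic_tsv, load_medic_tsv
    from .embedding import save_vectors
    from .evaluate import write_curve_tsv
    from .normalize import write_predictions_tsv

    config.validate()
    config.output_dir.mkdir(parents=True, exist_ok=True)

    def _load_dictionary(path: Path) -> EntityDictionary:
        with open(path, encoding="utf-8") as handle:
            first_data = next(
                (l for l in handle if l.strip() and not l.startswith("#")), ""
            )
        n_cols = len(first_data.rstrip("\n").split("\t"))
        return load_generic_tsv(path) if n_cols == 3 else load_medic_tsv(path)

    try:
        dictionary = _load_dictionary(config.dictionary)
        train_docs = read_pubtator(config.corpus)
        test_docs = read_pubtator(config.test_corpus)
        unlabeled_docs = (
            read_pubtator(config.unlabeled) if config.unlabeled else []
        )
        abbreviations = (
            AbbreviationDictionary.from_tsv(config.abbreviations)
            if config.abbreviations
            else None
        )
    except Exception as exc:
        raise RuntimeError(f"[load] {exc}") from exc

    result = run_experiment(
        train_docs,
        test_docs,
        unlabeled_docs,
        dictionary,
        regime=config.regime,
        embedding=config.embedding,
        augmentation=config.augmentation,
        abbreviations=abbreviations,
        top_k=config.top_k,
        max_threshold=config.max_threshold,
    )

    save_vectors(result.vector_set, config.output_dir / "vectors.txt")
    with open(config.output_dir / "predictions.tsv", "w", encoding="utf-8") as handle:
        write_predictions_tsv(result.records, handle)
    with open(config.output_dir / "evaluation.tsv", "w", encoding="utf-8") as handle:
        write_curve_tsv(result.curve, handle)
    return result
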
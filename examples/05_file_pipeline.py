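"""The file-driven pipeline: the same run the `bionorm run` CLI performs.

Writes a synthetic fixture set to disk in the pipeline's own formats
(generic dictionary TSV, PubTator corpora, abbreviation TSV), then runs
augment -> train -> normalize -> evaluate from those files, leaving
vectors.txt, predictions.tsv and evaluation.tsv in the output directory.
"""

import tempfile
from pathlib import Path

from bionorm.embedding import EmbeddingParams
from bionorm.pipeline import Regime, RunConfig, run_pipeline
from bionorm.simulate import FixtureSpec, write_fixture_set

with tempfile.TemporaryDirectory() as tmp:
    data = Path(tmp) / "data"
    paths = write_fixture_set(FixtureSpec(n_concepts=8, n_train_docs=15,
                                          n_test_docs=10, n_unlabeled_docs=40,
                                          seed=21), data)
    config = RunConfig(
        dictionary=paths["dictionary"],
        corpus=paths["train"],
        test_corpus=paths["test"],
        unlabeled=paths["unlabeled"],
        abbreviations=paths["abbreviations"],
        output_dir=Path(tmp) / "out",
        regime=Regime.SSL_MODIFIED_EVIDENCES,
        embedding=EmbeddingParams(algorithm="skipgram", window=5, dimension=32,
                                  epochs=8, seed=21),
        max_threshold=5,
    )
    result = run_pipeline(config)
    top = result.at_rank(1)
    print(f"training sentences: {result.n_training_sentences}")
    print(f"vocabulary: {len(result.vector_set)}")
    print(f"threshold 1: p={top.precision:.3f} r={top.recall:.3f} f={top.f_score:.3f}")
    print("artifacts:", sorted(p.name for p in (Path(tmp) / "out").iterdir()))

# The evaluation.tsv artifact holds the full threshold curve; an
# identical config and seed reproduces it byte for byte.
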
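# Methods

This note documents the model, the numerical and design choices, what
the synthetic data generator does and does not emulate, and the known
limitations. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The normalization model

A mention *m* (a surface string recognized by an upstream NER system) is
mapped to concepts of an entity dictionary in three stages.

1. **Exact match.** If *m* equals a preferred name or synonym under the
   surface normalization (casefold + whitespace collapse), the matching
   concept IDs are assigned directly with score 1.0 and the similarity
   machinery is never consulted. Ambiguous surfaces return every
   matching ID; the evaluator treats a mention as correct when any
   returned ID is a gold ID (configurable in spirit via the
   `first_hit` evaluation mode; see below). Hyphens are discriminative
   by default; `ignore_hyphens=True` treats them as spaces (exposed
   because punctuation conventions vary across vocabularies, off
   because there is no evidence the stricter form loses matches on the
   fixtures).

2. **Abbreviation resolution.** When an abbreviation table is supplied,
   `(doc_id, surface)` is looked up first; a global fallback applies
   only when a short form has exactly one long form — an ambiguous
   acronym like "AS" (Angelman Syndrome / Ankylosing Spondylitis)
   passes through unchanged. Omitting the table (the plant setting)
   simply skips this stage; resolution is a pure pre-transformation and
   cannot affect mentions absent from the table.

3. **Similarity ranking.** The mention vector is the token average
   v_m = (1/n) Σ v_{m_i}, with the zero vector for out-of-vocabulary
   tokens and the divisor fixed at the full token count n; a
   single-token in-vocabulary mention uses its vector verbatim. Every
   dictionary name is indexed in underscore-joined display form, both
   plain and per-token Porter-stemmed; a name whose underscore-joined
   token has a trained vector uses it, otherwise the name is vectorized
   by the same token-average rule, and names whose tokens are all OOV
   are kept in the index but flagged unrankable. Candidates are sorted
   by descending cosine with a deterministic (name, concept_id)
   tie-break. An all-OOV mention cannot be ranked and yields an empty
   candidate list with a diagnostic rather than an arbitrary guess.

The candidate list is name-level (several candidates may share a
concept); `concept_level()` provides the collapsed view keeping each
concept's best-scoring name.

## Corpus augmentation

Augmentation makes the method's premise literal: for each mention in a
sentence, one rewrite per applicable substitution — each synonym of the
mention's concept(s) (resolved by gold ID in labeled text, by exact
lookup in unlabeled text, with ambiguous mentions expanding over the
union of matches), the underscore-joined form of each name, and
per-token Porter stems. One substitution per generated sentence; no
cross-product over mentions (it explodes combinatorially and adds no
new co-occurrence pairs). The original sentence always comes first;
duplicates are dropped; output is capped at
`max_expansions_per_sentence` (default 50) sentences. Dictionary names
whose underscore-joined token never occurs in the assembled text are
injected as minimal sentences containing the name and its joined form,
so every concept name is rankable.

Unlabeled text is organized into the four nested groups — all
abstracts, entity abstracts, evidence sentences, modified evidence
sentences — and six regimes combine them with the (always-augmented)
training corpus, from `sl_only_training` to `ssl_modified_evidences`
and `ssl_only_modified_evidences`.

The Porter stemmer is a direct transcription of the classic algorithm,
verified against published reference outputs. One published worked
example around "metabolism" lists "metabolite" among the shared-stem
variants; under the reference algorithm "metabolite" stems to
"metabolit" (no step-4 suffix applies) while metabolism / metabolic /
metabolize share "metabol". The implementation follows the reference
algorithm, and the tests assert the genuinely shared-stem grouping.

No lowercasing or stop-word removal is applied before embedding
training: candidate vocabularies are mixed-case by construction
(stemmed forms are lowercase, unstemmed forms preserve dictionary
case), and case distinctions cost nothing at fixture scale.

## The embedding trainer

The trainer implements the standard word2vec objectives with negative
sampling: unigram^0.75 noise distribution, frequent-word subsampling
(threshold `sample=1e-3`, the word2vec default; 0 disables), dynamic
window (radius uniform in 1..window per position), linearly decaying
learning rate (initial 0.025 for skip-gram, 0.05 for CBOW), 5 negatives
and 5 epochs by default. `min_count` defaults to 1 because the corpora
this package targets are small enough that every token matters.
Skip-gram gradients are batched per sentence against a common parameter
snapshot and accumulated with `np.add.at`; CBOW updates are applied per
center word with context-mean averaging. Training is single-threaded
and fully deterministic given (corpus, params, seed) — the determinism
contract is part of the test suite, and byte-identical pipeline reruns
depend on it.

Named presets: `default` (CBOW, window 8, dim 200), `disease`
(skip-gram, window 5, dim 300), `plant` (CBOW, window 7, dim 200) — the
configurations appropriate for full-scale disease and plant corpora —
and `fixture` (skip-gram, window 5, dim 50, 15 epochs), the
small-corpus analogue used for the synthetic studies: dimension and
epochs are scaled to corpora of 10^3–10^4 sentences, where 200+
dimensions would be badly underdetermined. Vectors round-trip through
the word2vec text format at < 1e-6 absolute error (values printed with
8 decimals, float32 storage).

## The synthetic data generator

`simulate.FixtureSpec` defines a complete study: a dictionary of
`n_concepts` concepts (multi-word pseudo-word names, 3 synonyms each,
one an acronym when `abbreviation_rate > 0`), a gold-annotated
train/test corpus, unlabeled abstracts with recognized-but-unnormalized
mentions, and a document-scoped abbreviation table, all emitted in the
pipeline's own file formats. Default conditions: 40 training / 30 test
/ 100 unlabeled documents of 4 sentences, mention count per document
Poisson with mean 3 (at least 1, at most one per sentence), background
vocabulary of 500 Zipf-distributed words, 8 private topic words per
concept, 8 context words per sentence.

The central knob is `context_overlap`: the probability that a context
word in a sentence about concept *c* comes from *c*'s topic vocabulary
rather than the shared background. Each concept also has two *informal
aliases* built from fresh tokens that appear in no dictionary name and
nowhere in the training corpus; they occur only in the unlabeled text
(each alias exactly `variant_occurrences=4` times, truncated only if
the unlabeled corpus runs out of mention slots). Test mentions use
these aliases at rate `oov_rate` — such mentions cannot exact-match and
cannot be resolved by any lexical rule, so their normalization measures
pure context-based recovery. An earlier design derived aliases from the
concepts' own name tokens; that leaks a lexical signal through the
substitution rewrites and makes the zero-overlap condition recoverable,
so it was replaced — with fresh tokens, zero overlap leaves similarity
ranking statistically at chance (1/`n_concepts`), which the acceptance
suite verifies with a pooled binomial band over 5 seeds.

What the generator does **not** emulate: real biomedical morphology
(pseudo-words stem to themselves, so stem variants are exercised by the
generic head nouns and the hand-built fixtures rather than the
simulation), polysemy and cross-concept ambiguity, discontinuous or
overlapping mentions, NER errors (recognized spans are always correct),
and realistic document length or discourse structure. Passing the
end-to-end tests therefore shows that the pipeline recovers controlled
synonym/context structure, not that it attains any particular accuracy
on real corpora; full-scale results additionally require real
vocabularies (MEDIC, NCBI taxonomy) and millions of abstracts.

## Evaluation

At threshold *k*, each non-exact mention contributes one TP per correct
candidate and one FP per incorrect candidate within the top *k*, and
one FN if no candidate within *k* is correct; an exact-matched mention
contributes one TP when correct (a single assigned ID, no FPs at any
threshold) and one FN otherwise. Every incorrect candidate above the
threshold counts as an FP even below a correct one — positives are all
candidates above the threshold; the alternative `first_hit=True` mode
stops counting at the first correct candidate and is off by default. A
mention with several gold IDs (composite annotations) counts as TP on
any hit. Alias IDs (e.g. the OMIM ID of a merged vocabulary row)
resolve to their primary concept before judgement. Recall is
non-decreasing in the threshold by construction, which the curve tests
assert on random prediction matrices.

## Numerical and degenerate-input conventions

* Cosine of a zero-norm vector is −inf (an ordering key), so OOV
  vectors always rank last; finite cosines are clipped to [−1, 1].
* Ties in cosine break lexicographically on (name, concept_id).
* Offsets are 0-based half-open over `title + " " + abstract`; a
  mention whose surface mismatches its slice is a parse error.
* Sentence splitting is rule-based (`. `, `? `, `! `) with an
  abbreviation guard (e.g. `e.g.`, `Fig.`, `et al.`, single capitals,
  so `A. thaliana` survives); a mention spanning a detected boundary
  merges the adjacent sentences. The title is always one sentence and
  is included in evidence sentences.
* An empty candidate index, an empty corpus, or a non-positive
  dimension/threshold raise errors; an empty lookup result is a valid
  outcome, not an error.

## Problem sizes used by the shipped studies

The acceptance suite and `scripts/acceptance.py` run the default
conditions above: about 5,500–6,000 augmented training sentences and a
700-token vocabulary per regime, 50-dimensional skip-gram vectors, a
~230-entry candidate index, and 70–80 test mentions per run (15–25 of
them on the similarity path). These sizes were chosen as the smallest
at which the co-occurrence statistics are stable across seeds; the
library itself has no scale-specific code paths and the presets above
are the intended settings for full-size corpora.

## Known limitations

* The exact-match path trusts the dictionary: a surface that is a
  synonym of the wrong concept cannot be rescued by context.
* Mention tokenization keeps internal hyphens; vocabularies that
  hyphenate differently from the corpus need `ignore_hyphens` or
  upstream normalization.
* The bundled trainer is single-threaded; corpora beyond ~10^7 tokens
  will be slow and are better served by an external word2vec
  implementation writing the same text vector format, which
  `load_vectors` consumes unchanged.
* No automatic abbreviation detection (only table lookup) and no
  cross-sentence coreference.
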
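# bionorm

Entity-name **normalization** for biomedical text: mapping recognized
mentions of diseases and plants (e.g. `"C7 defects"`, `"thale cress"`) to
canonical dictionary concept identifiers (`OMIM:610102`,
`NCBITaxon:3702`). Dictionaries are never complete — biological names
have many synonyms, lexical variants and ad-hoc acronyms — so bionorm
combines a dictionary-based exact-match path with word-embedding
similarity learned from labeled *and unlabeled* text.

It is aimed at text-mining practitioners who already run a named-entity
recognizer (BANNER, LingPipe, a dictionary matcher) and need the next
step: assigning concept IDs to the recognized surface strings.

## Method

**Training.** Sentences from an annotated corpus and from unlabeled
abstracts (with NER-recognized mentions) are augmented: every mention is
rewritten with each dictionary synonym of its concept, the
underscore-joined single-token form of each multi-word name
(`breast cancer → breast_cancer`), and per-token Porter stem variants
(`C7 deficiency → c7 defici`); dictionary names missing from the text
are injected. Word vectors are then trained with word2vec-style CBOW or
skip-gram with negative sampling, maximizing the average log probability

```
CBOW:      (1/T) Σ_t log p(w_t | w_{t−c/2}, …, w_{t−1}, w_{t+1}, …, w_{t+c/2})
skip-gram: (1/T) Σ_t log p(w_{t−c/2}, …, w_{t+c/2} | w_t)
```

over the augmented corpus, yielding a vector set *V*. Because synonym
substitution places all names of a concept into identical contexts, the
names end up close in the vector space.

**Prediction.** A mention that exactly matches a dictionary name (case-
and whitespace-insensitive) is assigned directly. Otherwise acronyms are
expanded through a document-scoped abbreviation table, and the mention
vector is the token average

```
v_m = (1/n) Σ_i v_{m_i}
```

with the zero vector for out-of-vocabulary tokens (the divisor stays
*n*). Every dictionary name — underscore-joined and stemmed forms
included — is scored by cosine similarity and the top-*k* names are
returned as ranked candidates.

**Evaluation.** At rank threshold *k*, every candidate ranked ≤ *k* is a
positive prediction; a candidate is correct iff its concept ID is the
mention's gold ID. With TP/FP/FN counted per candidate (exact matches
contribute exactly one TP),

```
p = TP/(TP+FP)   r = TP/(TP+FN)   f = 2pr/(p+r).
```

Six training regimes are provided, from supervised-only
(`sl_only_training`) through semi-supervised with all abstracts, entity
abstracts, evidence sentences, and modified evidence sentences
(`ssl_modified_evidences`, the strongest configuration).

## Worked example

`examples/03_train_and_rank.py` generates a synthetic study (10
concepts), trains the semi-supervised regime, and ranks candidates for a
held-out informal alias that occurs in neither the dictionary nor the
training corpus:

```
training sentences: 2393
vocabulary: 491 tokens, dimension 50

query alias: 'borugo gonose disorder'  (gold concept: FIX:0002)
rank  candidate name                      concept     cosine
*1    vitome_lurasa_disease               FIX:0002    0.9264
*2    vks2                                FIX:0002    0.9245
*3    VKS2                                FIX:0002    0.9235
*4    kaduri_tisofu_defici                FIX:0002    0.9218
*5    kaduri_tisofu_deficiency            FIX:0002    0.9214
```

Starred rows belong to the gold concept: although the alias was never
seen with a label, its tokens share contexts with the concept's names,
so all five top candidates (a synonym, the acronym in both cases, and a
stemmed/unstemmed name pair) are correct. The other examples cover
dictionary lookup, sentence augmentation, the evaluation curve and the
file-driven pipeline; each prints a short explanation of its output.

A shell interface wraps the same functions:

```sh
bionorm simulate --seed 42 --out data/
bionorm augment  --corpus data/train.pubtator --dictionary data/dictionary.tsv \
                 --unlabeled data/unlabeled.pubtator --out sentences.txt
bionorm train    --sentences sentences.txt --preset disease --out vectors.txt
bionorm normalize --vectors vectors.txt --dictionary data/dictionary.tsv \
                  --corpus data/test.pubtator --abbrev data/abbreviations.tsv \
                  --out predictions.tsv
bionorm evaluate --vectors vectors.txt --dictionary data/dictionary.tsv \
                 --corpus data/test.pubtator --out curve.tsv
```

`--preset disease` is skip-gram, window 5, dimension 300; `--preset
plant` is CBOW, window 7, dimension 200; the generic default is CBOW,
window 8, dimension 200.

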
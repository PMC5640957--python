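"""Rewrite a training sentence with dictionary synonyms and variants.

For each mention, augmentation emits one new sentence per applicable
substitution: each synonym of the mention's concept, its
underscore-joined single-token form, and per-token Porter stems. These
rewrites are what ties synonym vectors together during embedding
training.
"""

from bionorm import AugmentationConfig, Concept, EntityDictionary, expand_sentence
from bionorm.corpus import Mention

dictionary = EntityDictionary(
    [Concept("OMIM:119300", "Van der Woude syndrome", synonyms={"lip pits"})]
)
sentence = "Affected males and females are equally likely to transmit VWS."
mention = Mention(
    doc_id="4019732",
    start=sentence.index("VWS"),
    end=sentence.index("VWS") + 3,
    surface="VWS",
    gold_concept_ids={"OMIM:119300"},
)

config = AugmentationConfig(use_stem_variants=False)
for line in expand_sentence(sentence, [mention], dictionary, config):
    print(line)

# The original sentence comes first, followed by the synonym
# substitutions in plain and underscore-joined form — four rewrites for
# a concept with one preferred name and one synonym.
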
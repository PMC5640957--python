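"""Build an entity dictionary and resolve surfaces by exact match.

Dictionaries map surface forms (preferred names + synonyms) to concept
identifiers; exact lookup is case- and whitespace-insensitive and keeps
ambiguity (a surface shared by two concepts returns both IDs).
"""

from bionorm import Concept, EntityDictionary

dictionary = EntityDictionary(
    [
        Concept(
            "OMIM:610102",
            "COMPLEMENT COMPONENT 7 DEFICIENCY",
            synonyms={"C7 deficiency", "C7D"},
        ),
        Concept(
            "MESH:D007153",
            "Immunologic Deficiency Syndromes",
            synonyms={"antibody deficiency syndrome"},
        ),
        Concept("MESH:D001321", "Autism", synonyms={"AD"}),
        Concept("MESH:D000544", "Alzheimer Disease", synonyms={"AD"}),
    ]
)

for surface in ("c7 DEFICIENCY", "C7D", "AD", "no such disease"):
    print(f"{surface!r:25s} -> {sorted(dictionary.lookup_exact(surface))}")

# Expected output: the first two surfaces resolve to OMIM:610102 despite
# case/spacing differences; "AD" is ambiguous and returns both concepts;
# an unknown surface returns an empty list.
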
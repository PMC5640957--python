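"""Entity dictionaries: loading, indexing and exact-surface lookup.

Three dialects are supported:

* MEDIC-style TSV — the merged MeSH-Diseases + OMIM disease vocabulary
  layout (``#`` comments; pipe-delimited multi-value fields),
* NCBI taxonomy dumps — ``names.dmp`` / ``nodes.dmp`` with fields
  separated by ``\\t|\\t`` and records ending ``\\t|``, filtered to the
  subtree under a chosen root (e.g. Viridiplantae for plant names),
* a generic 3-column TSV (``concept_id  name  name_type``) used by the
  synthetic fixtures.

Lookup is exact-match under a configurable surface normalization
(case-insensitive, whitespace-collapsed by default); an ambiguous surface
returns every matching concept ID.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, TextIO

from .text import normalize_surface


class DictionarySource(Enum):
    MEDIC = "medic"
    TAXONOMY = "taxonomy"
    GENERIC = "generic"


@dataclass
class Concept:
    """A dictionary entry: one normalization target.

    ``preferred_name`` is stored once and never duplicated in
    ``synonyms``; ``alt_ids`` are alternate identifiers (e.g. the OMIM id
    of a merged MEDIC row) that resolve to this concept.
    """

    concept_id: str
    preferred_name: str
    synonyms: set[str] = field(default_factory=set)
    parent_ids: set[str] = field(default_factory=set)
    alt_ids: set[str] = field(default_factory=set)
    source: DictionarySource = DictionarySource.GENERIC

    def __post_init__(self) -> None:
        if not self.concept_id:
            raise ValueError("concept_id must be non-empty")
        if not self.preferred_name.strip():
            raise ValueError(f"{self.concept_id}: empty preferred name")
        self.synonyms = {
            s for s in (syn.strip() for syn in self.synonyms)
            if s and normalize_surface(s) != normalize_surface(self.preferred_name)
        }

    def names(self) -> list[str]:
        """Preferred name first, then synonyms in sorted order."""
        return [self.preferred_name, *sorted(self.synonyms)]


class EntityDictionary:
    """A set of concepts with an exact-match surface index.

    The surface index maps every normalized preferred name and synonym to
    the set of concept IDs carrying it; ambiguity is preserved, not
    resolved.
    """

    def __init__(
        self,
        concepts: Iterable[Concept] = (),
        *,
        ignore_hyphens: bool = False,
    ) -> None:
        self.ignore_hyphens = ignore_hyphens
        self.concepts: dict[str, Concept] = {}
        self._surface_index: dict[str, set[str]] = {}
        self._alias: dict[str, str] = {}
        for concept in concepts:
            self.add(concept)

    def __len__(self) -> int:
        return len(self.concepts)

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self.concepts

    def __getitem__(self, concept_id: str) -> Concept:
        return self.concepts[self.resolve_alias(concept_id)]

    def _norm(self, surface: str) -> str:
        return normalize_surface(surface, ignore_hyphens=self.ignore_hyphens)

    def add(self, concept: Concept) -> None:
        if concept.concept_id in self.concepts:
            raise ValueError(f"duplicate concept_id: {concept.concept_id}")
        self.concepts[concept.concept_id] = concept
        for name in concept.names():
            self._surface_index.setdefault(self._norm(name), set()).add(
                concept.concept_id
            )
        for alt in concept.alt_ids:
            self._alias.setdefault(alt, concept.concept_id)

    def lookup_exact(self, surface: str) -> set[str]:
        """All concept IDs whose preferred name or synonym equals surface
        under the configured normalization. Empty set when no match."""
        return set(self._surface_index.get(self._norm(surface), ()))

    def resolve_alias(self, concept_id: str) -> str:
        """Map an alternate ID to its primary concept ID (identity if
        already primary or unknown)."""
        if concept_id in self.concepts:
            return concept_id
        return self._alias.get(concept_id, concept_id)

    def iter_names(self) -> Iterator[tuple[str, str]]:
        """Yield (name, concept_id) pairs in deterministic order:
        concepts sorted by ID, preferred name first, synonyms sorted."""
        for cid in sorted(self.concepts):
            for name in self.concepts[cid].names():
                yield name, cid

    def all_names(self) -> list[str]:
        return [name for name, _ in self.iter_names()]


# ---------------------------------------------------------------------------
# MEDIC-style TSV

def load_medic_tsv(path: str | Path, *, ignore_hyphens: bool = False) -> EntityDictionary:
    """Load a MEDIC-style disease vocabulary.

    Expected columns (tab-separated, ``#`` comment lines ignored):
    name, ID, alternate IDs, definition, parent IDs, [tree numbers,
    parent tree numbers,] synonyms. Both the 6-column minimal layout and
    the 8-column CTD layout are accepted; multi-value fields are
    pipe-delimited.
    """
    dictionary = EntityDictionary(ignore_hyphens=ignore_hyphens)
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(
                    f"{path}:{lineno}: expected at least 6 tab-separated "
                    f"columns, got {len(fields)}"
                )
            name, cid, alt_raw, _definition, parents_raw = fields[:5]
            syn_raw = fields[7] if len(fields) >= 8 else fields[5]
            concept = Concept(
                concept_id=cid.strip(),
                preferred_name=name.strip(),
                synonyms=_split_multi(syn_raw),
                parent_ids=_split_multi(parents_raw),
                alt_ids=_split_multi(alt_raw),
                source=DictionarySource.MEDIC,
            )
            try:
                dictionary.add(concept)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return dictionary


def _split_multi(raw: str) -> set[str]:
    return {part.strip() for part in raw.split("|") if part.strip()}


# ---------------------------------------------------------------------------
# NCBI taxonomy dumps

def _read_dmp(path: str | Path) -> Iterator[list[str]]:
    """Parse the NCBI dump dialect: fields separated by '\\t|\\t',
    records terminated by '\\t|'."""
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.endswith("\t|"):
                line = line[:-2]
            yield [f.strip() for f in line.split("\t|\t")]


def load_taxonomy_dump(
    names_path: str | Path,
    nodes_path: str | Path,
    root_taxid: str,
    *,
    id_prefix: str = "NCBITaxon:",
    ignore_hyphens: bool = False,
) -> EntityDictionary:
    """Build a dictionary from taxonomy name/node dumps, keeping only the
    subtree rooted at ``root_taxid``.

    Rows of name class "scientific name" become preferred names; all other
    classes (synonym, common name, equivalent name, ...) become synonyms.
    Taxa without a scientific name are skipped with a warning.
    """
    parent: dict[str, str] = {}
    for fields in _read_dmp(nodes_path):
        if len(fields) < 2:
            continue
        parent[fields[0]] = fields[1]
    if root_taxid not in parent:
        raise ValueError(f"root taxid {root_taxid!r} not present in {nodes_path}")

    children: dict[str, list[str]] = {}
    for taxid, par in parent.items():
        if taxid != par:  # the dump's root is its own parent
            children.setdefault(par, []).append(taxid)
    keep: set[str] = set()
    queue = deque([root_taxid])
    while queue:
        node = queue.popleft()
        if node in keep:
            continue
        keep.add(node)
        queue.extend(children.get(node, ()))

    scientific: dict[str, str] = {}
    synonyms: dict[str, set[str]] = {}
    for fields in _read_dmp(names_path):
        if len(fields) < 4:
            continue
        taxid, name_txt, _unique, name_class = fields[:4]
        if taxid not in keep or not name_txt:
            continue
        if name_class == "scientific name":
            scientific[taxid] = name_txt
        else:
            synonyms.setdefault(taxid, set()).add(name_txt)

    dictionary = EntityDictionary(ignore_hyphens=ignore_hyphens)
    for taxid in sorted(keep, key=lambda t: (len(t), t)):
        if taxid not in scientific:
            warnings.warn(
                f"taxid {taxid} has no scientific name; skipped", stacklevel=2
            )
            continue
        par = parent[taxid]
        dictionary.add(
            Concept(
                concept_id=f"{id_prefix}{taxid}",
                preferred_name=scientific[taxid],
                synonyms=synonyms.get(taxid, set()),
                parent_ids={f"{id_prefix}{par}"} if par != taxid else set(),
                source=DictionarySource.TAXONOMY,
            )
        )
    return dictionary


# ---------------------------------------------------------------------------
# Generic 3-column TSV (concept_id, name, name_type)

def load_generic_tsv(path: str | Path, *, ignore_hyphens: bool = False) -> EntityDictionary:
    """Load the generic fixture dialect: ``concept_id TAB name TAB
    name_type`` where name_type is ``preferred`` or ``synonym``."""
    preferred: dict[str, str] = {}
    synonyms: dict[str, set[str]] = {}
    order: list[str] = []
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 columns, got {len(fields)}"
                )
            cid, name, name_type = (f.strip() for f in fields)
            if cid not in preferred and cid not in synonyms:
                order.append(cid)
            if name_type == "preferred":
                if cid in preferred:
                    raise ValueError(
                        f"{path}:{lineno}: duplicate preferred name for {cid}"
                    )
                preferred[cid] = name
            elif name_type == "synonym":
                synonyms.setdefault(cid, set()).add(name)
            else:
                raise ValueError(f"{path}:{lineno}: unknown name_type {name_type!r}")
    dictionary = EntityDictionary(ignore_hyphens=ignore_hyphens)
    for cid in order:
        if cid not in preferred:
            raise ValueError(f"{path}: concept {cid} has no preferred name row")
        dictionary.add(
            Concept(
                concept_id=cid,
                preferred_name=preferred[cid],
                synonyms=synonyms.get(cid, set()),
                source=DictionarySource.GENERIC,
            )
        )
    return dictionary


def write_generic_tsv(dictionary: EntityDictionary, handle: TextIO) -> None:
    for cid in sorted(dictionary.concepts):
        concept = dictionary.concepts[cid]
        handle.write(f"{cid}\t{concept.preferred_name}\tpreferred\n")
        for syn in sorted(concept.synonyms):
            handle.write(f"{cid}\t{syn}\tsynonym\n")
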
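"""Mention normalization: exact-match shortcut, abbreviation resolution,
mention vectorization and cosine ranking over dictionary concept names.

The prediction path per mention:

1. exact match — a mention equal (under surface normalization) to a
   dictionary name is assigned directly with score 1.0; no similarity
   ranking is performed;
2. abbreviation resolution (optional) — acronyms are replaced by their
   document-scoped long form before any matching;
3. similarity ranking — the mention vector is the average of its token
   vectors (OOV tokens contribute the zero vector, the divisor stays the
   full token count) and every rankable dictionary name is scored by
   cosine; the top-k names are returned in descending order with a
   deterministic (name, concept_id) tie-break.

A mention whose tokens are all OOV has the zero vector and cannot be
ranked: it yields an empty candidate list with a diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import numpy as np

from .corpus import Document, Mention
from .dictionary import EntityDictionary
from .embedding import VectorSet
from .stemming import stem_name
from .text import tokenize, underscore_join


# ---------------------------------------------------------------------------
# Abbreviation dictionary

class AbbreviationDictionary:
    """Document-scoped acronym -> long-form table, with a global
    fallback used only when a short form has exactly one long form."""

    def __init__(self) -> None:
        self.entries: dict[tuple[str, str], str] = {}
        self.global_forms: dict[str, set[str]] = {}

    def add(self, doc_id: str, short_form: str, long_form: str) -> None:
        if not short_form:
            raise ValueError("empty short form")
        self.entries[(doc_id, short_form)] = long_form
        self.global_forms.setdefault(short_form, set()).add(long_form)

    def __len__(self) -> int:
        return len(self.entries)

    def resolve(self, doc_id: str, surface: str) -> str:
        """Document-scoped long form when present; else the global long
        form when unique; else the surface unchanged (e.g. "AS" with two
        competing long forms stays "AS")."""
        hit = self.entries.get((doc_id, surface))
        if hit is not None:
            return hit
        forms = self.global_forms.get(surface)
        if forms is not None and len(forms) == 1:
            return next(iter(forms))
        return surface

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AbbreviationDictionary":
        """Load ``doc_id TAB short_form TAB long_form`` rows."""
        out = cls()
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
                out.add(*[f.strip() for f in fields])
        return out

    def to_tsv(self, handle: TextIO) -> None:
        for (doc_id, short), long_form in sorted(self.entries.items()):
            handle.write(f"{doc_id}\t{short}\t{long_form}\n")


def resolve_abbreviation(
    mention: Mention, abbreviations: AbbreviationDictionary
) -> str:
    """The mention surface with its acronym expanded, if resolvable."""
    return abbreviations.resolve(mention.doc_id, mention.surface)


# ---------------------------------------------------------------------------
# Mention vectorization

def vectorize_mention(surface: str, vectors: VectorSet) -> np.ndarray:
    """Average of token vectors; OOV tokens contribute the zero vector
    and the divisor is the full token count. A single in-vocabulary
    token returns its vector verbatim; an all-OOV mention returns the
    zero vector."""
    tokens = tokenize(surface)
    if not tokens:
        raise ValueError(f"surface {surface!r} has no tokens")
    if len(tokens) == 1:
        v = vectors.get(tokens[0])
        if v is not None:
            return np.asarray(v, dtype=np.float64)
        return np.zeros(vectors.dimension)
    acc = np.zeros(vectors.dimension)
    for tok in tokens:
        v = vectors.get(tok)
        if v is not None:
            acc += np.asarray(v, dtype=np.float64)
    return acc / len(tokens)


# ---------------------------------------------------------------------------
# The normalization model

@dataclass(frozen=True)
class Candidate:
    rank: int
    name: str
    concept_id: str
    score: float


@dataclass(frozen=True)
class NameEntry:
    """One row of the candidate index: a display form of a dictionary
    name (underscore-joined, possibly stemmed) tied to its concept."""

    display: str
    concept_id: str
    source_name: str
    stemmed: bool
    rankable: bool


@dataclass
class NormalizationResult:
    surface: str
    resolved_surface: str
    exact_match: bool
    candidates: list[Candidate]
    diagnostic: str = ""


class NormalizationModel:
    """Vector set + dictionary + candidate-name index.

    The index covers every preferred name and synonym, in plain and
    per-token-stemmed form, displayed underscore-joined. A name's vector
    is the underscore-joined token's vector when that token is in V,
    otherwise the token-average of its constituent tokens; names whose
    tokens are all OOV are retained but flagged unrankable.
    """

    def __init__(
        self,
        vector_set: VectorSet,
        dictionary: EntityDictionary,
        abbreviations: AbbreviationDictionary | None = None,
        *,
        include_stemmed: bool = True,
    ) -> None:
        self.vector_set = vector_set
        self.dictionary = dictionary
        self.abbreviations = abbreviations
        self.name_index: list[NameEntry] = []
        vecs: list[np.ndarray] = []

        seen: set[tuple[str, str]] = set()
        for name, cid in dictionary.iter_names():
            forms = [(name, False)]
            if include_stemmed:
                stemmed = stem_name(name)
                if stemmed != name:
                    forms.append((stemmed, True))
            for form, is_stemmed in forms:
                display = underscore_join(form)
                if (display, cid) in seen:
                    continue
                seen.add((display, cid))
                vec = self._name_vector(form, display)
                rankable = vec is not None
                self.name_index.append(
                    NameEntry(
                        display=display,
                        concept_id=cid,
                        source_name=name,
                        stemmed=is_stemmed,
                        rankable=rankable,
                    )
                )
                vecs.append(
                    vec if vec is not None else np.zeros(vector_set.dimension)
                )

        self._rankable_rows = [
            i for i, e in enumerate(self.name_index) if e.rankable
        ]
        matrix = (
            np.vstack([vecs[i] for i in self._rankable_rows])
            if self._rankable_rows
            else np.zeros((0, vector_set.dimension))
        )
        norms = np.linalg.norm(matrix, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        self._unit_matrix = matrix / norms

    def _name_vector(self, form: str, display: str) -> np.ndarray | None:
        joined_vec = self.vector_set.get(display)
        if joined_vec is not None:
            return np.asarray(joined_vec, dtype=np.float64)
        vec = vectorize_mention(form, self.vector_set)
        if not vec.any():
            return None
        return vec

    # -- ranking -----------------------------------------------------------

    def rank_candidates(self, surface: str, k: int = 10) -> NormalizationResult:
        """Ranked candidates for a (possibly already abbreviation-
        resolved) surface. Exact dictionary matches short-circuit the
        similarity path entirely."""
        if k < 1:
            raise ValueError("k must be >= 1")
        exact_ids = self.dictionary.lookup_exact(surface)
        if exact_ids:
            candidates = [
                Candidate(rank=i + 1, name=surface, concept_id=cid, score=1.0)
                for i, cid in enumerate(sorted(exact_ids))
            ]
            return NormalizationResult(
                surface=surface,
                resolved_surface=surface,
                exact_match=True,
                candidates=candidates,
            )

        v = vectorize_mention(surface, self.vector_set)
        norm = float(np.linalg.norm(v))
        if norm == 0.0:
            return NormalizationResult(
                surface=surface,
                resolved_surface=surface,
                exact_match=False,
                candidates=[],
                diagnostic="all mention tokens are out of vocabulary",
            )
        scores = self._unit_matrix @ (v / norm)
        order = sorted(
            range(len(self._rankable_rows)),
            key=lambda i: (
                -scores[i],
                self.name_index[self._rankable_rows[i]].display,
                self.name_index[self._rankable_rows[i]].concept_id,
            ),
        )
        candidates = []
        for rank, i in enumerate(order[:k], start=1):
            entry = self.name_index[self._rankable_rows[i]]
            candidates.append(
                Candidate(
                    rank=rank,
                    name=entry.display,
                    concept_id=entry.concept_id,
                    score=float(scores[i]),
                )
            )
        return NormalizationResult(
            surface=surface,
            resolved_surface=surface,
            exact_match=False,
            candidates=candidates,
        )

    def normalize_mention(self, mention: Mention, k: int = 10) -> NormalizationResult:
        surface = mention.surface
        if self.abbreviations is not None:
            surface = resolve_abbreviation(mention, self.abbreviations)
        result = self.rank_candidates(surface, k)
        result.surface = mention.surface
        result.resolved_surface = surface
        return result


def concept_level(candidates: Sequence[Candidate]) -> list[Candidate]:
    """Concept-level view of a name-level list: each concept keeps its
    best-scoring name; ranks are renumbered."""
    best: dict[str, Candidate] = {}
    for cand in candidates:
        if cand.concept_id not in best:
            best[cand.concept_id] = cand
    out = sorted(best.values(), key=lambda c: c.rank)
    return [
        Candidate(rank=i + 1, name=c.name, concept_id=c.concept_id, score=c.score)
        for i, c in enumerate(out)
    ]


# ---------------------------------------------------------------------------
# Corpus-level prediction

@dataclass
class PredictionRecord:
    doc_id: str
    mention: Mention
    result: NormalizationResult
    error: str = ""

    @property
    def candidates(self) -> list[Candidate]:
        return self.result.candidates

    @property
    def exact_match(self) -> bool:
        return self.result.exact_match

    @property
    def gold_concept_ids(self) -> set[str]:
        return self.mention.gold_concept_ids


def normalize_corpus(
    documents: Iterable[Document],
    model: NormalizationModel,
    k: int = 10,
) -> list[PredictionRecord]:
    """Normalize every mention of every document. Per-mention failures
    are recorded, never propagated: one bad mention cannot abort a
    corpus run."""
    records: list[PredictionRecord] = []
    for doc in documents:
        for mention in doc.mentions:
            try:
                result = model.normalize_mention(mention, k)
                records.append(
                    PredictionRecord(doc_id=doc.doc_id, mention=mention, result=result)
                )
            except Exception as exc:  # noqa: BLE001 - contract: never abort
                records.append(
                    PredictionRecord(
                        doc_id=doc.doc_id,
                        mention=mention,
                        result=NormalizationResult(
                            surface=mention.surface,
                            resolved_surface=mention.surface,
                            exact_match=False,
                            candidates=[],
                            diagnostic=str(exc),
                        ),
                        error=str(exc),
                    )
                )
    return records


def write_predictions_tsv(records: Iterable[PredictionRecord], handle: TextIO) -> None:
    """doc_id, start, end, surface, rank, name, concept_id, score,
    exact_match — one row per candidate (or one row with empty candidate
    fields for unrankable mentions)."""
    for rec in records:
        m = rec.mention
        prefix = f"{rec.doc_id}\t{m.start}\t{m.end}\t{m.surface}"
        if not rec.candidates:
            handle.write(f"{prefix}\t\t\t\t\t{int(rec.exact_match)}\n")
            continue
        for cand in rec.candidates:
            handle.write(
                f"{prefix}\t{cand.rank}\t{cand.name}\t{cand.concept_id}"
                f"\t{cand.score:.6f}\t{int(rec.exact_match)}\n"
            )
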
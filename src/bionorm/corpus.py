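"""Annotated corpora: PubTator I/O, sentence splitting, summary statistics.

A :class:`Document` is a title + abstract with character-offset entity
mentions (0-based, half-open, over ``title + " " + abstract``). The same
model serves labeled corpora (gold concept IDs attached) and unlabeled
text from upstream NER (empty gold ID sets).

The PubTator dialect: blocks of ``PMID|t|title`` and ``PMID|a|abstract``
lines followed by tab-separated annotation lines
``PMID  start  end  surface  type  concept_ids``, blocks separated by a
blank line. Composite concept IDs joined by ``|`` or ``+`` are split into
the ID set.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence, TextIO


class EntityType(Enum):
    DISEASE = "Disease"
    PLANT = "Plant"
    OTHER = "Other"

    @classmethod
    def from_label(cls, label: str) -> "EntityType":
        label_cf = label.strip().casefold()
        if label_cf in {"disease", "diseaseclass", "specificdisease", "compositemention", "modifier"}:
            return cls.DISEASE
        if label_cf in {"plant", "species", "taxon", "organism"}:
            return cls.PLANT
        return cls.OTHER


@dataclass
class Mention:
    """A recognized entity surface with character offsets into the
    document text (``title + " " + abstract``)."""

    doc_id: str
    start: int
    end: int
    surface: str
    entity_type: EntityType = EntityType.OTHER
    gold_concept_ids: set[str] = field(default_factory=set)
    raw_type: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"{self.doc_id}: mention end {self.end} <= start {self.start}"
            )
        if not self.raw_type:
            self.raw_type = self.entity_type.value

    def sort_key(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class Document:
    doc_id: str
    title: str
    abstract: str
    mentions: list[Mention] = field(default_factory=list)

    @property
    def text(self) -> str:
        """Concatenated title + single space + abstract (offset base)."""
        if not self.abstract:
            return self.title
        return f"{self.title} {self.abstract}"

    def validate_offsets(self) -> None:
        text = self.text
        for m in self.mentions:
            if m.end > len(text) or text[m.start:m.end] != m.surface:
                raise ValueError(
                    f"{self.doc_id}: mention surface {m.surface!r} does not "
                    f"match text slice [{m.start},{m.end}) "
                    f"{text[m.start:m.end]!r}"
                )


@dataclass
class Sentence:
    doc_id: str
    text: str
    mentions: list[Mention] = field(default_factory=list)

    @property
    def mention_surfaces(self) -> list[str]:
        return [m.surface for m in self.mentions]


# SentenceStream is simply an ordered collection of Sentence records.
SentenceStream = list[Sentence]


# ---------------------------------------------------------------------------
# PubTator reading / writing

_TITLE_RE = re.compile(r"^(?P<pmid>[^|]+)\|t\|(?P<text>.*)$")
_ABSTRACT_RE = re.compile(r"^(?P<pmid>[^|]+)\|a\|(?P<text>.*)$")
_ID_SPLIT_RE = re.compile(r"[|+]")


def split_concept_ids(raw: str) -> set[str]:
    """Split a composite concept-ID field on '|' or '+'; '-1', '-' and
    empty fields mean unlabeled."""
    raw = raw.strip()
    if raw in {"", "-", "-1"}:
        return set()
    return {part.strip() for part in _ID_SPLIT_RE.split(raw) if part.strip()}


def read_pubtator(source: TextIO | str | Path) -> list[Document]:
    """Parse a PubTator stream or file into Documents.

    Raises on a block with no title line and on any annotation whose
    surface does not equal the text slice at its offsets.
    """
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as handle:
            return read_pubtator(handle)

    documents: list[Document] = []
    block: list[str] = []
    for line in source:
        line = line.rstrip("\n")
        if not line.strip():
            if block:
                documents.append(_parse_block(block))
                block = []
        else:
            block.append(line)
    if block:
        documents.append(_parse_block(block))
    return documents


def _parse_block(lines: list[str]) -> Document:
    title_match = _TITLE_RE.match(lines[0])
    if title_match is None:
        raise ValueError(
            f"PubTator block does not start with a 'PMID|t|' line: {lines[0]!r}"
        )
    pmid = title_match.group("pmid")
    title = title_match.group("text")
    abstract = ""
    annotation_lines: list[str] = []
    for line in lines[1:]:
        abstract_match = _ABSTRACT_RE.match(line)
        if abstract_match is not None and "\t" not in line:
            abstract = abstract_match.group("text")
        else:
            annotation_lines.append(line)

    doc = Document(doc_id=pmid, title=title, abstract=abstract)
    for line in annotation_lines:
        fields = line.split("\t")
        if len(fields) < 5:
            raise ValueError(
                f"{pmid}: annotation line has {len(fields)} fields: {line!r}"
            )
        _, start_s, end_s, surface, type_label = fields[:5]
        ids = split_concept_ids(fields[5]) if len(fields) > 5 else set()
        mention = Mention(
            doc_id=pmid,
            start=int(start_s),
            end=int(end_s),
            surface=surface,
            entity_type=EntityType.from_label(type_label),
            gold_concept_ids=ids,
            raw_type=type_label,
        )
        doc.mentions.append(mention)
    doc.mentions.sort(key=Mention.sort_key)
    doc.validate_offsets()
    return doc


def write_pubtator(documents: Iterable[Document], handle: TextIO) -> None:
    for doc in documents:
        handle.write(f"{doc.doc_id}|t|{doc.title}\n")
        handle.write(f"{doc.doc_id}|a|{doc.abstract}\n")
        for m in sorted(doc.mentions, key=Mention.sort_key):
            ids = "|".join(sorted(m.gold_concept_ids))
            handle.write(
                f"{doc.doc_id}\t{m.start}\t{m.end}\t{m.surface}\t{m.raw_type}\t{ids}\n"
            )
        handle.write("\n")


# ---------------------------------------------------------------------------
# Plain abstract streams (unlabeled text without annotations)

def read_plain_abstracts(
    source: TextIO | str | Path, *, id_prefix: str = "doc"
) -> list[Document]:
    """Read unlabeled abstracts: blank-line-separated blocks (or one per
    line) of plain text; each block becomes a Document with an empty
    mention list and a generated ID."""
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as handle:
            return read_plain_abstracts(handle, id_prefix=id_prefix)
    documents: list[Document] = []
    block: list[str] = []

    def flush() -> None:
        if block:
            text = " ".join(block)
            documents.append(
                Document(doc_id=f"{id_prefix}{len(documents) + 1}", title=text, abstract="")
            )
            block.clear()

    for line in source:
        line = line.strip()
        if not line:
            flush()
        else:
            block.append(line)
    flush()
    return documents


# ---------------------------------------------------------------------------
# Sentence splitting

#: Tokens before a period that do not end a sentence.
_ABBREV_GUARDS = {
    "e.g", "i.e", "cf", "vs", "ca", "approx", "fig", "figs", "eq", "eqs",
    "ref", "refs", "et al", "sp", "spp", "subsp", "var", "st", "dr", "no",
}
_BOUNDARY_RE = re.compile(r"[.?!](?=\s)")
_LAST_WORD_RE = re.compile(r"(\S+)\s*$")


def _is_guarded(prefix: str) -> bool:
    """True when the text before a '.' ends with an abbreviation that
    should not close the sentence (e.g. 'e.g.', 'Fig.', 'A.' in
    'A. thaliana')."""
    match = _LAST_WORD_RE.search(prefix)
    if match is None:
        return True
    word = match.group(1)
    if len(word) == 1 and word.isalpha() and word.isupper():
        return True  # single capital: species abbreviations, initials
    word_cf = word.casefold().lstrip("([")
    if word_cf in _ABBREV_GUARDS:
        return True
    if word_cf == "al" and prefix.casefold().rstrip().endswith("et al"):
        return True
    return False


def _sentence_spans(text: str) -> list[tuple[int, int]]:
    spans: list[tuple[int, int]] = []
    start = 0
    for match in _BOUNDARY_RE.finditer(text):
        end = match.end()  # include the punctuation mark
        if match.group(0) == "." and _is_guarded(text[start:match.start()]):
            continue
        spans.append((start, end))
        start = end
        while start < len(text) and text[start].isspace():
            start += 1
    if start < len(text):
        spans.append((start, len(text)))
    return spans


def split_sentences(document: Document) -> SentenceStream:
    """Split a document into sentences, attaching each mention to the
    sentence containing its start offset; a mention spanning a detected
    boundary forces the adjacent sentences to merge.

    The title is always its own sentence (its end is a hard boundary).
    """
    text = document.text
    if not text.strip():
        return []
    title_end = len(document.title)
    spans: list[tuple[int, int]] = []
    if document.abstract:
        for s, e in _sentence_spans(document.title):
            spans.append((s, e))
        offset = title_end + 1  # the single separator space
        for s, e in _sentence_spans(document.abstract):
            spans.append((s + offset, e + offset))
    else:
        spans = _sentence_spans(text)

    # Merge sentences that a mention spans.
    changed = True
    while changed:
        changed = False
        for m in document.mentions:
            for i, (s, e) in enumerate(spans):
                if s <= m.start < e and m.end > e:
                    if i + 1 < len(spans):
                        spans[i] = (s, spans[i + 1][1])
                        del spans[i + 1]
                        changed = True
                    break
            if changed:
                break

    sentences: list[Sentence] = []
    for s, e in spans:
        sent_mentions = [m for m in document.mentions if s <= m.start < e]
        sentences.append(
            Sentence(doc_id=document.doc_id, text=text[s:e], mentions=sent_mentions)
        )
    return sentences


# ---------------------------------------------------------------------------
# Corpus statistics

@dataclass(frozen=True)
class CorpusStats:
    n_documents: int
    n_mentions: int
    n_unique_surfaces: int
    n_unique_concept_ids: int


def corpus_stats(documents: Sequence[Document]) -> CorpusStats:
    """Abstract / mention / unique-surface / unique-concept counts
    (case-sensitive surface uniqueness; concept ID sets flattened)."""
    surfaces: set[str] = set()
    concept_ids: set[str] = set()
    n_mentions = 0
    for doc in documents:
        for m in doc.mentions:
            n_mentions += 1
            surfaces.add(m.surface)
            concept_ids.update(m.gold_concept_ids)
    return CorpusStats(
        n_documents=len(documents),
        n_mentions=n_mentions,
        n_unique_surfaces=len(surfaces),
        n_unique_concept_ids=len(concept_ids),
    )


# ---------------------------------------------------------------------------
# Mention TSV export (doc_id, start, end, surface, predicted/gold IDs)

def write_mention_tsv(documents: Iterable[Document], handle: TextIO) -> None:
    for doc in documents:
        for m in sorted(doc.mentions, key=Mention.sort_key):
            ids = "|".join(sorted(m.gold_concept_ids))
            handle.write(f"{doc.doc_id}\t{m.start}\t{m.end}\t{m.surface}\t{ids}\n")


def iter_sentences(documents: Iterable[Document]) -> Iterator[Sentence]:
    for doc in documents:
        yield from split_sentences(doc)
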
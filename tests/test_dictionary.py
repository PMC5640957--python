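"""Dictionary loading (MEDIC, taxonomy, generic), indexing and lookup."""

from __future__ import annotations

import io
from pathlib import Path

import pytest

from bionorm.dictionary import (
    Concept,
    EntityDictionary,
    load_generic_tsv,
    load_medic_tsv,
    load_taxonomy_dump,
    write_generic_tsv,
)

MEDIC_ROWS = (
    "# MEDIC-style fixture\n"
    "COMPLEMENT COMPONENT 7 DEFICIENCY\tOMIM:610102\tMESH:C536276\tdef\t"
    "MESH:D007153\tC7 deficiency|C7D\n"
    "Immunologic Deficiency Syndromes\tMESH:D007153\t\tdef\t\t"
    "antibody deficiency syndrome\n"
)


@pytest.fixture
def medic_path(tmp_path: Path) -> Path:
    path = tmp_path / "medic.tsv"
    path.write_text(MEDIC_ROWS, encoding="utf-8")
    return path


class TestMedic:
    def test_load_row(self, medic_path: Path) -> None:
        d = load_medic_tsv(medic_path)
        concept = d["OMIM:610102"]
        assert concept.synonyms == {"C7 deficiency", "C7D"}
        assert concept.parent_ids == {"MESH:D007153"}
        assert d.resolve_alias("MESH:C536276") == "OMIM:610102"

    def test_empty_file_is_empty_dictionary(self, tmp_path: Path) -> None:
        path = tmp_path / "empty.tsv"
        path.write_text("# only a comment\n\n", encoding="utf-8")
        assert len(load_medic_tsv(path)) == 0

    def test_duplicate_id_is_hard_error_naming_the_id(self, tmp_path: Path) -> None:
        path = tmp_path / "dup.tsv"
        row = "name\tMESH:D1\t\t\t\tsyn\n"
        path.write_text(row + row, encoding="utf-8")
        with pytest.raises(ValueError, match="MESH:D1"):
            load_medic_tsv(path)

    def test_short_row_reports_line_number(self, tmp_path: Path) -> None:
        path = tmp_path / "bad.tsv"
        path.write_text("only\tthree\tcolumns\n", encoding="utf-8")
        with pytest.raises(ValueError, match=":1"):
            load_medic_tsv(path)


def _write_taxonomy(tmp_path: Path) -> tuple[Path, Path]:
    # 5-node toy tree: 1 (root) -> 33090 (plants) -> {3701 -> 3702, 13333};
    # 9606 hangs off the root outside the plant subtree.
    nodes = tmp_path / "nodes.dmp"
    nodes.write_text(
        "1\t|\t1\t|\tno rank\t|\n"
        "33090\t|\t1\t|\tkingdom\t|\n"
        "3701\t|\t33090\t|\tgenus\t|\n"
        "3702\t|\t3701\t|\tspecies\t|\n"
        "9606\t|\t1\t|\tspecies\t|\n",
        encoding="utf-8",
    )
    names = tmp_path / "names.dmp"
    names.write_text(
        "1\t|\troot\t|\t\t|\tscientific name\t|\n"
        "33090\t|\tViridiplantae\t|\t\t|\tscientific name\t|\n"
        "33090\t|\tgreen plants\t|\t\t|\tcommon name\t|\n"
        "3701\t|\tArabidopsis\t|\t\t|\tscientific name\t|\n"
        "3702\t|\tArabidopsis thaliana\t|\t\t|\tscientific name\t|\n"
        "3702\t|\tthale cress\t|\t\t|\tcommon name\t|\n"
        "3702\t|\tmouse-ear cress\t|\t\t|\tequivalent name\t|\n"
        "9606\t|\tHomo sapiens\t|\t\t|\tscientific name\t|\n",
        encoding="utf-8",
    )
    return names, nodes


class TestTaxonomy:
    def test_subtree_filter_keeps_exactly_reachable_taxa(self, tmp_path: Path) -> None:
        names, nodes = _write_taxonomy(tmp_path)
        d = load_taxonomy_dump(names, nodes, "33090")
        # brute-force reachability from 33090: {33090, 3701, 3702}
        assert set(d.concepts) == {"NCBITaxon:33090", "NCBITaxon:3701", "NCBITaxon:3702"}

    def test_leaf_root_keeps_only_itself(self, tmp_path: Path) -> None:
        names, nodes = _write_taxonomy(tmp_path)
        d = load_taxonomy_dump(names, nodes, "3702")
        assert set(d.concepts) == {"NCBITaxon:3702"}

    def test_name_class_routing(self, tmp_path: Path) -> None:
        names, nodes = _write_taxonomy(tmp_path)
        d = load_taxonomy_dump(names, nodes, "33090")
        at = d["NCBITaxon:3702"]
        assert at.preferred_name == "Arabidopsis thaliana"
        assert at.synonyms == {"thale cress", "mouse-ear cress"}

    def test_missing_root_is_hard_error(self, tmp_path: Path) -> None:
        names, nodes = _write_taxonomy(tmp_path)
        with pytest.raises(ValueError, match="99999"):
            load_taxonomy_dump(names, nodes, "99999")

    def test_taxon_without_scientific_name_is_skipped_with_warning(
        self, tmp_path: Path
    ) -> None:
        names, nodes = _write_taxonomy(tmp_path)
        names.write_text(
            names.read_text(encoding="utf-8").replace(
                "3701\t|\tArabidopsis\t|\t\t|\tscientific name\t|\n", ""
            ),
            encoding="utf-8",
        )
        with pytest.warns(UserWarning, match="3701"):
            d = load_taxonomy_dump(names, nodes, "33090")
        assert "NCBITaxon:3701" not in d

    def test_subtree_filter_is_monotone(self, tmp_path: Path) -> None:
        names, nodes = _write_taxonomy(tmp_path)
        inner = set(load_taxonomy_dump(names, nodes, "3701").concepts)
        outer = set(load_taxonomy_dump(names, nodes, "33090").concepts)
        whole = set(load_taxonomy_dump(names, nodes, "1").concepts)
        assert inner <= outer <= whole


class TestLookup:
    def test_exact_lookup_is_case_and_whitespace_insensitive(
        self, c7_dictionary: EntityDictionary
    ) -> None:
        assert c7_dictionary.lookup_exact("C7 deficiency") == {"OMIM:610102"}
        assert c7_dictionary.lookup_exact("c7  DEFICIENCY") == {"OMIM:610102"}
        assert c7_dictionary.lookup_exact("no such disease zzz") == set()

    def test_ambiguous_synonym_returns_both_ids(self) -> None:
        d = EntityDictionary(
            [
                Concept("A:1", "alpha disease", synonyms={"AD"}),
                Concept("B:2", "beta disorder", synonyms={"AD"}),
            ]
        )
        assert d.lookup_exact("AD") == {"A:1", "B:2"}

    def test_every_enumerated_name_round_trips_through_lookup(
        self, c7_dictionary: EntityDictionary
    ) -> None:
        for name, cid in c7_dictionary.iter_names():
            assert cid in c7_dictionary.lookup_exact(name)

    def test_preferred_name_not_duplicated_in_synonyms(self) -> None:
        c = Concept("X:1", "some disease", synonyms={"Some  Disease", "other name"})
        assert c.synonyms == {"other name"}

    def test_duplicate_add_rejected(self, c7_dictionary: EntityDictionary) -> None:
        with pytest.raises(ValueError, match="OMIM:610102"):
            c7_dictionary.add(Concept("OMIM:610102", "again"))


def test_generic_tsv_round_trip(tmp_path: Path, c7_dictionary: EntityDictionary) -> None:
    buffer = io.StringIO()
    write_generic_tsv(c7_dictionary, buffer)
    path = tmp_path / "generic.tsv"
    path.write_text(buffer.getvalue(), encoding="utf-8")
    reloaded = load_generic_tsv(path)
    assert set(reloaded.concepts) == set(c7_dictionary.concepts)
    for cid, concept in c7_dictionary.concepts.items():
        assert reloaded[cid].preferred_name == concept.preferred_name
        assert reloaded[cid].synonyms == concept.synonyms
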
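"""Dataset parsing, table loading and output writing."""

import logging

import pytest

from ancac import (Dataset, DataError, IntegrityError, ScoreRow,
                   datasets_equal, export_fasta, load_taxonomy, load_traits,
                   parse_fasta_bundle, parse_nucocog_xml, write_members_tsv,
                   write_nucocog_xml, write_ranking_tsv)


class TestParseXml:
    def test_toy_fixture_counts(self, toy_dataset):
        assert len(toy_dataset.sequences) == 4
        assert set(toy_dataset.cogs) == {"COG0001", "COG0002"}
        assert set(toy_dataset.organisms) == {"eco", "mja"}
        assert toy_dataset.cogs["COG0001"].description == "ribosomal protein"

    def test_empty_dataset_rejected(self, tmp_path):
        path = tmp_path / "empty.xml"
        path.write_text('<dataset source="cog"><organism id="a" name="A"/></dataset>')
        with pytest.raises(DataError, match="no sequences"):
            parse_nucocog_xml(path)

    def test_case_and_rna_normalization(self, tmp_path):
        path = tmp_path / "lc.xml"
        path.write_text(
            '<dataset source="cog"><organism id="a" name="A"/>'
            '<cog id="COG0001" desc=""><seq org="a" protein_gi="1" gene_gi="2">'
            "<aa>mk</aa><nt>augaaa</nt></seq></cog></dataset>")
        ds = parse_nucocog_xml(path)
        rec = ds.sequences[0]
        assert rec.aa_seq == "MK"
        assert rec.nt_seq == "ATGAAA"
        assert "U" not in rec.nt_seq

    def test_malformed_xml_names_line(self, tmp_path):
        path = tmp_path / "bad.xml"
        path.write_text('<dataset source="cog">\n<organism id="a"\n')
        with pytest.raises(DataError, match="line"):
            parse_nucocog_xml(path)

    def test_unknown_organism_reference(self, tmp_path):
        path = tmp_path / "dangling.xml"
        path.write_text(
            '<dataset source="cog"><organism id="a" name="A"/>'
            '<cog id="COG0001" desc=""><seq org="ghost" protein_gi="77" gene_gi="2">'
            "<aa>MK</aa><nt></nt></seq></cog></dataset>")
        with pytest.raises(IntegrityError, match="77"):
            parse_nucocog_xml(path)

    def test_unknown_attributes_tolerated(self, tmp_path):
        path = tmp_path / "extra.xml"
        path.write_text(
            '<dataset source="cog" release="2026"><organism id="a" name="A" taxid="5"/>'
            '<cog id="COG0001" desc="" funcat="J"><seq org="a" protein_gi="1" '
            'gene_gi="2" note="x"><aa>MK</aa><nt>ATGAAA</nt></seq></cog></dataset>')
        ds = parse_nucocog_xml(path)
        assert len(ds.sequences) == 1

    def test_round_trip(self, toy_dataset, small_synth, tmp_path):
        for i, ds in enumerate((toy_dataset, small_synth)):
            path = tmp_path / f"rt{i}.xml"
            write_nucocog_xml(ds, path)
            again = parse_nucocog_xml(path)
            again.validate()
            assert datasets_equal(ds, again)


class TestFastaBundle:
    @staticmethod
    def _write_bundle(tmp_path, with_cds=True):
        (tmp_path / "prot").mkdir()
        (tmp_path / "cds").mkdir()
        (tmp_path / "prot" / "COG0001.faa").write_text(
            ">eco|101|201\nMK\n>mja|102|202\nMKK\n")
        if with_cds:
            (tmp_path / "cds" / "COG0001.fna").write_text(
                ">eco|101|201\nATGAAATAA\n>mja|102|202\nATGAAAAAGTAA\n")
        manifest = tmp_path / "manifest.tsv"
        manifest.write_text("eco\tEscherichia coli\nmja\tMethanocaldococcus jannaschii\n")
        return tmp_path / "prot", tmp_path / "cds", manifest

    def test_paired_records(self, tmp_path):
        ds = parse_fasta_bundle(*self._write_bundle(tmp_path))
        assert len(ds.sequences) == 2
        assert all(rec.nt_seq for rec in ds.sequences)

    def test_fasta_and_xml_agree(self, tmp_path, toy_dataset):
        ds = parse_fasta_bundle(*self._write_bundle(tmp_path))
        # the FASTA route cannot carry COG descriptions; blank them for comparison
        xml_side = Dataset(source=toy_dataset.source,
                           organisms=toy_dataset.organisms)
        for cog_id, cog in toy_dataset.cogs.items():
            if cog_id in ds.cogs:
                xml_side.cogs[cog_id] = type(cog)(cog_id, "", set(cog.member_ids))
        xml_side.sequences = [s for s in toy_dataset.sequences
                              if s.cog_id == "COG0001"]
        assert datasets_equal(ds, xml_side)

    def test_missing_cds_kept_protein_only(self, tmp_path, caplog):
        with caplog.at_level(logging.WARNING, logger="ancac"):
            ds = parse_fasta_bundle(*self._write_bundle(tmp_path, with_cds=False))
        assert all(rec.nt_seq == "" for rec in ds.sequences)
        assert any("no CDS partner" in r.message for r in caplog.records)

    def test_bad_header_rejected(self, tmp_path):
        prot, cds, manifest = self._write_bundle(tmp_path)
        (prot / "COG0002.faa").write_text(">abc\nMK\n")
        with pytest.raises(DataError, match="abc"):
            parse_fasta_bundle(prot, cds, manifest)


class TestTables:
    def test_taxonomy_full_row(self, tmp_path):
        path = tmp_path / "tax.tsv"
        path.write_text(
            "organism_id\tsuperkingdom\tphylum\tclass\torder\tfamily\tgenus\tspecies\n"
            "eco\tBacteria\tProteobacteria\tGammaproteobacteria\tEnterobacterales"
            "\tEnterobacteriaceae\tEscherichia\tEscherichia coli\n")
        lineages = load_taxonomy(path)
        assert len(lineages["eco"]) == 7
        assert lineages["eco"]["species"] == "Escherichia coli"

    def test_taxonomy_blank_rank_absent(self, tmp_path):
        path = tmp_path / "tax.tsv"
        path.write_text(
            "organism_id\tsuperkingdom\tphylum\tclass\torder\tfamily\tgenus\tspecies\n"
            "xxx\tBacteria\t\t\t\t\t\tXxx yyy\n")
        assert "genus" not in load_taxonomy(path)["xxx"]

    def test_taxonomy_duplicate_and_missing_species(self, tmp_path):
        header = ("organism_id\tsuperkingdom\tphylum\tclass\torder\tfamily"
                  "\tgenus\tspecies\n")
        dup = tmp_path / "dup.tsv"
        dup.write_text(header + "a\t\t\t\t\t\t\tA a\na\t\t\t\t\t\t\tA a\n")
        with pytest.raises(DataError, match="duplicate"):
            load_taxonomy(dup)
        nosp = tmp_path / "nosp.tsv"
        nosp.write_text(header + "a\tBacteria\t\t\t\t\t\t\n")
        with pytest.raises(DataError, match="species"):
            load_taxonomy(nosp)

    def test_traits_parsing(self, tmp_path):
        path = tmp_path / "traits.tsv"
        path.write_text("organism_id\toxygen_class\togt\n"
                        "mja\tanaerobe\t85\neco\taerobe\t\n")
        traits = load_traits(path)
        assert traits["mja"] == ("anaerobe", 85.0)
        assert traits["eco"] == ("aerobe", None)

    def test_traits_unknown_oxygen_warns(self, tmp_path, caplog):
        path = tmp_path / "traits.tsv"
        path.write_text("organism_id\toxygen_class\togt\nxxx\tmicroaerophile\t20\n")
        with caplog.at_level(logging.WARNING, logger="ancac"):
            traits = load_traits(path)
        assert traits["xxx"][0] == "unknown"
        assert any("not recognized" in r.message for r in caplog.records)

    def test_traits_non_numeric_ogt(self, tmp_path):
        path = tmp_path / "traits.tsv"
        path.write_text("organism_id\toxygen_class\togt\nxxx\taerobe\twarm\n")
        with pytest.raises(DataError, match="warm"):
            load_traits(path)


class TestWriters:
    @staticmethod
    def _row(label="COG0001", score=0.6):
        return ScoreRow(label, None, 3, 5, 60.0, score, "desc", 2, 0)

    def test_line_counts(self, tmp_path):
        path = tmp_path / "ranking.tsv"
        write_ranking_tsv([self._row(f"COG{i:04d}") for i in range(1, 4)], path)
        assert len(path.read_text().splitlines()) == 4
        write_ranking_tsv([], path)
        assert len(path.read_text().splitlines()) == 1

    def test_four_decimal_rendering_and_count_columns(self, tmp_path):
        path = tmp_path / "ranking.tsv"
        write_ranking_tsv([self._row()], path, normalized=True)
        header, line = path.read_text().splitlines()
        assert "Number of selected features" in header
        assert "Total number of features" in header
        fields = line.split("\t")
        assert "0.6000" in fields and "60.0000" in fields
        assert "3" in fields and "5" in fields

    def test_members_listing(self, toy_dataset, tmp_path):
        path = tmp_path / "members.tsv"
        write_members_tsv(toy_dataset, "COG0001", path)
        lines = path.read_text().splitlines()
        assert lines[0].split("\t") == ["domain", "protein_gi", "gene_gi",
                                        "cog", "organism"]
        assert len(lines) == 3
        assert "Escherichia coli" in lines[1]

    def test_export_fasta(self, toy_dataset, tmp_path):
        out = tmp_path / "out.faa"
        n = export_fasta(toy_dataset, out, "protein", ["COG0001"])
        assert n == 2
        text = out.read_text()
        assert text.startswith(">eco|101|201")
        assert export_fasta(toy_dataset, tmp_path / "cds.fna", "cds") == 4
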
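import logging

import pytest

from operonscan import annotation_io
from operonscan.model import FormatError, GeneRecord, ValidationError


def _gff_line(contig, start, end, strand, attrs):
    return "\t".join(
        [contig, "src", "CDS", str(start), str(end), ".", strand, "0", attrs]
    )


def write(tmp_path, lines, name="test.gff3"):
    path = tmp_path / name
    path.write_text("##gff-version 3\n" + "\n".join(lines) + ("\n" if lines else ""))
    return path


class TestReadGff3:
    def test_headers_only_yields_empty_list(self, tmp_path):
        assert annotation_io.read_gff3(write(tmp_path, [])) == []

    def test_out_of_order_cds_sorted_and_indexed(self, tmp_path):
        lines = [
            _gff_line("c1", 5000, 5500, "+", "ID=c;protein_id=P3"),
            _gff_line("c1", 100, 600, "+", "ID=a;protein_id=P1"),
            _gff_line("c1", 2000, 2600, "+", "ID=b;protein_id=P2"),
        ]
        records = annotation_io.read_gff3(write(tmp_path, lines))
        assert [r.protein_accession for r in records] == ["P1", "P2", "P3"]
        assert [r.gene_index for r in records] == [0, 1, 2]

    def test_two_exon_cds_merged_to_envelope(self, tmp_path):
        lines = [
            _gff_line("c1", 100, 200, "+", "ID=x;protein_id=PX"),
            _gff_line("c1", 300, 400, "+", "ID=x;protein_id=PX"),
        ]
        records = annotation_io.read_gff3(write(tmp_path, lines))
        assert len(records) == 1
        assert (records[0].start, records[0].end) == (100, 400)

    def test_non_cds_features_skipped(self, tmp_path):
        lines = [
            "\t".join(["c1", "src", "gene", "100", "600", ".", "+", ".", "ID=g1"]),
            _gff_line("c1", 100, 600, "+", "ID=a;protein_id=P1;product=ferredoxin"),
        ]
        records = annotation_io.read_gff3(write(tmp_path, lines))
        assert len(records) == 1
        assert records[0].product == "ferredoxin"

    def test_malformed_column_count_names_line(self, tmp_path):
        path = write(tmp_path, ["c1\tsrc\tCDS\t100"])
        with pytest.raises(FormatError, match="line 2"):
            annotation_io.read_gff3(path)

    def test_end_before_start_rejected(self, tmp_path):
        path = write(tmp_path, [_gff_line("c1", 600, 100, "+", "ID=a")])
        with pytest.raises(ValidationError, match="end"):
            annotation_io.read_gff3(path)

    def test_unknown_strand_rejected(self, tmp_path):
        path = write(tmp_path, [_gff_line("c1", 100, 600, "?", "ID=a")])
        with pytest.raises(ValidationError, match="strand"):
            annotation_io.read_gff3(path)


class TestGeneRecordTable:
    def test_round_trip_identity(self, tmp_path, sim_result):
        path = tmp_path / "genes.tsv"
        subset = sim_result.gene_records[:200]
        annotation_io.write_gene_records(subset, path)
        assert annotation_io.read_gene_records(path) == subset

    def test_gff_round_trip_through_simulation(self, tmp_path, sim_result):
        from operonscan.synthetic_data import write_gff3

        records = [
            r for r in sim_result.gene_records if r.assembly_id == "SYN_00000"
        ]
        path = tmp_path / "SYN_00000.gff3"
        write_gff3(records, path)
        assert annotation_io.read_gff3(path) == records

    def test_gene_index_is_bijection_per_contig(self, sim_result):
        by_contig = {}
        for r in sim_result.gene_records:
            by_contig.setdefault((r.assembly_id, r.contig_id), []).append(r)
        for genes in by_contig.values():
            indices = sorted(g.gene_index for g in genes)
            assert indices == list(range(len(genes)))
            ordered = sorted(genes, key=lambda g: (g.start, g.end))
            assert [g.gene_index for g in ordered] == indices


class TestReadTargets:
    def _write(self, tmp_path, rows):
        path = tmp_path / "targets.tsv"
        header = "protein_accession\tfamily\tclade_label\tassembly_id\n"
        path.write_text(header + "".join("\t".join(r) + "\n" for r in rows))
        return path

    def test_valid_row(self, tmp_path):
        targets = annotation_io.read_targets(
            self._write(tmp_path, [("WP_X", "CODH", "A", "GCA_1")])
        )
        assert len(targets) == 1
        assert targets[0].clade_label == "A"

    def test_label_from_wrong_family_rejected(self, tmp_path):
        path = self._write(tmp_path, [("WP_X", "CODH", "II", "GCA_1")])
        with pytest.raises(ValidationError, match="II"):
            annotation_io.read_targets(path)

    def test_duplicate_rows_collapse_with_warning(self, tmp_path, caplog):
        path = self._write(
            tmp_path, [("WP_X", "CODH", "A", "GCA_1"), ("WP_X", "CODH", "A", "GCA_1")]
        )
        with caplog.at_level(logging.WARNING):
            targets = annotation_io.read_targets(path)
        assert len(targets) == 1
        assert any("duplicate" in rec.message for rec in caplog.records)


class TestReadFunctionAnnotations:
    def test_eggnog_two_rows(self, tmp_path):
        path = tmp_path / "e.annotations"
        path.write_text(
            "## eggNOG-mapper annotations\n"
            "#query\tseed_ortholog\tDescription\teggNOG_OGs\n"
            "WP_1\tsx\tferredoxin\tCOG1234@1\n"
            "WP_2\tsy\tMFS transporter\tCOG9999@1\n"
        )
        annotations = annotation_io.read_function_annotations(path, "eggnog")
        assert len(annotations) == 2
        assert annotations["WP_1"].description == "ferredoxin"
        assert annotations["WP_1"].ortholog_group == "COG1234@1"

    def test_comment_only_file_empty_map(self, tmp_path):
        path = tmp_path / "e.annotations"
        path.write_text("## nothing here\n## still nothing\n")
        assert annotation_io.read_function_annotations(path, "eggnog") == {}

    def test_versioned_query_kept_verbatim(self, tmp_path):
        # normalization is the caller's job: the key is the exact string
        path = tmp_path / "e.annotations"
        path.write_text("#query\tDescription\nWP_1.1\tferredoxin\n")
        annotations = annotation_io.read_function_annotations(path, "eggnog")
        assert "WP_1.1" in annotations and "WP_1" not in annotations

    def test_missing_description_column_rejected(self, tmp_path):
        path = tmp_path / "e.annotations"
        path.write_text("#query\tseed_ortholog\nWP_1\tx\n")
        with pytest.raises(FormatError, match="Description"):
            annotation_io.read_function_annotations(path, "eggnog")
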
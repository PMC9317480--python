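"""Genome/panel reading, coordinate conventions, and tabular round-trips."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from disymbio import annotation_io as aio
from disymbio import pathways, simulate, strains
from disymbio.annotation_io import AnnotatedGenome, CdsRecord, Replicon


def _tiny_genome(n_cds=10, n_pseudo=2):
    cds = []
    pos = 10
    for i in range(n_cds):
        cds.append(
            CdsRecord(
                id=f"c{i}",
                replicon_id="chr",
                start=pos,
                end=pos + 90,
                strand="+" if i % 2 else "-",
                translation="MKTAYIAKQRQISFVKSHFSRQLEERLGLI",
                declared_pseudo=i < n_pseudo,
            )
        )
        pos += 120
    seq = "ACGT" * ((pos + 40) // 4)
    return AnnotatedGenome(
        "tiny", [Replicon("chr", len(seq), "circular", "chromosome")], cds, {"chr": seq}
    )


class TestCoordinateConventions:
    def test_gff3_one_based_interval_converts_to_half_open(self, tmp_path):
        panel = simulate.generate_reference_panel(1, (99, 99), seed=3)
        spec = simulate.DegradationSpec(p_delete=0, p_truncate=0, p_fragment=0,
                                        mutation_rate=0, seed=3)
        genome, _ = simulate.degrade_genome(panel, spec)
        gff, fna = tmp_path / "g.gff3", tmp_path / "g.fna"
        simulate.write_gff3_fasta(genome, str(gff), str(fna))
        cds = genome.cds[0]
        line = next(l for l in gff.read_text().splitlines() if "\tCDS\t" in l)
        fields = line.split("\t")
        # 0-based half-open internally, 1-based inclusive on disk
        assert int(fields[3]) == cds.start + 1
        assert int(fields[4]) == cds.end
        back = aio.read_genome_annotation(str(gff), "gff3", fasta=str(fna))
        assert back.cds[0].start == cds.start
        assert back.cds[0].end == cds.end

    @given(start=st.integers(0, 10_000), length=st.integers(1, 5_000))
    @settings(max_examples=100, derandomize=True)
    def test_coordinate_conversion_is_a_bijection(self, start, length):
        end = start + length
        one_based = (start + 1, end)  # as written to GFF3
        assert (one_based[0] - 1, one_based[1]) == (start, end)
        assert one_based[1] - (one_based[0] - 1) == length


class TestGenomeRoundTrips:
    def test_genbank_pseudo_flags_pass_through(self, tmp_path):
        genome = _tiny_genome(10, 2)
        path = tmp_path / "tiny.gbk"
        simulate.write_genbank(genome, str(path))
        back = aio.read_genome_annotation(str(path), "genbank")
        assert len(back.cds) == 10
        assert sum(c.declared_pseudo for c in back.cds) == 2

    @pytest.mark.parametrize("fmt", ["genbank", "gff3"])
    def test_synthetic_genome_round_trips_identically(self, tmp_path, small_panel, fmt):
        spec = simulate.DegradationSpec(seed=5)
        genome, _ = simulate.degrade_genome(small_panel, spec)
        if fmt == "genbank":
            p = tmp_path / "s.gbk"
            simulate.write_genbank(genome, str(p))
            back = aio.read_genome_annotation(str(p), "genbank")
        else:
            gff, fna = tmp_path / "s.gff3", tmp_path / "s.fna"
            simulate.write_gff3_fasta(genome, str(gff), str(fna))
            back = aio.read_genome_annotation(str(gff), "gff3", fasta=str(fna))
        assert back.strain_id == genome.strain_id
        assert back.replicons == genome.replicons
        assert back.cds == genome.cds
        assert back.sequence == genome.sequence

    def test_malformed_file_raises_parse_error(self, tmp_path):
        bad = tmp_path / "bad.gbk"
        bad.write_text("this is not a genbank file\n")
        with pytest.raises((aio.AnnotationParseError, ValueError)):
            aio.read_genome_annotation(str(bad), "genbank")

    def test_cds_record_invariants(self):
        with pytest.raises(ValueError):
            CdsRecord("x", "chr", 100, 100, "+", "MKT")
        with pytest.raises(ValueError):
            CdsRecord("x", "chr", 0, 9, "+", "MJT")  # J is not an amino acid
        with pytest.raises(ValueError):
            CdsRecord("x", "chr", 0, 9, "+", "")  # empty needs pseudo flag
        ok = CdsRecord("x", "chr", 0, 9, "+", "", declared_pseudo=True)
        assert ok.aa_length == 0


class TestReferencePanels:
    def test_panel_round_trip_is_lossless(self, tmp_path, small_panel):
        path = tmp_path / "panel.faa"
        aio.write_reference_panel(small_panel, str(path))
        back = aio.read_reference_panel(str(path))
        assert back.entries == small_panel.entries

    def test_three_records_three_entries(self, tmp_path):
        path = tmp_path / "p.faa"
        path.write_text(">bioA|biotin\nMKT\n>bioB|biotin\nMAV\n>ribA|riboflavin\nMLW\n")
        panel = aio.read_reference_panel(str(path))
        assert len(panel) == 3
        assert panel["bioA"].category == "biotin"

    def test_duplicate_gene_name_rejected(self, tmp_path):
        path = tmp_path / "dup.faa"
        path.write_text(">bioA|biotin\nMKT\n>bioA|biotin\nMAV\n")
        with pytest.raises(aio.AnnotationParseError):
            aio.read_reference_panel(str(path))


class TestStatusMatrices:
    def test_single_cell_matrix_has_header_and_one_row(self, tmp_path):
        frame = pd.DataFrame([{"pathway": "p", "step": "s", "gene": "g", "G1": "INTACT"}])
        path = tmp_path / "m.tsv"
        aio.write_status_matrix(frame, str(path))
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 2

    def test_written_matrix_reads_back_identically(self, tmp_path, catalog, vitamin_tables):
        matrix = pathways.complementarity_matrix(
            catalog.subset(["riboflavin", "biotin"]), list(vitamin_tables.values())
        )
        path = tmp_path / "matrix.tsv"
        aio.write_status_matrix(matrix, str(path))
        back = aio.read_status_matrix(str(path))
        assert list(back.columns) == list(matrix.columns)
        assert back["gene"].tolist() == matrix["gene"].tolist()
        for col in vitamin_tables:
            assert back[col].tolist() == matrix[col].tolist()

    def test_curated_riboflavin_matrix_cells(self, catalog, vitamin_tables):
        # the SsSm phosphatase alternative survives only as a pseudogene,
        # and neither Buchnera strain kept any riboflavin gene
        matrix = pathways.complementarity_matrix(
            catalog.subset(["riboflavin"]), list(vitamin_tables.values())
        )
        yigL = matrix[matrix["gene"] == "yigL"].iloc[0]
        assert yigL["SsSm"] == "PSEUDOGENE"
        assert yigL["SsPl"] == "INTACT"
        for strain in ("BaSm", "BaPl"):
            assert (matrix[strain] == "MISSING").all()

    def test_empty_matrix_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            aio.write_status_matrix(pd.DataFrame(), str(tmp_path / "e.tsv"))
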
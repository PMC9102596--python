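"""Parsing and round-tripping of GFF3, GTF and BED12 annotation."""

import pytest

from genepanel import annotation_io as aio
from genepanel import fixtures, gene_structure as gs
from genepanel.model import SegmentKind


GFF3_MINIMAL = """##gff-version 3
Chr1\tsrc\tgene\t1\t300\t.\t+\t.\tID=g1
Chr1\tsrc\tmRNA\t1\t300\t.\t+\t.\tID=g1.1;Parent=g1
Chr1\tsrc\texon\t1\t300\t.\t+\t.\tParent=g1.1
"""


class TestReadGff3:
    def test_single_exon_passthrough(self):
        result = aio.read_gff3(GFF3_MINIMAL)
        assert len(result.models) == 1
        (m,) = result.models
        assert m.transcript_id == "g1.1" and m.gene_id == "g1"
        assert [(s.kind, s.start, s.end) for s in m.segments] == [
            (SegmentKind.EXON, 1, 300)
        ]

    def test_empty_stream(self):
        result = aio.read_gff3("##gff-version 3\n")
        assert result.models == [] and result.warnings == []

    def test_two_cds_one_utr_gene_matches_reference_shape(self):
        # spans sum to a 2103 bp transcript: UTR[1,100] + CDS[101,1000],
        # intron, CDS[1501,2103] -> 2 cds, 1 utr, 1 intron, length 2103
        text = (
            "##gff-version 3\n"
            "Chr1\ts\tmRNA\t1\t2103\t.\t+\t.\tID=t1\n"
            "Chr1\ts\tfive_prime_UTR\t1\t100\t.\t+\t.\tParent=t1\n"
            "Chr1\ts\tCDS\t101\t1000\t.\t+\t0\tParent=t1\n"
            "Chr1\ts\tCDS\t1501\t2103\t.\t+\t0\tParent=t1\n"
        )
        (m,) = aio.read_gff3(text).models
        assert len(m.segments) == 3
        st = gs.compute_stats(m)
        assert (st.gene_length, st.n_introns, st.n_cds, st.n_utrs) == (2103, 1, 2, 1)

    def test_malformed_column_count_raises_with_line_number(self):
        bad = "##gff-version 3\nChr1\tsrc\tgene\t1\t300\n"
        with pytest.raises(aio.AnnotationParseError, match="line 2"):
            aio.read_gff3(bad)

    def test_unknown_parent_is_warned_not_dropped_silently(self):
        text = (
            "##gff-version 3\n"
            "Chr1\ts\tmRNA\t1\t100\t.\t+\t.\tID=t1\n"
            "Chr1\ts\tCDS\t1\t100\t.\t+\t0\tParent=ghost\n"
        )
        result = aio.read_gff3(text)
        assert any("ghost" in w for w in result.warnings)

    def test_unknown_feature_type_kept_as_other_with_label(self):
        text = (
            "##gff-version 3\n"
            "Chr1\ts\tmRNA\t1\t100\t.\t+\t.\tID=t1\n"
            "Chr1\ts\texon\t1\t100\t.\t+\t.\tParent=t1\n"
            "Chr1\ts\tsignal_peptide\t1\t60\t.\t+\t.\tParent=t1\n"
        )
        (m,) = aio.read_gff3(text).models
        other = m.segments_of(SegmentKind.OTHER)
        assert len(other) == 1 and other[0].label == "signal_peptide"


class TestReadGtf:
    GTF = (
        'Chr1\ts\texon\t1\t100\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
        'Chr1\ts\texon\t201\t300\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
        'Chr1\ts\tCDS\t51\t100\t.\t+\t0\tgene_id "g1"; transcript_id "t1";\n'
        'Chr1\ts\tCDS\t201\t250\t.\t+\t1\tgene_id "g1"; transcript_id "t1";\n'
    )

    def test_direct_mapping(self):
        (m,) = aio.read_gtf(self.GTF).models
        assert len(m.segments) == 4
        assert len(m.cds_segments()) == 2

    @pytest.mark.parametrize(
        "utr_row,strand,expected",
        [
            ('Chr1\ts\tUTR\t1\t50\t.\t+\t.\t{a}', "+", SegmentKind.FIVE_UTR),
            ('Chr1\ts\tUTR\t251\t300\t.\t+\t.\t{a}', "+", SegmentKind.THREE_UTR),
            ('Chr1\ts\tUTR\t1\t50\t.\t-\t.\t{a}', "-", SegmentKind.THREE_UTR),
        ],
    )
    def test_generic_utr_classified_positionally(self, utr_row, strand, expected):
        attrs = 'gene_id "g1"; transcript_id "t1";'
        base = (
            f'Chr1\ts\tCDS\t51\t100\t.\t{strand}\t0\t{attrs}\n'
            f'Chr1\ts\tCDS\t201\t250\t.\t{strand}\t0\t{attrs}\n'
        )
        text = base + utr_row.format(a=attrs) + "\n"
        (m,) = aio.read_gtf(text).models
        utrs = m.utr_segments()
        assert len(utrs) == 1 and utrs[0].kind is expected

    def test_missing_quotes_is_parse_error(self):
        bad = "Chr1\ts\texon\t1\t100\t.\t+\t.\tgene_id g1; transcript_id t1;\n"
        with pytest.raises(aio.AnnotationParseError, match="line 1"):
            aio.read_gtf(bad)


class TestReadBed12:
    def test_single_block_fully_coding(self):
        line = "Chr1\t0\t300\tt1\t0\t+\t0\t300\t0\t1\t300\t0\n"
        (m,) = aio.read_bed12(line).models
        exons = m.segments_of(SegmentKind.EXON)
        cds = m.cds_segments()
        assert [(s.start, s.end) for s in exons] == [(1, 300)]
        assert [(s.start, s.end) for s in cds] == [(1, 300)]

    def test_degenerate_thick_region_noncoding(self):
        line = "Chr1\t0\t300\tt1\t0\t+\t0\t0\t0\t2\t100,100\t0,200\n"
        (m,) = aio.read_bed12(line).models
        assert len(m.segments_of(SegmentKind.EXON)) == 2
        assert m.cds_segments() == []

    def test_half_open_to_inclusive_conversion(self):
        # blocks [0,100) and [200,300), thick [50,250)
        line = "Chr1\t0\t300\tt1\t0\t+\t50\t250\t0\t2\t100,100\t0,200\n"
        (m,) = aio.read_bed12(line).models
        assert [(s.start, s.end) for s in m.cds_segments()] == [(51, 100), (201, 250)]
        utrs = m.utr_segments()
        assert [(s.kind, s.start, s.end) for s in utrs] == [
            (SegmentKind.FIVE_UTR, 1, 50),
            (SegmentKind.THREE_UTR, 251, 300),
        ]

    def test_block_count_mismatch_raises(self):
        line = "Chr1\t0\t300\tt1\t0\t+\t0\t300\t0\t2\t300\t0\n"
        with pytest.raises(aio.AnnotationParseError, match="blockCount"):
            aio.read_bed12(line)

    def test_roundtrip_is_bit_exact(self):
        models, _truth, _g = fixtures.synth_gene_models(
            fixtures.FixtureConfig(n_genes=30, seed=4, groups=())
        )
        text = aio.write_bed12(models)
        again = aio.write_bed12(aio.read_bed12(text).models)
        assert text == again


class TestSubsetByIds:
    def test_identity_and_order(self, table1_models):
        ids = {m.transcript_id for m in table1_models}
        result = aio.subset_by_ids(table1_models, ids)
        assert [m.transcript_id for m in result.models] == [
            m.transcript_id for m in table1_models
        ]

    def test_empty_filter(self, table1_models):
        assert aio.subset_by_ids(table1_models, set()).models == []

    def test_group1_selection_has_26_members(self, table1_models, table1):
        _stats, groups = table1
        g1 = {tid for tid, g in groups.items() if g == "Group 1"}
        result = aio.subset_by_ids(table1_models, g1)
        assert len(result.models) == 26 and not result.warnings

    def test_missing_ids_reported_as_warnings(self, table1_models):
        result = aio.subset_by_ids(table1_models, {"LOC_Os01g13320.1", "nope"})
        assert len(result.models) == 1
        assert result.warnings and "nope" in result.warnings[0]


class TestFormatEquivalence:
    def test_same_genes_in_all_three_formats_give_identical_stats(self):
        """The multiset of structural statistics must not depend on whether a
        gene arrived as GFF3, GTF or BED12."""
        models, truth, _g = fixtures.synth_gene_models(
            fixtures.FixtureConfig(n_genes=100, seed=9, groups=())
        )
        baseline = [
            (t.gene_length, t.n_introns, t.n_cds, t.n_utrs) for t in truth
        ]
        for text, reader in (
            (aio.write_gff3(models), aio.read_gff3),
            (aio.write_gtf(models), aio.read_gtf),
            (aio.write_bed12(models), aio.read_bed12),
        ):
            parsed = reader(text).models
            stats = [gs.compute_stats(m) for m in parsed]
            assert [
                (s.gene_length, s.n_introns, s.n_cds, s.n_utrs) for s in stats
            ] == baseline

    def test_cds_basepair_multiset_identical_across_formats(self):
        models, _t, _g = fixtures.synth_gene_models(
            fixtures.FixtureConfig(n_genes=10, seed=2, groups=())
        )

        def cds_bp(parsed):
            return [
                sorted(
                    bp
                    for s in m.cds_segments()
                    for bp in range(s.start, s.end + 1)
                )
                for m in parsed
            ]

        ref = cds_bp(models)
        assert cds_bp(aio.read_gff3(aio.write_gff3(models)).models) == ref
        assert cds_bp(aio.read_gtf(aio.write_gtf(models)).models) == ref
        assert cds_bp(aio.read_bed12(aio.write_bed12(models)).models) == ref

    def test_parser_only_sorts_by_start(self):
        text = (
            "##gff-version 3\n"
            "Chr1\ts\tmRNA\t1\t500\t.\t+\t.\tID=t1\n"
            "Chr1\ts\tCDS\t301\t400\t.\t+\t0\tParent=t1\n"
            "Chr1\ts\tCDS\t1\t100\t.\t+\t0\tParent=t1\n"
        )
        (m,) = aio.read_gff3(text).models
        assert [s.start for s in m.segments] == [1, 301]


def test_write_gene_table_lists_every_segment(table1_models):
    table = aio.write_gene_table(table1_models[:2])
    lines = table.strip().splitlines()
    assert lines[0].startswith("transcript_id\t")
    assert len(lines) == 1 + sum(len(m.segments) for m in table1_models[:2])
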
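"""MEME/domain/cis-element readers, p-value height scaling, selective display."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genepanel import fixtures, protein_tracks as pt

MINIMAL_XML = """<?xml version="1.0"?>
<MEME version="5.4.1">
<training_set>
<sequence id="sequence_0" name="seqA" length="100" weight="1.0"/>
</training_set>
<motifs>
<motif id="motif_1" name="M1" width="30">
<contributing_sites>
<contributing_site sequence_id="sequence_0" position="9" strand="plus" pvalue="1e-20"/>
</contributing_sites>
</motif>
</motifs>
</MEME>
"""


class TestReadMeme:
    def test_minimal_xml_passthrough(self):
        result = pt.read_meme(MINIMAL_XML, "xml")
        (track,) = result.tracks
        assert track.sequence_id == "seqA" and track.length == 100
        (item,) = track.items
        assert (item.kind, item.start, item.end) == (pt.TrackKind.MOTIF, 10, 39)
        assert item.p_value == 1e-20
        assert any("scanned" in w for w in result.warnings)

    def test_scanned_sites_are_transparent(self, bundle):
        tracks = pt.read_meme(bundle.meme_xml, "xml").tracks
        scanned = [
            i for t in tracks for i in t.items
            if i.kind is pt.TrackKind.SCANNED_SITE
        ]
        assert scanned and all(i.opacity < 1 for i in scanned)

    def test_42_sequence_bundle_has_motifs_1_to_12(self, bundle):
        tracks = pt.read_meme(bundle.meme_xml, "xml").tracks
        assert len(tracks) == 42
        names = {
            i.name for t in tracks for i in t.items
            if i.kind is pt.TrackKind.MOTIF
        }
        assert names == {f"motif {k}" for k in range(1, 13)}

    def test_text_dialect_agrees_with_xml_on_motif_items(self, bundle):
        def motif_multisets(tracks):
            return {
                t.sequence_id: sorted(
                    (i.name, i.start, i.end) for i in t.items
                    if i.kind is pt.TrackKind.MOTIF
                )
                for t in tracks
            }

        xml = pt.read_meme(bundle.meme_xml, "xml").tracks
        txt = pt.read_meme(bundle.meme_text, "text").tracks
        assert motif_multisets(xml) == motif_multisets(txt)

    def test_sequence_reordering_does_not_change_per_sequence_items(self, bundle):
        lines = bundle.meme_xml.splitlines()
        seqs = [l for l in lines if l.startswith("<sequence ")]
        reordered = bundle.meme_xml.replace(
            "\n".join(seqs), "\n".join(reversed(seqs))
        )
        a = pt.read_meme(bundle.meme_xml, "xml").tracks
        b = pt.read_meme(reordered, "xml").tracks

        def key(tracks):
            return {
                t.sequence_id: sorted(
                    (i.kind.value, i.name, i.start, i.end) for i in t.items
                )
                for t in tracks
            }

        assert key(a) == key(b)

    def test_no_motifs_is_an_error(self):
        empty = MINIMAL_XML.replace(
            MINIMAL_XML[MINIMAL_XML.index("<motif id") : MINIMAL_XML.index("</motifs>")],
            "",
        )
        with pytest.raises(pt.TrackParseError, match="no motifs"):
            pt.read_meme(empty, "xml")

    def test_items_stay_within_sequence_bounds(self, bundle):
        for t in pt.read_meme(bundle.meme_xml, "xml").tracks:
            for i in t.items:
                assert 1 <= i.start <= i.end <= t.length


class TestReadDomainTable:
    def test_generic_row(self):
        items = pt.read_domain_table(
            "seqA\tpectinesterase\t120\t400\t1e-50\n", "generic"
        )
        assert [(i.sequence_id, i.name, i.start, i.end) for i in items] == [
            ("seqA", "pectinesterase", 120, 400)
        ]
        assert items[0].kind is pt.TrackKind.DOMAIN

    def test_identical_rows_deduplicated(self):
        text = "seqA\tPMEI\t10\t90\t1e-20\nseqA\tPMEI\t10\t90\t1e-20\n"
        assert len(pt.read_domain_table(text, "generic")) == 1

    def test_distinct_overlapping_hits_kept(self):
        text = "seqA\tPMEI\t10\t90\t1e-20\nseqA\tPMEI\t12\t92\t1e-18\n"
        assert len(pt.read_domain_table(text, "generic")) == 2

    def test_reversed_coordinates_rejected_per_row(self):
        with pytest.raises(pt.TrackParseError, match="line 1"):
            pt.read_domain_table("seqA\tPMEI\t90\t10\t1e-20\n", "generic")

    def test_unknown_dialect_lists_supported(self):
        with pytest.raises(ValueError, match="generic"):
            pt.read_domain_table("x", "hmmer3")

    def test_cdd_dialect_column_map(self):
        row = (
            "Q#1 - seqA\tspecific\t238492\t120\t400\t1e-50\t300\tpfam01095\t"
            "Pectinesterase\t-\t-\n"
        )
        (item,) = pt.read_domain_table(row, "cdd")
        assert (item.name, item.start, item.end) == ("Pectinesterase", 120, 400)

    def test_pmei_only_on_first_clade(self, bundle):
        items = pt.read_domain_table(bundle.domains_tsv, "generic")
        pmei_seqs = {i.sequence_id for i in items if i.name == "PMEI"}
        group1 = {t for t, g in bundle.group_of.items() if g == "Group 1"}
        assert pmei_seqs == group1


class TestReadCisElements:
    def test_single_row(self):
        result = pt.read_cis_elements("geneA\tTATA-box\t35\t7\t+\n", 2000)
        (track,) = result.tracks
        assert track.length == 2000
        (item,) = track.items
        assert (item.start, item.end, item.strand) == (35, 41, "+")

    def test_empty_table(self):
        assert pt.read_cis_elements("", 2000).tracks == []

    def test_element_name_catalogue_is_complete(self, bundle):
        tracks = pt.read_cis_elements(bundle.cis_tsv, 2000).tracks
        names = {i.name for t in tracks for i in t.items}
        assert names == set(fixtures._CIS_NAMES)
        assert len(names) == 5

    def test_element_past_promoter_end_rejected(self):
        with pytest.raises(pt.TrackParseError, match="exceeds"):
            pt.read_cis_elements("geneA\tTATA-box\t1998\t7\t+\n", 2000)

    def test_duplicate_rows_deduplicated(self):
        text = "geneA\tTATA-box\t35\t7\t+\ngeneA\tTATA-box\t35\t7\t+\n"
        (track,) = pt.read_cis_elements(text, 2000).tracks
        assert len(track.items) == 1


class TestMotifHeight:
    def test_p_equal_one_gives_floor(self):
        assert pt.motif_height(1.0) == pytest.approx(0.2)

    def test_saturation_at_cap(self):
        assert pt.motif_height(1e-30) == pytest.approx(1.0)
        assert pt.motif_height(1e-45) == pytest.approx(1.0)

    def test_midpoint_value(self):
        assert pt.motif_height(1e-15) == pytest.approx(0.6)

    @pytest.mark.parametrize("p", [0.0, -1e-3, 1.5])
    def test_domain_errors(self, p):
        with pytest.raises(ValueError):
            pt.motif_height(p)

    @settings(derandomize=True, max_examples=200)
    @given(
        p1=st.floats(1e-300, 1.0, exclude_min=False),
        p2=st.floats(1e-300, 1.0),
        h_min=st.floats(0.01, 0.5),
        spread=st.floats(0.01, 0.5),
        cap=st.floats(0.5, 100.0),
    )
    def test_monotone_non_increasing_in_p(self, p1, p2, h_min, spread, cap):
        h_max = min(h_min + spread, 1.0)
        if h_max <= h_min:
            return
        lo, hi = sorted((p1, p2))
        assert pt.motif_height(lo, h_min, h_max, cap) >= pt.motif_height(
            hi, h_min, h_max, cap
        )


class TestFilterItems:
    def test_empty_selection_is_show_all(self, bundle):
        tracks = pt.read_meme(bundle.meme_xml, "xml").tracks
        out = pt.filter_items(tracks, set())
        assert [t.items for t in out] == [t.items for t in tracks]

    def test_select_all_names_is_identity(self, bundle):
        tracks = pt.read_meme(bundle.meme_xml, "xml").tracks
        names = {i.name for t in tracks for i in t.items}
        out = pt.filter_items(tracks, names)
        assert [t.items for t in out] == [t.items for t in tracks]

    def test_idempotent_and_coordinate_preserving(self, bundle):
        tracks = pt.read_meme(bundle.meme_xml, "xml").tracks
        once = pt.filter_items(tracks, {"motif 3"})
        twice = pt.filter_items(once, {"motif 3"})
        assert [t.items for t in once] == [t.items for t in twice]
        originals = {
            (i.sequence_id, i.name, i.kind): (i.start, i.end)
            for t in tracks for i in t.items
        }
        for t in once:
            for i in t.items:
                assert originals[(i.sequence_id, i.name, i.kind)] == (i.start, i.end)

    def test_clade_specific_motif_lands_inside_its_domain(self, bundle):
        """The PMEI-signature motif appears only on first-clade sequences and
        always inside the PMEI domain interval."""
        tracks = pt.read_meme(bundle.meme_xml, "xml").tracks
        doms = pt.read_domain_table(bundle.domains_tsv, "generic")
        pmei = {
            i.sequence_id: (i.start, i.end) for i in doms if i.name == "PMEI"
        }
        selected = pt.filter_items(tracks, {"motif 10"})
        for t in selected:
            motif_items = [i for i in t.items if i.kind is pt.TrackKind.MOTIF]
            if not motif_items:
                continue
            assert t.sequence_id in pmei
            lo, hi = pmei[t.sequence_id]
            for i in motif_items:
                assert lo <= i.start and i.end <= hi

    def test_unmatched_selection_warns(self, bundle):
        tracks = pt.read_meme(bundle.meme_xml, "xml").tracks
        with pytest.warns(pt.TrackWarning, match="motif 99"):
            pt.filter_items(tracks, {"motif 99"})
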
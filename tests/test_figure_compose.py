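"""Row alignment, scene building and deterministic rendering."""

import pytest

from genepanel import figure_compose as fc
from genepanel import protein_tracks as pt
from genepanel import tree_model as tm
from genepanel.model import FeatureSegment, GeneModel, SegmentKind


@pytest.fixture(scope="module")
def assembled(bundle):
    tree = tm.assign_groups(tm.parse_newick(bundle.newick), bundle.group_of)
    tracks = pt.attach_items(
        pt.read_meme(bundle.meme_xml, "xml").tracks,
        pt.read_domain_table(bundle.domains_tsv, "generic"),
    )
    prom = pt.read_cis_elements(bundle.cis_tsv, 2000).tracks
    spec = fc.FigureSpec(
        panels=[
            fc.PanelSpec("tree", 0.25),
            fc.PanelSpec("gene_structure", 0.30, scale_bar=True),
            fc.PanelSpec("motif", 0.25),
            fc.PanelSpec("domain", 0.10),
            fc.PanelSpec("promoter", 0.10),
        ]
    )
    return spec, tree, tracks, prom


def single_gene():
    return GeneModel(
        gene_id="g", transcript_id="g.1", chrom="Chr1", strand="+",
        segments=[FeatureSegment(SegmentKind.EXON, 1, 300)],
    )


class TestAlignRows:
    def test_full_match(self):
        rows, warnings = fc.align_rows(["A", "B", "C"], {"p": {"A", "B", "C"}})
        assert rows == {"A": 0, "B": 1, "C": 2} and not warnings

    def test_lenient_mode_blanks_and_warns(self):
        rows, warnings = fc.align_rows(["A", "B"], {"p": {"A"}}, strict=False)
        assert rows["B"] == 1
        assert any("'B'" in w for w in warnings)

    def test_strict_mode_enumerates_mismatches(self):
        with pytest.raises(fc.AlignmentError) as err:
            fc.align_rows(["A", "B"], {"p": {"A", "X"}}, strict=True)
        assert set(err.value.mismatched) == {"B", "X"}

    def test_complete_bundle_aligns_without_warnings(self, bundle, assembled):
        spec, tree, tracks, prom = assembled
        rows, warnings = fc.align_rows(
            tree.leaves,
            {
                "structure": {m.transcript_id for m in bundle.models},
                "protein": {t.sequence_id for t in tracks},
                "promoter": {t.sequence_id for t in prom},
            },
            strict=True,
        )
        assert len(rows) == 42 and warnings == []


class TestBuildScene:
    def test_minimal_single_exon_scene(self):
        spec = fc.FigureSpec(
            panels=[fc.PanelSpec("gene_structure", 1.0)],
            row_source="input_order",
        )
        scene = fc.build_scene(spec, models=[single_gene()])
        rects = [e for e in scene.elements if isinstance(e, fc.Rect)]
        lines = [e for e in scene.elements if isinstance(e, fc.Line)]
        assert len(rects) == 1 and rects[0].id == "struct.g.1.exon.0"
        assert any(e.id.endswith("baseline") for e in lines)

    def test_missing_data_for_panel_errors(self):
        spec = fc.FigureSpec(
            panels=[fc.PanelSpec("motif", 1.0)], row_source="input_order"
        )
        with pytest.raises(fc.FigureError, match="protein tracks"):
            fc.build_scene(spec)

    def test_domain_outline_drawn_above_motifs(self, bundle, assembled):
        """Domains superimpose on the motif panel: outline-only rectangles
        appended after (over) the motif boxes of the same track."""
        spec, tree, tracks, prom = assembled
        scene = fc.build_scene(
            spec, tree=tree, models=bundle.models, tracks=tracks,
            promoter_tracks=prom,
        )
        for tid in tree.leaves[:5]:
            ids = [e.id for e in scene.elements]
            motif_ids = [
                i for i, eid in enumerate(ids)
                if eid.startswith(f"motif.{tid}.motif.")
            ]
            domain_ids = [
                i for i, eid in enumerate(ids)
                if eid.startswith(f"motif.{tid}.domain.")
            ]
            assert domain_ids and motif_ids
            assert min(domain_ids) > max(motif_ids)
            for i in domain_ids:
                assert scene.elements[i].fill is None  # outline keeps motifs visible

    def test_row_centers_match_tree_leaf_y(self, bundle, assembled):
        spec, tree, tracks, prom = assembled
        scene = fc.build_scene(
            spec, tree=tree, models=bundle.models, tracks=tracks,
            promoter_tracks=prom,
        )
        layout = tm.layout_tree(tree, spec.canvas[1], 1.0)
        for tid in tree.leaves:
            baseline = next(
                e for e in scene.elements if e.id == f"struct.{tid}.baseline"
            )
            assert abs(baseline.y1 - layout.leaf_y[tid]) < 1e-6

    def test_within_row_scaling_is_linear(self, bundle, assembled):
        spec, tree, tracks, prom = assembled
        scene = fc.build_scene(spec, tree=tree, models=bundle.models,
                               tracks=tracks, promoter_tracks=prom)
        m = bundle.models[0]
        tid = m.transcript_id
        lo, _hi = m.span
        rects = {
            e.id: e for e in scene.elements
            if e.id.startswith(f"struct.{tid}.cds.")
        }
        cds = m.cds_segments()
        assert len(rects) == len(cds)
        # x-distance between any two cds rect left edges proportional to bp distance
        keys = sorted(rects)
        if len(keys) >= 2 and m.strand == "+":
            r0, r1 = rects[keys[0]], rects[keys[1]]
            c0, c1 = cds[0], cds[1]
            bp = c1.start - c0.start
            scale = (r1.x - r0.x) / bp
            for key, seg in zip(keys, cds):
                expect = r0.x + (seg.start - c0.start) * scale
                assert rects[key].x == pytest.approx(expect, abs=1e-6)

    def test_all_primitives_inside_canvas(self, bundle, assembled):
        spec, tree, tracks, prom = assembled
        scene = fc.build_scene(spec, tree=tree, models=bundle.models,
                               tracks=tracks, promoter_tracks=prom)
        W, H = spec.canvas
        for e in scene.elements:
            if isinstance(e, fc.Rect):
                assert -1e-9 <= e.x and e.x + e.w <= W + 1e-9
                assert -1e-9 <= e.y and e.y + e.h <= H + 1e-9
            elif isinstance(e, fc.Line):
                assert min(e.x1, e.x2) >= -1e-9 and max(e.x1, e.x2) <= W + 1e-9
            elif isinstance(e, fc.Polyline):
                for x, y in e.points:
                    assert -1e-9 <= x <= W + 1e-9 and -1e-9 <= y <= H + 1e-9

    def test_panel_permutation_shifts_x_only(self, bundle, assembled):
        _spec, tree, tracks, prom = assembled
        spec_a = fc.FigureSpec(panels=[
            fc.PanelSpec("tree", 0.4), fc.PanelSpec("gene_structure", 0.6),
        ])
        spec_b = fc.FigureSpec(panels=[
            fc.PanelSpec("gene_structure", 0.6), fc.PanelSpec("tree", 0.4),
        ])
        sa = fc.build_scene(spec_a, tree=tree, models=bundle.models)
        sb = fc.build_scene(spec_b, tree=tree, models=bundle.models)
        # structure panel origin moves from 0.4*W (after tree) to 0
        shift = 0.4 * spec_a.canvas[0]
        ra = {e.id: e for e in sa.elements if isinstance(e, fc.Rect)}
        rb = {e.id: e for e in sb.elements if isinstance(e, fc.Rect)}
        assert set(ra) == set(rb)
        for eid, ea in ra.items():
            eb = rb[eid]
            # geometry relative to the panel origin is unchanged
            assert ea.w == pytest.approx(eb.w, abs=1e-9)
            assert ea.y == pytest.approx(eb.y, abs=1e-9)
            assert ea.h == pytest.approx(eb.h, abs=1e-9)
            assert ea.x - eb.x == pytest.approx(shift, abs=1e-9)


class TestRender:
    def test_empty_scene_valid_svg(self):
        data = fc.render(fc.SceneGraph(width=2.0, height=1.0), "svg")
        assert data.startswith(b"<?xml") and b"</svg>" in data

    def test_single_rect_svg_preserves_id(self):
        scene = fc.SceneGraph(width=2.0, height=1.0)
        scene.elements.append(
            fc.Rect(id="item1", x=0.1, y=0.1, w=0.5, h=0.2, fill="#ff0000")
        )
        svg = fc.render(scene, "svg").decode()
        assert svg.count("<rect") == 1 and 'id="item1"' in svg

    def test_png_pixel_dimensions_follow_dpi(self):
        import io

        from PIL import Image

        scene = fc.SceneGraph(width=10.0, height=4.0)
        png = fc.render(scene, "png", dpi=300)
        assert Image.open(io.BytesIO(png)).size == (3000, 1200)

    def test_pdf_smoke(self):
        scene = fc.SceneGraph(width=2.0, height=1.0)
        scene.elements.append(
            fc.Rect(id="r", x=0.1, y=0.1, w=0.5, h=0.2, fill="#ff0000")
        )
        data = fc.render(scene, "pdf")
        assert data.startswith(b"%PDF")

    def test_unsupported_format(self):
        with pytest.raises(ValueError, match="unsupported"):
            fc.render(fc.SceneGraph(width=1, height=1), "tiff")

    def test_byte_identical_svg_across_runs(self, bundle, assembled):
        spec, tree, tracks, prom = assembled
        runs = [
            fc.render(
                fc.build_scene(spec, tree=tree, models=bundle.models,
                               tracks=tracks, promoter_tracks=prom),
                "svg",
            )
            for _ in range(2)
        ]
        assert runs[0] == runs[1]


class TestFigureSpecValidation:
    def test_width_fractions_must_sum_to_one(self):
        with pytest.raises(fc.FigureError, match="sum"):
            fc.FigureSpec(panels=[fc.PanelSpec("tree", 0.5)])

    def test_at_most_one_tree_panel(self):
        with pytest.raises(fc.FigureError, match="tree"):
            fc.FigureSpec(panels=[
                fc.PanelSpec("tree", 0.5), fc.PanelSpec("tree", 0.5),
            ])

    def test_yaml_roundtrip(self):
        text = """
panels:
  - {kind: tree, width: 0.4}
  - {kind: gene_structure, width: 0.6, scale_bar: true}
canvas: [10, 4]
per_row_scaling: true
"""
        spec = fc.FigureSpec.from_yaml(text)
        assert [p.kind for p in spec.panels] == ["tree", "gene_structure"]
        assert spec.canvas == (10.0, 4.0) and spec.per_row_scaling
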
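"""Build the classic stitched figure: tree + gene structure + motif panel.

Generates a consistent synthetic bundle (42 genes, two clades), aligns every
panel row to the tree leaf order, and renders a deterministic SVG.
"""

from pathlib import Path

from genepanel import figure_compose as fc
from genepanel import fixtures, protein_tracks as pt, tree_model as tm

bundle = fixtures.synth_meme_and_domains(fixtures.FixtureConfig(seed=0))

tree = tm.assign_groups(tm.parse_newick(bundle.newick), bundle.group_of)
tracks = pt.attach_items(
    pt.read_meme(bundle.meme_xml).tracks,
    pt.read_domain_table(bundle.domains_tsv),
)

spec = fc.FigureSpec(
    panels=[
        fc.PanelSpec("tree", 0.30),
        fc.PanelSpec("gene_structure", 0.35, scale_bar=True),
        fc.PanelSpec("motif", 0.35),
    ],
    canvas=(14.0, 10.0),
)
scene = fc.build_scene(spec, tree=tree, models=bundle.models, tracks=tracks)
out = Path("stitched_figure.svg")
out.write_bytes(fc.render(scene, "svg"))
print(f"wrote {out} with {len(scene.elements)} primitives")
print("rows are tree leaves; motif box heights encode site p-values;")
print("domain outlines are superimposed so the motifs beneath stay visible")
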
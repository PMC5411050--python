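"""Render a 16-OTU Yule tree as a topographic map (SVG + PNG).

Generates a seeded random tree, lays it out, traces the per-level union
contours and writes both output formats plus the machine-readable layout
JSON. Prints the clade purity per elevation level: 1.0 means the spatial
grouping at that level exactly reproduces the tree's clades.
"""

from pathlib import Path

import topophylo as tp

out_dir = Path("example_output")
out_dir.mkdir(exist_ok=True)

tree = tp.yule_tree(tp.TreeGenSpec(kind="yule", n_leaves=16, seed=42))
result = tp.layout_tree(tree)

options = tp.RenderOptions(mode="polygons", show_links=True)
svg = tp.render_svg(tree, result.stacks, result.state, result.contours, options)
(out_dir / "topo16.svg").write_text(svg)
(out_dir / "topo16.png").write_bytes(
    tp.export_png(tree, result.stacks, result.state, options, png_scale=2.0)
)
doc = tp.layout_to_json(tree, result.stacks, result.state,
                        result.stack_config, result.force_config)
from topophylo.render import dumps_layout
(out_dir / "topo16.json").write_text(dumps_layout(doc))

print(f"layout converged in {result.state.iteration} iterations")
purity = tp.clade_purity(tree, result.contours)
for level in sorted(purity):
    n_bands = len(result.contours[level - 1].polygons)
    print(f"  level {level:2d}: {n_bands} contour band(s), "
          f"clade purity {purity[level]:.2f}")
print(f"wrote {out_dir}/topo16.svg, .png (2x), .json")
# Level 1 purity 1.0: the lowest elevation bands are exactly the root's
# clades — unrelated groups are separated by "valleys".
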
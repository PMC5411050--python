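"""SVG / PNG / JSON output of a topo-phylogeny layout.

Two SVG modes:

* ``polygons`` (default): each topographic level is a group of traced
  union-of-disks paths — fully vector, viewer-independent, printable.
* ``goo-circles``: each level is a group of raw circles sharing a
  blur-then-sharpen filter, reproducing the merged-blob look of the
  original browser DOM for visual comparison.

Levels are painted bottom-up (level 1 first) so higher plateaus are never
covered by the wider bands beneath them; link lines and labels go on top.
"""

from __future__ import annotations

import io
import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, asdict

from PIL import Image, ImageDraw

from .contour_geometry import LevelContours
from .force_layout import ForceConfig, LayoutState
from .stack_builder import CircleStack, StackConfig
from .tree_io import PhyloTree, parse_newick, write_newick

#: elevation ramp, low (level 1) to high: greens through tans to white
DEFAULT_PALETTE = [
    "#276419",
    "#4d9221",
    "#7fbc41",
    "#b8e186",
    "#e6f5d0",
    "#f6e8c3",
    "#dfc27d",
    "#bf812d",
    "#8c510a",
    "#f7f7f7",
]


@dataclass
class RenderOptions:
    mode: str = "polygons"  # polygons | goo-circles
    palette: list[str] = field(default_factory=lambda: list(DEFAULT_PALETTE))
    show_links: bool = False
    label_font_px: float = 11.0
    canvas_pad: float = 20.0
    png_scale: float = 1.0
    grid_px: float = 2.0

    def __post_init__(self) -> None:
        if not self.palette:
            raise ValueError("palette must be non-empty")
        if self.mode not in ("polygons", "goo-circles"):
            raise ValueError(f"unknown render mode {self.mode!r}")

    def level_color(self, level: int) -> str:
        return self.palette[(level - 1) % len(self.palette)]


def _canvas_bounds(
    stacks: dict[int, CircleStack],
    state: LayoutState,
    pad: float,
) -> tuple[float, float, float, float]:
    xs, ys, rs = [], [], []
    for leaf_id, stack in stacks.items():
        x, y = state.positions[leaf_id]
        xs.append(x)
        ys.append(y)
        rs.append(stack.bottom.radius)
    rmax = max(rs) if rs else 0.0
    x0 = min(xs) - rmax - pad
    x1 = max(xs) + rmax + pad
    y0 = min(ys) - rmax - pad
    y1 = max(ys) + rmax + pad
    return x0, y0, x1 - x0, y1 - y0


def _fmt(x: float) -> str:
    return f"{x:.2f}"


def render_svg(
    tree: PhyloTree,
    stacks: dict[int, CircleStack],
    state: LayoutState,
    contours: list[LevelContours] | None,
    options: RenderOptions,
) -> str:
    """Build the chart as an SVG 1.1 document (returned as text)."""
    if tree.n_leaves == 0:
        raise ValueError("cannot render an empty tree")
    if options.mode == "polygons" and contours is None:
        raise ValueError("polygons mode requires traced contours")

    x0, y0, w, h = _canvas_bounds(stacks, state, options.canvas_pad)
    svg = ET.Element(
        "svg",
        {
            "xmlns": "http://www.w3.org/2000/svg",
            "version": "1.1",
            "width": _fmt(w),
            "height": _fmt(h),
            "viewBox": f"{_fmt(x0)} {_fmt(y0)} {_fmt(w)} {_fmt(h)}",
        },
    )

    if options.mode == "goo-circles":
        defs = ET.SubElement(svg, "defs")
        filt = ET.SubElement(
            defs, "filter", {"id": "goo", "x": "-50%", "y": "-50%",
                             "width": "200%", "height": "200%"}
        )
        ET.SubElement(
            filt, "feGaussianBlur",
            {"in": "SourceGraphic", "stdDeviation": "10", "result": "blur"},
        )
        ET.SubElement(
            filt, "feColorMatrix",
            {
                "in": "blur",
                "mode": "matrix",
                "values": "1 0 0 0 0  0 1 0 0 0  0 0 1 0 0  0 0 0 18 -7",
            },
        )

    levels_g = ET.SubElement(svg, "g", {"id": "levels"})
    max_level = tree.max_depth
    for level in range(1, max_level + 1):  # bottom-up paint order
        color = options.level_color(level)
        if options.mode == "polygons":
            lc = contours[level - 1]
            g = ET.SubElement(
                levels_g, "g",
                {"class": "level", "data-level": str(level), "fill": color},
            )
            for poly in lc.polygons:
                d = "M " + " L ".join(
                    f"{_fmt(px)} {_fmt(py)}" for px, py in poly
                ) + " Z"
                ET.SubElement(g, "path", {"d": d})
        else:
            g = ET.SubElement(
                levels_g, "g",
                {
                    "class": "level",
                    "data-level": str(level),
                    "fill": color,
                    "filter": "url(#goo)",
                },
            )
            for leaf_id, stack in stacks.items():
                for c in stack.circles:
                    if c.level == level:
                        x, y = state.positions[leaf_id]
                        ET.SubElement(
                            g, "circle",
                            {"cx": _fmt(x), "cy": _fmt(y), "r": _fmt(c.radius)},
                        )

    if options.show_links:
        svg.append(draw_links(tree, state))

    labels = ET.SubElement(svg, "g", {"id": "labels"})
    for leaf in tree.leaves:
        x, y = state.positions[leaf.id]
        t = ET.SubElement(
            labels, "text",
            {
                "x": _fmt(x),
                "y": _fmt(y),
                "text-anchor": "middle",
                "dominant-baseline": "central",
                "font-size": _fmt(options.label_font_px),
                "font-family": "sans-serif",
            },
        )
        t.text = leaf.name or str(leaf.id)

    return ET.tostring(svg, encoding="unicode")


def draw_links(tree: PhyloTree, state: LayoutState) -> ET.Element:
    """Link-line overlay: one line per tree edge, drawn above the bands."""
    g = ET.Element("g", {"id": "links", "stroke": "#555", "stroke-width": "1"})
    for node in tree.nodes():
        for child in node.children:
            x1, y1 = state.positions[node.id]
            x2, y2 = state.positions[child.id]
            ET.SubElement(
                g, "line",
                {"x1": _fmt(x1), "y1": _fmt(y1), "x2": _fmt(x2), "y2": _fmt(y2)},
            )
    return g


def _hex_to_rgba(color: str, alpha: int = 255) -> tuple[int, int, int, int]:
    c = color.lstrip("#")
    return int(c[0:2], 16), int(c[2:4], 16), int(c[4:6], 16), alpha


def export_png(
    tree: PhyloTree,
    stacks: dict[int, CircleStack],
    state: LayoutState,
    options: RenderOptions,
    png_scale: float | None = None,
) -> bytes:
    """Rasterize the chart to PNG bytes at ``png_scale`` x nominal size.

    Draws the same scene directly: per level, all circles in one flat
    color — overlapping same-color disks *are* the union silhouette, so
    the topographic bands come out exactly without any blur filter.
    Transparent background (RGBA).
    """
    scale = options.png_scale if png_scale is None else png_scale
    if scale <= 0:
        raise ValueError("png_scale must be positive")
    x0, y0, w, h = _canvas_bounds(stacks, state, options.canvas_pad)
    W, H = max(1, int(round(w * scale))), max(1, int(round(h * scale)))
    img = Image.new("RGBA", (W, H), (0, 0, 0, 0))
    draw = ImageDraw.Draw(img)

    def to_px(x: float, y: float) -> tuple[float, float]:
        return (x - x0) * scale, (y - y0) * scale

    for level in range(1, tree.max_depth + 1):
        fill = _hex_to_rgba(options.level_color(level))
        for leaf_id, stack in stacks.items():
            for c in stack.circles:
                if c.level == level:
                    cx, cy = to_px(*state.positions[leaf_id])
                    r = c.radius * scale
                    draw.ellipse((cx - r, cy - r, cx + r, cy + r), fill=fill)

    if options.show_links:
        for node in tree.nodes():
            for child in node.children:
                draw.line(
                    [to_px(*state.positions[node.id]),
                     to_px(*state.positions[child.id])],
                    fill=(85, 85, 85, 255),
                )

    for leaf in tree.leaves:
        cx, cy = to_px(*state.positions[leaf.id])
        draw.text((cx, cy), leaf.name or str(leaf.id),
                  fill=(0, 0, 0, 255), anchor="mm")

    buf = io.BytesIO()
    img.save(buf, format="PNG")
    return buf.getvalue()


def layout_to_json(
    tree: PhyloTree,
    stacks: dict[int, CircleStack],
    state: LayoutState,
    stack_config: StackConfig | None = None,
    force_config: ForceConfig | None = None,
) -> dict:
    """Machine-readable layout export; round-trips losslessly.

    Carries the Newick text (topology + lengths), per-node positions, the
    per-leaf radii, the resolved configs and the convergence report —
    enough to re-render an identical chart without re-running the forces.
    """
    nodes = []
    for node in tree.nodes():
        rec = {
            "id": node.id,
            "name": node.name,
            "depth": node.depth,
            "parent": node.parent.id if node.parent else None,
            "x": state.positions[node.id][0],
            "y": state.positions[node.id][1],
        }
        if node.is_leaf:
            rec["radii"] = [
                {"level": c.level, "radius": c.radius}
                for c in stacks[node.id].circles
            ]
        nodes.append(rec)
    doc = {
        "newick": write_newick(tree),
        "nodes": nodes,
        "convergence": {
            "iterations": state.iteration,
            "converged": state.converged,
            "max_displacement": max(state.last_displacement.values())
            if state.last_displacement
            else 0.0,
        },
    }
    if stack_config is not None:
        doc["stack_config"] = asdict(stack_config)
    if force_config is not None:
        doc["force_config"] = asdict(force_config)
    return doc


def layout_from_json(doc: dict) -> tuple[PhyloTree, dict[int, CircleStack], LayoutState]:
    """Rebuild (tree, stacks, state) from a :func:`layout_to_json` export."""
    tree = parse_newick(doc["newick"])
    positions = {n["id"]: (n["x"], n["y"]) for n in doc["nodes"]}
    from .stack_builder import Circle  # local: avoid polluting module surface

    stacks: dict[int, CircleStack] = {}
    for n in doc["nodes"]:
        if "radii" in n:
            circles = [
                Circle(level=r["level"], radius=r["radius"], area_raw=0.0)
                for r in n["radii"]
            ]
            stacks[n["id"]] = CircleStack(leaf_id=n["id"], circles=circles)
    conv = doc.get("convergence", {})
    state = LayoutState(
        positions=positions,
        last_displacement={nid: 0.0 for nid in positions},
        iteration=int(conv.get("iterations", 0)),
        converged=bool(conv.get("converged", True)),
    )
    return tree, stacks, state


def dumps_layout(doc: dict) -> str:
    return json.dumps(doc, indent=2, sort_keys=False)
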
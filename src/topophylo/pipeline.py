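"""One-call pipeline: Newick text to converged topographic layout."""

from __future__ import annotations

from dataclasses import dataclass, replace

from .contour_geometry import LevelContours, extract_all_contours
from .force_layout import ForceConfig, LayoutState, run
from .radial_init import HomePositions, default_tightness, home_positions
from .stack_builder import CircleStack, StackConfig, build_all_stacks, resolve_unit_scale
from .tree_io import PhyloTree, parse_newick


@dataclass
class LayoutResult:
    tree: PhyloTree
    stacks: dict[int, CircleStack]
    home: HomePositions
    state: LayoutState
    contours: list[LevelContours]
    stack_config: StackConfig
    force_config: ForceConfig


def layout_tree(
    tree: PhyloTree,
    stack_config: StackConfig | None = None,
    force_config: ForceConfig | None = None,
    tightness: float | None = None,
    grid_px: float = 2.0,
    trace_contours: bool = True,
) -> LayoutResult:
    """Build stacks, place homes, run the force layout, trace contours."""
    scfg = stack_config or StackConfig()
    fcfg = force_config or ForceConfig()
    # freeze the per-tree automatic scale so exports are reproducible
    scfg = replace(scfg, unit_scale=resolve_unit_scale(tree, scfg))
    stacks = build_all_stacks(tree, scfg)
    tight = tightness if tightness is not None else default_tightness(tree, scfg)
    home = home_positions(tree, tight)
    state = run(tree, stacks, home, fcfg)
    contours: list[LevelContours] = []
    if trace_contours:
        contours = extract_all_contours(
            stacks, state.positions, tree.max_depth, grid_px
        )
    return LayoutResult(
        tree=tree,
        stacks=stacks,
        home=home,
        state=state,
        contours=contours,
        stack_config=scfg,
        force_config=fcfg,
    )


def layout_newick(text: str, **kwargs) -> LayoutResult:
    return layout_tree(parse_newick(text), **kwargs)
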
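"""Force simulation that settles leaves at phylogeny-derived distances.

Every leaf pair carries one piecewise interaction whose rest length is set
by the pair's most recent common ancestor: the two stack circles *one level
below* the MRCA plus a safety margin. Above rest length the pair attracts
with a strength that decays geometrically with each level of
unrelatedness; below it the pair repels at full strength, enforced as a
positional separation constraint so pairs settle at (not merely near) their
rest distances. Internal nodes are drawn toward their radial "home"
positions and toward the centroid of their children. Each iteration is a
stiffness-weighted relaxation move scaled by a cooling step size followed
by a few separation sweeps; the run stops when every node's displacement
drops below ``conv_eps`` — i.e. 100% of the nodes stop moving — or the
iteration cap is hit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .radial_init import HomePositions
from .stack_builder import CircleStack
from .tree_io import PhyloTree, TreeNode, mrca_depth

logger = logging.getLogger(__name__)

#: per-node displacement cap, px per iteration; prevents a node from
#: tunnelling through another stack in one move
DISPLACEMENT_CAP = 20.0

#: multiplicative step-size decay per iteration (cooling, guarantees halt)
COOLING = 0.999

#: separation (repulsion) projection sweeps per iteration; enough that
#: residual pair overlaps at convergence stay well under a pixel
SEPARATION_SWEEPS = 16


@dataclass
class ForceConfig:
    k_pair: float = 0.02  # leaf-pair spring weight
    k_home: float = 0.05  # internal-node home spring weight
    k_child: float = 0.03  # internal-node -> children-centroid weight
    relatedness_decay: float = 0.5  # attraction falloff per level of unrelatedness
    sep_margin: float = 10.0  # px added to rest distances; < gap_min
    step_size: float = 0.8  # displacement multiplier, cooled per iteration
    conv_eps: float = 0.1  # px; below this a node counts as stopped
    max_iters: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.k_pair, self.k_home, self.k_child) < 0:
            raise ValueError("stiffnesses must be non-negative")
        if not 0 < self.relatedness_decay <= 1:
            raise ValueError("relatedness_decay must be in (0, 1]")
        if not 0 < self.sep_margin < 30:
            raise ValueError("sep_margin must be in (0, 2*gap_min)")
        if self.conv_eps <= 0:
            raise ValueError("conv_eps must be positive")


@dataclass
class LayoutState:
    positions: dict[int, tuple[float, float]]
    last_displacement: dict[int, float]
    iteration: int = 0
    converged: bool = False
    _sim: Optional["ForceSimulation"] = field(default=None, repr=False, compare=False)


def rest_distance(
    u: TreeNode,
    v: TreeNode,
    stacks: dict[int, CircleStack],
    tree: PhyloTree,
    sep_margin: float = 10.0,
) -> float:
    """Equilibrium separation of two terminal nodes.

    With d = depth of the MRCA, the rest distance is the sum of the two
    stack radii at level d+1 plus the margin: sisters rest at their small
    label circles, root-only relatives at their biggest circles. Circles
    strictly above the MRCA level therefore cannot overlap at rest, while
    circles at the MRCA level and below can merge (each stack's gap of at
    least gap_min exceeds the margin).
    """
    if not (u.is_leaf and v.is_leaf):
        raise ValueError("rest_distance is defined for terminal nodes only")
    d = mrca_depth(tree, u, v)
    return (
        stacks[u.id].radius_at(d + 1)
        + stacks[v.id].radius_at(d + 1)
        + sep_margin
    )


def pair_stiffness(u: TreeNode, v: TreeNode, tree: PhyloTree, config: ForceConfig) -> float:
    """Attraction weight: maximal for sisters, geometrically weaker with
    every level separating the leaf from the pair's MRCA."""
    d = mrca_depth(tree, u, v)
    return config.k_pair * config.relatedness_decay ** (u.depth - d - 1)


class ForceSimulation:
    """Precomputed pairwise structure + vectorized relaxation steps."""

    def __init__(
        self,
        tree: PhyloTree,
        stacks: dict[int, CircleStack],
        home: HomePositions,
        config: ForceConfig,
    ):
        self.tree = tree
        self.config = config
        self.node_ids = [n.id for n in tree.nodes()]
        self.index = {nid: k for k, nid in enumerate(self.node_ids)}
        nodes = {n.id: n for n in tree.nodes()}
        self.leaf_idx = np.array(
            [self.index[leaf.id] for leaf in tree.leaves], dtype=int
        )
        m = len(self.leaf_idx)

        # pairwise rest distances and attraction weights among leaves
        self.rest = np.zeros((m, m))
        self.attract_w = np.zeros((m, m))
        for a, u in enumerate(tree.leaves):
            for b, v in enumerate(tree.leaves):
                if a == b:
                    continue
                self.rest[a, b] = rest_distance(
                    u, v, stacks, tree, config.sep_margin
                )
                self.attract_w[a, b] = pair_stiffness(u, v, tree, config)

        # internal nodes: home anchors and children index lists
        self.internal_idx = np.array(
            [self.index[n.id] for n in tree.nodes() if not n.is_leaf], dtype=int
        )
        self.home_xy = np.array(
            [home[nid] for nid in self.node_ids], dtype=float
        )
        self.children: list[list[int]] = [
            [self.index[c.id] for c in nodes[nid].children] for nid in self.node_ids
        ]

    def initial_state(self, home: HomePositions) -> LayoutState:
        positions = {nid: home[nid] for nid in self.node_ids}
        return LayoutState(
            positions=positions,
            last_displacement={nid: float("inf") for nid in self.node_ids},
            iteration=0,
            converged=False,
            _sim=self,
        )

    def _as_array(self, state: LayoutState) -> np.ndarray:
        return np.array([state.positions[nid] for nid in self.node_ids], dtype=float)

    def _leaf_geometry(
        self, pos: np.ndarray, iteration: int
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Pairwise diff/dist with deterministic jitter on exact ties."""
        cfg = self.config
        diff = pos[:, None, :] - pos[None, :, :]
        dist = np.sqrt((diff**2).sum(axis=2))
        tied = (dist < 1e-9) & ~np.eye(len(pos), dtype=bool)
        if tied.any():
            rng = np.random.default_rng(cfg.seed + iteration)
            jitter = rng.normal(size=pos.shape)
            jitter *= 0.5 / np.maximum(
                np.linalg.norm(jitter, axis=1, keepdims=True), 1e-12
            )
            rows = np.unique(np.nonzero(tied)[0])
            pos = pos.copy()
            pos[rows] += jitter[rows]
            diff = pos[:, None, :] - pos[None, :, :]
            dist = np.sqrt((diff**2).sum(axis=2))
        np.fill_diagonal(dist, 1.0)  # self-distance placeholder
        return pos, diff, dist

    def step(self, state: LayoutState) -> LayoutState:
        cfg = self.config
        P0 = self._as_array(state)
        P = P0.copy()
        step_t = cfg.step_size * COOLING**state.iteration

        L = self.leaf_idx
        if len(L) > 1:
            # attraction: stiffness-weighted relaxation toward rest length
            pos, diff, dist = self._leaf_geometry(P[L], state.iteration)
            unit = diff / dist[:, :, None]
            err = self.rest - dist  # <0: too far apart, pull together
            np.fill_diagonal(err, 0.0)
            weight = np.where(err < 0, self.attract_w, cfg.k_pair)
            np.fill_diagonal(weight, 0.0)
            # each spring asks this endpoint to move half the error outward
            corr = 0.5 * np.where(err < 0, err, 0.0)[:, :, None] * unit
            wsum = weight.sum(axis=1)
            num = (weight[:, :, None] * corr).sum(axis=1)
            ok = wsum > 0
            disp_attr = np.zeros_like(pos)
            disp_attr[ok] = step_t * num[ok] / wsum[ok, None]
            norms = np.linalg.norm(disp_attr, axis=1)
            over = norms > DISPLACEMENT_CAP
            if over.any():
                disp_attr[over] *= (DISPLACEMENT_CAP / norms[over])[:, None]
            P[L] = pos + disp_attr

            # repulsion: project violated pairs back to their rest
            # distances (full strength regardless of relatedness)
            for _ in range(SEPARATION_SWEEPS):
                pos, diff, dist = self._leaf_geometry(P[L], state.iteration)
                overlap = self.rest - dist
                np.fill_diagonal(overlap, 0.0)
                violated = overlap > 0
                if not violated.any():
                    break
                unit = diff / dist[:, :, None]
                push = 0.5 * np.where(violated, overlap, 0.0)[:, :, None] * unit
                counts = np.maximum(violated.sum(axis=1), 1)
                P[L] = pos + push.sum(axis=1) / counts[:, None]

        for i in self.internal_idx:
            corr_home = self.home_xy[i] - P0[i]
            kids = self.children[i]
            centroid = P0[kids].mean(axis=0)
            corr_child = centroid - P0[i]
            wsum = cfg.k_home + cfg.k_child
            if wsum > 0:
                move = step_t * (
                    cfg.k_home * corr_home + cfg.k_child * corr_child
                ) / wsum
                norm = float(np.linalg.norm(move))
                if norm > DISPLACEMENT_CAP:
                    move *= DISPLACEMENT_CAP / norm
                P[i] = P0[i] + move

        total = np.linalg.norm(P - P0, axis=1)
        positions = {nid: (float(P[k, 0]), float(P[k, 1])) for k, nid in enumerate(self.node_ids)}
        last = {nid: float(total[k]) for k, nid in enumerate(self.node_ids)}
        return LayoutState(
            positions=positions,
            last_displacement=last,
            iteration=state.iteration + 1,
            converged=bool(total.max(initial=0.0) < cfg.conv_eps),
            _sim=self,
        )


def step(
    state: LayoutState,
    tree: PhyloTree,
    stacks: dict[int, CircleStack],
    home: HomePositions,
    config: ForceConfig,
) -> LayoutState:
    """One relaxation iteration (see :class:`ForceSimulation`)."""
    sim = state._sim
    if sim is None or sim.tree is not tree or sim.config is not config:
        sim = ForceSimulation(tree, stacks, home, config)
        state = replace(state, _sim=sim)
    return sim.step(state)


def run(
    tree: PhyloTree,
    stacks: dict[int, CircleStack],
    home: HomePositions,
    config: ForceConfig,
    log_every: int = 100,
) -> LayoutState:
    """Iterate until 100% of nodes stop moving, or ``max_iters``.

    Deterministic for a fixed (tree, config, seed). ``converged`` is False
    when the cap stops the run first; positions are still usable (this is
    the freeze-the-display behaviour for charts with no ideal layout).
    """
    sim = ForceSimulation(tree, stacks, home, config)
    state = sim.initial_state(home)
    while state.iteration < config.max_iters:
        state = sim.step(state)
        if log_every and state.iteration % log_every == 0:
            logger.info(
                "iteration %d: max displacement %.3f px",
                state.iteration,
                max(state.last_displacement.values()),
            )
        if state.converged:
            logger.info("converged at iteration %d", state.iteration)
            return state
    logger.warning(
        "iteration cap %d reached without full convergence", config.max_iters
    )
    return state
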
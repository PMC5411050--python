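"""Force layout: rest distances, stiffness, equilibria, convergence."""

import math

import pytest

import topophylo as tp
from topophylo.force_layout import ForceConfig, ForceSimulation
from topophylo.stack_builder import StackConfig


def _dist(state, u, v):
    (x1, y1), (x2, y2) = state.positions[u.id], state.positions[v.id]
    return math.hypot(x1 - x2, y1 - y2)


class TestRestDistance:
    def test_sisters_rest_at_label_circles(self, three_leaf_tree):
        cfg = StackConfig()
        stacks = tp.build_all_stacks(three_leaf_tree, cfg)
        a, b, _ = three_leaf_tree.leaves
        rest = tp.rest_distance(a, b, stacks, three_leaf_tree, 10.0)
        assert rest == pytest.approx(2 * cfg.top_radius + 10.0)

    def test_root_relatives_rest_at_biggest_circles(self, three_leaf_tree):
        stacks = tp.build_all_stacks(three_leaf_tree, StackConfig())
        a, _, c = three_leaf_tree.leaves
        rest = tp.rest_distance(a, c, stacks, three_leaf_tree, 10.0)
        expected = stacks[a.id].radius_at(1) + stacks[c.id].radius_at(1) + 10.0
        assert rest == pytest.approx(expected)

    def test_deepest_mrca_gives_smallest_rest(self, yule16):
        stacks = tp.build_all_stacks(yule16, StackConfig())
        pairs = [
            (u, v)
            for i, u in enumerate(yule16.leaves)
            for v in yule16.leaves[i + 1:]
        ]
        rests = {
            (u.id, v.id): tp.rest_distance(u, v, stacks, yule16, 10.0)
            for u, v in pairs
        }
        deepest = max(pairs, key=lambda p: tp.mrca_depth(yule16, *p))
        assert rests[(deepest[0].id, deepest[1].id)] == min(rests.values())

    def test_internal_node_rejected(self, three_leaf_tree):
        stacks = tp.build_all_stacks(three_leaf_tree, StackConfig())
        with pytest.raises(ValueError):
            tp.rest_distance(
                three_leaf_tree.root,
                three_leaf_tree.leaves[0],
                stacks,
                three_leaf_tree,
            )


class TestPairStiffness:
    def test_sisters_full_strength(self, three_leaf_tree):
        cfg = ForceConfig()
        a, b, _ = three_leaf_tree.leaves
        assert tp.pair_stiffness(a, b, three_leaf_tree, cfg) == cfg.k_pair

    def test_one_level_less_related_halves(self, three_leaf_tree):
        cfg = ForceConfig()
        a, _, c = three_leaf_tree.leaves
        # a has depth 2, mrca(a, c) = 0 -> decay^(2-0-1) = 0.5
        assert tp.pair_stiffness(a, c, three_leaf_tree, cfg) == pytest.approx(
            cfg.k_pair * 0.5
        )

    def test_geometric_decay_with_depth(self):
        cfg = ForceConfig()
        tree = tp.caterpillar_tree(6)
        deepest = max(tree.leaves, key=lambda l: l.depth)
        shallow = next(l for l in tree.leaves if l.depth == 1)
        got = tp.pair_stiffness(deepest, shallow, tree, cfg)
        assert got == pytest.approx(cfg.k_pair * 0.5 ** (deepest.depth - 1))


class TestStep:
    def _pair_setup(self):
        tree = tp.parse_newick("(A:1,B:1);")
        scfg = StackConfig()
        stacks = tp.build_all_stacks(tree, scfg)
        home = tp.home_positions(tree, 100.0)
        fcfg = ForceConfig()
        sim = ForceSimulation(tree, stacks, home, fcfg)
        return tree, stacks, home, fcfg, sim

    def test_pair_at_rest_is_fixed_point_for_leaves(self):
        tree, stacks, home, fcfg, sim = self._pair_setup()
        a, b = tree.leaves
        rest = tp.rest_distance(a, b, stacks, tree, fcfg.sep_margin)
        state = sim.initial_state(home)
        state.positions[a.id] = (-rest / 2, 0.0)
        state.positions[b.id] = (rest / 2, 0.0)
        out = sim.step(state)
        assert out.last_displacement[a.id] == pytest.approx(0.0, abs=1e-9)
        assert out.last_displacement[b.id] == pytest.approx(0.0, abs=1e-9)

    def test_overlapping_pair_separates(self):
        tree, stacks, home, fcfg, sim = self._pair_setup()
        a, b = tree.leaves
        state = sim.initial_state(home)
        state.positions[a.id] = (-5.0, 0.0)
        state.positions[b.id] = (5.0, 0.0)
        out = sim.step(state)
        assert _dist(out, a, b) > 10.0

    def test_symmetric_trifurcation_stays_mirror_symmetric(self):
        """All-sister 3-leaf star: reflection symmetry across the x-axis
        is preserved through the whole run."""
        tree = tp.parse_newick("(A:1,B:1,C:1);")
        res = tp.layout_tree(tree, trace_contours=False)
        a, b, c = (res.state.positions[l.id] for l in tree.leaves)
        assert a[1] == pytest.approx(0.0, abs=1e-9)
        assert b[0] == pytest.approx(c[0], abs=1e-9)
        assert b[1] == pytest.approx(-c[1], abs=1e-9)


class TestRun:
    def test_single_leaf_converges_leaf_unmoved(self):
        tree = tp.parse_newick("(A:1);")
        res = tp.layout_tree(tree, trace_contours=False)
        assert res.state.converged
        leaf = tree.leaves[0]
        assert res.state.positions[leaf.id] == pytest.approx(res.home[leaf.id])

    def test_two_leaf_separation_matches_analytic_rest(self):
        tree = tp.parse_newick("(A:1,B:1);")
        res = tp.layout_tree(tree, trace_contours=False)
        a, b = tree.leaves
        rest = tp.rest_distance(
            a, b, res.stacks, tree, res.force_config.sep_margin
        )
        assert res.state.converged
        assert abs(_dist(res.state, a, b) - rest) < 10 * res.force_config.conv_eps

    def test_sixteen_leaf_fixture_converges(self, yule16_layout):
        state = yule16_layout.state
        cfg = yule16_layout.force_config
        assert state.converged
        assert all(d < cfg.conv_eps for d in state.last_displacement.values())

    def test_deterministic_for_fixed_seed(self, yule16):
        r1 = tp.layout_tree(yule16, trace_contours=False)
        r2 = tp.layout_tree(yule16, trace_contours=False)
        assert r1.state.positions == r2.state.positions
        assert r1.state.iteration == r2.state.iteration

    def test_separation_property(self, yule16, yule16_layout):
        """Converged leaf pairs sit at no less than rest distance - 1 px."""
        res = yule16_layout
        for i, u in enumerate(yule16.leaves):
            for v in yule16.leaves[i + 1:]:
                rest = tp.rest_distance(
                    u, v, res.stacks, yule16, res.force_config.sep_margin
                )
                assert _dist(res.state, u, v) >= rest - 1.0

    def test_merge_property_sisters_overlap_at_parent_level(
        self, yule16, yule16_layout
    ):
        """Sister leaves' circles at their parent's level overlap."""
        res = yule16_layout
        found = False
        for i, u in enumerate(yule16.leaves):
            for v in yule16.leaves[i + 1:]:
                if u.parent is v.parent:
                    d = tp.mrca_depth(yule16, u, v)
                    r_sum = res.stacks[u.id].radius_at(d) + res.stacks[
                        v.id
                    ].radius_at(d)
                    assert _dist(res.state, u, v) < r_sum
                    found = True
        assert found

    def test_iteration_cap_reports_nonconvergence(self, yule16):
        res = tp.layout_tree(
            yule16,
            force_config=ForceConfig(max_iters=3),
            trace_contours=False,
        )
        assert not res.state.converged
        assert res.state.iteration == 3

    def test_coincident_leaves_resolved_by_seeded_jitter(self):
        tree = tp.parse_newick("(A:1,B:1);")
        stacks = tp.build_all_stacks(tree, StackConfig())
        home = tp.home_positions(tree, 100.0)
        fcfg = ForceConfig(seed=5)
        sim = ForceSimulation(tree, stacks, home, fcfg)
        state = sim.initial_state(home)
        a, b = tree.leaves
        state.positions[a.id] = (0.0, 0.0)
        state.positions[b.id] = (0.0, 0.0)
        out = sim.step(state)
        assert _dist(out, a, b) > 0.0
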
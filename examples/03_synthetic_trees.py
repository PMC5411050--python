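"""Generate the three synthetic tree shapes and compare their geometry.

Yule (random birth), caterpillar (fully pectinate) and balanced trees
exercise very different stack shapes: caterpillars give a staircase of
stack sizes, balanced trees give uniform stacks, Yule trees something in
between.
"""

import topophylo as tp

trees = {
    "yule (n=16, seed 42)": tp.yule_tree(
        tp.TreeGenSpec(kind="yule", n_leaves=16, seed=42)
    ),
    "caterpillar (n=8)": tp.caterpillar_tree(8),
    "balanced (depth 4)": tp.balanced_tree(4),
}

cfg = tp.StackConfig()
for name, tree in trees.items():
    stacks = tp.build_all_stacks(tree, cfg)
    sizes = sorted(len(s.circles) for s in stacks.values())
    print(f"{name}: {tree.n_leaves} leaves, max depth {tree.max_depth}")
    print(f"  stack sizes (= leaf depths): {sizes}")
    biggest = max(s.bottom.radius for s in stacks.values())
    print(f"  largest bottom circle: {biggest:.0f} px")
    print(f"  newick: {tp.write_newick(tree)[:60]}...")
# Stack size equals leaf depth; bottom-circle radius grows by 15-30 px per
# level, so deep leaves carry visibly wider "mountains".
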
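# topophylo

Phylogenetic trees drawn as topographic maps.

Large phylogenies are hard to read as trees: deciding how two operational
taxonomic units (OTUs) are related means consciously tracing branches back
to a common ancestor. `topophylo` renders the same rooted tree as a
*topo-phylogeny*: each OTU becomes a stack of concentric circles — one
circle per ancestor level, sized by cumulative branch length — and a force
simulation settles the stacks at distances keyed to common-ancestor depth.
Circles of the same level merge into nested "elevation" bands, so clades
appear as mountains separated by valleys, and relatedness can be read off
at a glance: OTUs enclosed by the same contour share an ancestor at that
level.

The package is aimed at anyone exploring evolutionary or other
hierarchical data who wants a nested (container) view to complement the
standard phylogram: it reads Newick, writes publication-ready SVG and PNG,
and exports a machine-readable layout JSON.

## The method

For a leaf at depth *D* with cumulative branch length *L(d)* from the leaf
up to its depth-*d* ancestor, the circle at level *d* has radius

    r(d) = sqrt(s * L(d) / pi)

with *s* a pixels²-per-tree-unit scale, and consecutive radii clamped so
that `r(d) - r(d+1)` lies in [15, 30] px. The smallest (label) circle sits
at the leaf's own depth; the largest, at level 1, encodes relatedness at
the root.

Nodes start at radial-phylogram "home" positions (radius = tightness x
depth, angle = mean of child angles) so clades begin uncrossed. Leaves
then interact pairwise: with *d* = depth of the pair's most recent common
ancestor, the rest distance is

    rest(u, v) = r_u(d+1) + r_v(d+1) + margin

so sister OTUs rest label-circle to label-circle while root-level
relatives rest at their biggest circles. Pairs farther apart than rest
attract with strength decaying by 0.5 per level of unrelatedness; pairs
closer than rest are pushed back out at full strength. Internal nodes are
drawn toward their homes and their children's centroid. The simulation
stops automatically when 100% of the nodes stop moving (per-iteration
displacement below 0.1 px).

Per level, the union outline of all circles — the topographic band — is
traced as the zero isocontour of the signed distance field
`f(x) = min_i(|x - c_i| - r_i)` by marching squares, and each band is
mapped to the exact set of leaves it encloses.

## Worked example

```sh
python examples/01_layout_small_tree.py
```

```
5 OTUs, max depth 3, total branch length 5.60
layout: 1278 iterations, converged=True

  A: position (  393.9,   186.0)  stack radii top->bottom: 12, 42, 72 px
  B: position (  395.6,   219.9)  stack radii top->bottom: 12, 42, 72 px
  C: position (  332.3,   229.0)  stack radii top->bottom: 12, 42 px
  ...
  sisters A,B: distance 34.0 px, rest distance 34.0 px
  root-level A,E: distance 124.0 px, rest distance 124.0 px
```

Sisters A and B settle 34 px apart — their two 12 px label circles plus
the 10 px margin — so every circle below their parent's level overlaps and
they share all higher elevation bands. A and E, related only at the root,
settle 124 px apart: their biggest circles just clear each other, leaving
a valley. `examples/02_render_topographic_map.py` renders a 16-OTU random
tree and prints, per level, the number of contour bands and the *clade
purity* (1.00 at every level for the seeded example: each band encloses
exactly one clade of the tree).

## Command line

```sh
topophylo gen-tree --kind yule --n 16 --seed 42 --out tree.nwk
topophylo layout tree.nwk --out layout.json        # exit 3 if iteration-capped
topophylo render layout.json --svg map.svg --png map.png --links
```

`render` accepts either a stored layout JSON or a raw Newick file; every
run writes a manifest with the resolved configuration, seed, iteration
count and convergence flag. The layout JSON schema: a `newick` string,
one record per node (`id`, `name`, `depth`, `parent`, `x`, `y`, plus the
ordered `radii` for leaves), the resolved configs, and a convergence
report.

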
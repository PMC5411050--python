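# Methods

## Model

A rooted phylogeny with branch lengths is re-encoded as geometry in three
stages.

**Circle stacks.** Each terminal node (OTU) carries one circle per
ancestor level d in 1..depth(leaf). The circle's area is proportional to
the cumulative branch length from the leaf up to (but excluding the edge
above) its depth-d ancestor, so radius = sqrt(area / pi); deeper
divergence means visibly wider "mountains". Cumulative length is measured
leaf-to-ancestor, which puts the biggest circle at the bottom (root side)
of the stack — the only orientation consistent with sisters resting at
their smallest circles and root-level relatives at their biggest.
Consecutive radii are clamped to differ by at least `gap_min` = 15 px
(keeps near-zero branches visible) and at most `gap_max` = 30 px (keeps
long branches bounded); clamping proceeds sequentially from the label
circle downward, which makes radii strictly increasing by construction.
The label circle radius is a constant 12 px rather than font-metric
derived — label sizing is renderer-dependent and does not affect the
geometry the method is about. The area scale `unit_scale` (px² per tree
unit) defaults to the value that puts the deepest leaf's unclamped
level-1 radius at 150 px, which keeps typical gaps inside the clamp band
across very differently scaled trees; it can be fixed explicitly for
cross-tree comparability.

**Initial placement.** Leaves are spread uniformly on a circle in Newick
order; every node sits at radius `tightness * depth` with angle equal to
the arithmetic mean of its children's angles. Because leaf angles are
monotone in Newick order, each clade occupies a contiguous angular sector
and its internal nodes stay inside it, so no two clades start crossed. An
arithmetic rather than circular mean is used deliberately: a circular
mean of child angles can leave the sector once a clade spans more than
half the circle. Default tightness is `3 * gap_max * mean leaf depth`, so
initial spacing comfortably exceeds typical rest distances and the
simulation starts expansion-free.

**Force layout.** Every leaf pair (u, v) has one piecewise interaction
with rest length `r_u(d+1) + r_v(d+1) + sep_margin`, where d is the depth
of the pair's most recent common ancestor and `r_x(l)` is x's stack
radius at level l. Since per-stack gaps (>= 15 px) exceed `sep_margin`
(10 px), circles strictly above the MRCA level cannot overlap at rest
while circles at the MRCA level and below must — this single inequality
is what makes contour bands coincide with clades. Above rest length the
pair attracts with weight `k_pair * decay^(depth(u) - d - 1)` (sisters
strongest, relatedness halving per level at the default decay of 0.5);
below rest length it repels at full strength.

The integrator is a weighted constraint relaxation rather than a raw
force sum. Each iteration:

1. *Attraction pass*: every node moves by `step * (sum_i w_i * c_i) /
   (sum_i w_i)`, where each spring contributes the correction `c_i` (half
   the length error along the pair axis for leaves; the full offset to
   the home position with weight `k_home`, and to the children's centroid
   with weight `k_child`, for internal nodes). Normalising by total
   weight makes stiffnesses act as relative priorities and makes the
   residual length error at convergence about `2 * conv_eps / step`
   (≈ 0.25 px at defaults) independent of the absolute stiffness scale —
   a raw force sum at these stiffnesses would freeze several pixels short
   of equilibrium.
2. *Separation pass*: pairs closer than rest are projected back toward
   rest (each endpoint moves half the overlap, averaged over that node's
   violated pairs), repeated for up to 16 sweeps. Treating repulsion as a
   positional constraint rather than a soft force is what keeps converged
   layouts within 1 px of every pairwise rest floor; a soft spring
   equilibrium leaves 10–30 px overlaps wherever a large clade presses
   against a small one, which destroys the band-equals-clade property.

The per-iteration step size (0.8) decays by 0.999 per iteration. This
cooling guarantees termination even for trees with no ideal layout, at
the cost that a pathological instance may be declared converged while
still slightly frustrated; the convergence flag and final maximum
displacement are always reported. Displacements are capped at 20 px per
iteration so a node cannot tunnel through another stack. The layout is
fully deterministic for a fixed (tree, config, seed); randomness enters
only as a seeded 0.5 px jitter when two nodes coincide exactly.
Convergence is declared when every node's per-iteration displacement is
below `conv_eps` = 0.1 px — the "100% of the nodes stop moving" rule —
with a cap of 5000 iterations (a 16-leaf tree typically needs 2000–4500
and about two seconds on one core; all-pairs interactions make the cost
O(n² ) per iteration, adequate at desk scale).

A note on the one-leaf degenerate case: the lone leaf never moves (it has
no pair), but the root still relaxes along the segment between its home
and its child before converging, so convergence takes a handful of
iterations rather than exactly one.

## Contours

The topographic band at level d is the zero isocontour of
`f(x) = min_i (|x - c_i| - r_i)` over that level's circles, traced by
marching squares (scikit-image) on a grid of `grid_px` = 2 px, with the
bounding box padded by the largest radius plus 4 px so every contour
closes. Linear interpolation makes the traced area of a lone 50 px circle
accurate to well under 1%; the acceptance band is 2%. Band-to-clade
mapping does not use the traced polygons: connected components of the
exact circle-overlap graph (edge iff center distance < sum of radii) are
computed first, and each polygon inherits the exact component of the
centers it contains, so the clade-purity metric carries no raster error.
Nesting of level-(d+1) bands inside level-d bands follows from per-stack
concentricity and radius monotonicity; tests assert it geometrically with
a 2-grid-cell buffer tolerance.

Purity at level d is the fraction of components whose leaf set equals the
descendant-leaf set of some depth-d tree node. It is 1.0 at level 1 on
converged 16-leaf trees across seeds; interior levels occasionally dip
below 1.0 when a mid-level band transiently bridges two cousined
subclades — the metric exists precisely to expose this.

## Rendering

SVG 1.1, levels painted bottom-up so higher bands are never covered. Two
modes: `polygons` (default; traced paths, pure vector, viewer
independent) and `goo-circles`, which reproduces the browser-style DOM —
per level, one `<g>` of raw circles sharing a Gaussian-blur +
contrast-matrix filter that visually fuses overlapping circles. The
filter constants (blur stdDeviation 10, alpha slope 18, intercept -7) are
this package's own defaults, chosen to fuse 15–30 px gaps cleanly. Link
lines (one per tree edge) and leaf labels are drawn on top; links are
off by default, mirroring their auto-hide once nodes stop moving. A
topographic 10-color palette (dark green low to white high) cycles when
trees run deeper.

PNG export draws the same primitives directly with Pillow: all circles of
a level in one flat color *are* the union silhouette, so the raster needs
no blur trick and scales exactly with `png_scale`. The layout JSON
(newick + per-node positions + per-leaf radii + configs + convergence
report) round-trips to a bit-identical SVG.

## Synthetic data

The generators stand in for user-supplied Newick files. `yule_tree` is a
pure-birth process (split a uniformly chosen tip until n tips) with
i.i.d. exponential branch lengths, rate 1 by default — heavy enough in
both tails to exercise both clamp branches; it emulates the topology and
length heterogeneity of moderate real phylogenies but not rate
autocorrelation, extinction, or calibrated time scales, so passing tests
demonstrate geometric and convergence behaviour, not biological realism.
`caterpillar_tree` (maximally unbalanced) and `balanced_tree` (complete
binary) bracket the depth-distribution extremes. The standard test
fixture is a 16-leaf Yule tree, seed 42.

## Known limitations

- All-pairs forces are O(n²) per iteration; hundreds of OTUs are fine,
  thousands are slow (the parser and serializer themselves are iterative
  and handle 3740-tip trees without recursion limits).
- Cooling can freeze an over-constrained layout slightly short of its
  rest geometry; the convergence report makes this visible but does not
  repair it.
- Marching-squares bands may bridge two blobs whose true boundaries come
  within one grid cell; purity is immune (exact graph) but the drawn band
  is merged.
- Internal node labels that are numeric are read as bootstrap supports,
  the dominant Newick dialect; quote a label to force it to be a name.
- Supports are carried through parse/serialize but do not influence the
  layout.
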
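# Methods

## Model

A molecule is a rigid set of balls: each atom a sphere at its deposited
coordinates with an element-dependent van der Waals radius. The Bondi set
is used (C 1.70, N 1.55, O 1.52, S 1.80, P 1.80, H 1.20 Å; default 1.70 Å
for anything else, with a logged warning) and is fully overridable via
`RadiiTable`. Waters are always excluded; hydrogens and in-chain HETATM
ligands are kept by default (most X-ray entries deposit no hydrogens, and
ligands move with the rigid body); alternate locations collapse to the
first occurrence. A "molecule" is whatever chain selection the user names,
so multi-chain binding partners are supported.

## Binding direction

The separating direction of B w.r.t. A is a translation direction along
which B moves a distance δ away from A without sphere collisions; the
binding direction is its negation. Atoms farther than δ from the partner
cannot collide within a δ-bounded move and are dropped first (KD-tree
prefilter, equal by construction to the all-pairs definition).

For a pair (a, b) with centre offset v = a.c − b.c the blocked directions
of b form the infinite cone {u : ∠(u, v) ≤ arcsin((a.r + b.r)/‖v‖)}; once
the spheres touch or interpenetrate the half-angle is π/2 (a half-space —
such pairs, e.g. covalent contacts, can still separate within the open
opposite half-space). Two deliberate conservatisms, kept because they make
"free" claims safe: cones are infinite (no range cut at δ beyond the pair
prefilter), and a direction exactly on a cone boundary counts as blocked.
Coincident centres across molecules (degenerate input) block the whole
sphere for that pair, with a warning.

Directions are sampled as the vertices of a subdivided icosahedron
(10·4^level + 2 points; default level 4 = 2562 points, ≈ 4° resolution).
An icosphere was chosen over a Fibonacci lattice because its mesh edges
give the neighbour relation the grouping step needs. Per point the number
of containing cones is counted; points with count < `count_threshold`
(default 1) are free and are partitioned into connected patches by an
iterative flood fill (explicit stack — recursion would overflow on fine
samplings). The returned direction is the normalized mean of the largest
patch; ties go to the patch best aligned with the centroid offset of B
from A. If nothing is free the threshold is relaxed to (min count + 1) and
the result is flagged `relaxed` — reported, never silent.

δ defaults to 5 Å after the five-five interaction criterion (five residue
pairs within 5 Å).

## Distance map and sectional area

Both molecules are rotated by the minimal-angle rotation taking the
separating direction onto −z (180° about x in the antiparallel corner
case), leaving A on the +z side. Depth buffers are computed by analytic
software rasterization: per pixel centre, each covering sphere contributes
z = c_z ∓ √(r² − ρ²), and the partner-facing extreme is kept (min for A
seen from −∞, max for B seen from +∞). Working directly in world-z
collapses the normalized-[0, 1] depth convention of a graphics z-buffer,
its 1−depth flip for the opposing view, and the final rescale by the view
volume's z extent into one subtraction: gap = z_A − z_B in Å, undefined
(NaN) where either projection is missing, negative where the surfaces
interpenetrate along z. Negative gaps are retained and count toward any
positive cutoff.

Resolution is set by the physical pixel edge (default 0.2 Å, padding 2 Å
around the joint bounding box), so one pixel represents exactly
pixel_size² of area; the sectional contact area at cutoff t is the count
of defined pixels with gap ≤ t times that unit area. Pixel sample points
are pixel centres. Cumulative areas over ascending cutoffs (default
1/3/5 Å) are differenced into per-band partial areas; percentages are
relative to the largest cumulative area and sum to 100 by construction.
The ruggedness ratio divides an externally supplied buried 3-D area
(PISA or equivalent — computing solvent-accessible areas is out of scope)
by the 5 Å sectional area.

Rounding to one decimal happens only at report serialization; all internal
values are full precision, and the whole pipeline is deterministic —
identical input and options give byte-identical JSON.

## Synthetic fixtures and what they do (not) show

The generator builds complexes stacked along z with analytic ground truth:

- `two_atom` — one sphere per side; closed-form gap profile
  g(ρ) = D − √(r_A²−ρ²) − √(r_B²−ρ²) makes the sectional area at any
  cutoff an exact disk area.
- `slab_pair` — n×n sphere grids. At the default tangent pitch (2r) the
  projected footprint is exactly n²πr² (tangent disks; the inter-disk
  cusps project to no sphere and stay undefined). At covering pitches
  (pitch·√2/2 ≤ r) the footprint is the rounded square L² + 4Lr + πr²,
  and the facing-surface area factor is integrated numerically from the
  sphere envelope (≈ 1.02 at pitch 0.5, r = 1 — a genuinely flat contact).
- `cap_and_bowl` — a large sphere of radius R seated in a complementary
  shell of small spheres at constant clearance: buried cap area
  2πR²(1−cos α) over flattened disk π(R sin α)², ratio 2 for a
  hemisphere. Calibrates the ruggedness reading of the ratio.
- `jittered_interface` — the slab with uniform per-atom displacement up to
  0.3 Å, seeded and reproducible; small enough that the ground-truth axis
  stays valid.

Two independent oracles back the tests: a swept-sphere collision check
(closed-form segment-to-point distance over all pairs) and the two-sphere
gap-area inversion above. Passing on these fixtures shows the geometry,
rasterization and bookkeeping are right; it does not exercise the
irregular packing, mixed radii and partial occupancies of real structures.
A bundled benchmark table for 32 deposited complexes (binding directions,
sectional areas at 1/3/5 Å, PISA buried areas, and the published derived
columns) lets the decomposition and ratio arithmetic be checked offline;
reproducing its sectional areas end-to-end additionally needs the PDB
entries themselves (fetched at test time from RCSB or a local cache —
coordinates are not redistributed here). That published table's partial
areas were evidently differenced before rounding, so exact arithmetic on
its printed cumulative areas can disagree by one unit in the last decimal;
tests and documentation account for that explicitly.

## Numerical choices and problem sizes

- Cone membership uses dot(p, axis) ≥ cos(half-angle); counts are chunked
  matrix products, invariant under cone order.
- Flood fill is iterative; group representatives with vanishing mean
  (perfectly symmetric patches) fall back to a member point.
- The sagitta error of pixel sampling bounds the gap-map error by
  Σ (1 − √(1 − ρ²/r²))·r with ρ ≤ pixel/√2; tests use this exact bound.
- Area convergence on the two-unit-sphere fixture: −6.9% at 0.2 Å pixels,
  −0.3% at 0.05 Å against the closed form.
- Test and acceptance runs use desk-scale sizes chosen as the smallest
  that exercise every code path with clear margins: slabs of 25–81 spheres
  per side set, a bowl of ~1600 spheres, 2×10⁴ random pair/direction
  instances for the cone-vs-sweep agreement check, sampling level 4.

## Known limitations

- Infinite-cone semantics over-block: a direction free for a δ-bounded
  move can be classified blocked. This is one-sided (never the reverse)
  and matches the algorithm as specified.
- The sectional area is resolution-limited; boundary pixels are counted by
  centre membership with no sub-pixel coverage.
- Perfectly symmetric free regions have a direction only by tie-break.
- Buried 3-D areas are inputs, not computed; mmCIF input and assembly
  expansion are not supported.
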
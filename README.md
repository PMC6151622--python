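# ppisect

Binding direction and two-dimensional **sectional contact area** of
protein–protein interfaces.

The buried surface area of a complex (e.g. from PISA) measures how much
3-D surface the two partners hide from solvent, but says nothing about the
*shape* of the contact — a flat patch and a deep ball-and-socket joint can
bury the same area. `ppisect` flattens the interface instead: it first
finds the **binding direction** of the complex, then projects the contact
region onto the plane perpendicular to it, like reading an island's size
off a map regardless of its mountains. Comparing the 3-D buried area with
this 2-D sectional area quantifies the ruggedness of the interface.

It is aimed at structural bioinformaticians analysing deposited complexes
(PDB files), and is usable both as a Python library and as the `ppisect`
command-line tool.

## Method

Each molecule is a set of van der Waals balls (Bondi radii by default).
For partners M_A, M_B:

1. **Binding direction.** The *separating direction* **d** is a unit vector
   along which M_B can translate a distance δ (default 5 Å, after the
   five-five interaction rule) away from M_A without sphere collisions.
   For every interface atom pair (Aᵢ, Bⱼ) with surface distance ≤ δ, the
   translation directions of B blocked by A form an infinite cone with axis
   v = Aᵢ.c − Bⱼ.c and half-angle θ = arcsin((Aᵢ.r + Bⱼ.r)/‖v‖) — a
   half-space (θ = π/2) if the spheres already touch. Cone membership is
   accumulated on an icosphere sampling of the unit sphere; sample points
   inside fewer than `count_threshold` cones are *free*, flood-filled into
   connected patches along mesh edges, and **d** is the normalized mean of
   the largest patch. The binding direction is **−d**.
2. **Distance map.** Both molecules are rigidly rotated so **d** → −z, and
   each is rendered into an orthographic depth buffer by analytic sphere
   rasterization (pixel edge 0.2 Å by default). Subtracting B's upper
   surface from A's lower surface gives the inter-surface gap in Å per
   pixel wherever both project.
3. **Sectional areas.** The sectional contact area at cutoff t is
   (pixels with gap ≤ t) × pixel area. Computing it for cutoffs 1/3/5 Å
   and differencing splits the contact into gap bands (tight contact
   < 1 Å, water-mediated spacing above), and the ratio
   (PISA buried area)/(5 Å sectional area) reads as ruggedness: ≈ 1 flat,
   ~2 hemispherical, up to ~4 sphere-like.

## Worked example

```python
from ppisect import (FixtureSpec, make_fixture, binding_direction,
                     align_to_binding_axis, distance_map, area_series)

mol_a, mol_b, truth = make_fixture(FixtureSpec("slab_pair", n=5, gap=3.0))
res = binding_direction(mol_a, mol_b, delta=5.0, level=4)
print(res.binding_direction)        # [-0. -0.  1.] — the slabs stack along z
print(round(res.free_fraction, 3))  # 0.767 — fraction of unblocked directions
```

Running `python examples/sectional_area.py` (two unit spheres 2.5 Å apart):

```
closed-form area at 1 Å cutoff: 1.3744 Å²
pixel 0.20 Å -> area 1.2800 Å² (-6.87%)
pixel 0.10 Å -> area 1.4000 Å² (+1.86%)
pixel 0.05 Å -> area 1.3700 Å² (-0.32%)
```

i.e. the pixel-counted sectional area converges to the analytic disk area
π·0.4375 as the raster is refined. `python examples/ruggedness.py` prints
the flatness calibration (dense slab ratio 1.02, hemispherical cap-in-bowl
ratio 2.00) and the bundled 32-complex benchmark summary (mean 5 Å
sectional area 490.1 Å², surface/sectional ratio 1.9–4.3, mean 2.8).

The same pipeline runs from the shell:

```sh
ppisect fixture --kind slab_pair --n 5 --gap 3 --radius 1.7 --out slab.pdb
ppisect direction slab.pdb -a A -b B
ppisect area slab.pdb -a A -b B --cutoffs 1,3,5 --surface-area 200
ppisect render slab.pdb -a A -b B --quantize 5 --out-prefix slab
```

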
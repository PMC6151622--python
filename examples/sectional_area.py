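"""Sectional contact area of two unit spheres vs the closed form.

Two unit spheres 2.5 Å apart along z have a z-gap profile
g(ρ) = 2.5 − 2√(1−ρ²), so at cutoff t = 1 Å the contact region is the disk
ρ² ≤ 0.4375 with area π·0.4375 ≈ 1.374 Å².  The pixel-counted area from the
depth-map pipeline converges to that value as the pixel size shrinks.
"""

from ppisect import (
    FixtureSpec, area_series, contact_area, distance_map, make_fixture,
    oracle_two_sphere_gap_area,
)

mol_a, mol_b, truth = make_fixture(FixtureSpec("two_atom", gap=0.5, radius=1.0))

closed = oracle_two_sphere_gap_area(1.0, 1.0, truth["center_distance"], 1.0)
print(f"closed-form area at 1 Å cutoff: {closed:.4f} Å²")
for pixel_size in (0.2, 0.1, 0.05):
    dmap = distance_map(mol_a, mol_b, pixel_size=pixel_size)
    area = contact_area(dmap, 1.0)
    print(f"pixel {pixel_size:4.2f} Å -> area {area:.4f} Å² "
          f"({100 * (area - closed) / closed:+.2f}%)")

# cutoff series: cumulative areas, per-band partial areas, band shares
dmap = distance_map(mol_a, mol_b, pixel_size=0.05)
series = area_series(dmap, (0.6, 0.8, 1.0))
print("cutoffs:    ", series.cutoffs)
print("cumulative: ", [round(a, 3) for a in series.cumulative_area])
print("partial:    ", [round(a, 3) for a in series.partial_area])
print("percentage: ", [round(p, 1) for p in series.percentage])
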
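"""Synthetic sphere-set complexes with known geometry, plus test oracles.

Every fixture is a pair of molecules stacked along z — molecule A on the +z
side, molecule B on the −z side — so the ground-truth separating direction
of B is (0, 0, −1) and the binding direction (0, 0, +1).  Ground truths are
closed-form where possible (disk unions, spherical caps) and brute-force
numeric where not (envelope surface area of an overlapping sphere slab).

The oracles are deliberately independent of the cone/depth-map code paths:
swept-sphere collision uses the closed-form segment-to-point distance, and
the two-sphere gap area inverts the analytic z-gap profile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import brentq

from .structures import Molecule, SphereAtom

__all__ = [
    "FixtureSpec",
    "make_fixture",
    "oracle_swept_collision",
    "oracle_two_sphere_gap_area",
]

FixtureKind = Literal["two_atom", "slab_pair", "cap_and_bowl", "jittered_interface"]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic complex.

    gap is the minimum surface-to-surface distance between the two
    molecules (Å); radius the sphere radius (Å).  ``spacing`` is the grid
    pitch of slab fixtures (default 2·radius: tangent spheres); ``n`` the
    grid side.  ``cap_radius``/``cap_angle`` shape the cap-and-bowl fixture
    (big-sphere radius and polar half-opening of the bowl).  ``seed`` makes
    the jittered fixture reproducible.
    """

    kind: FixtureKind
    gap: float = 1.0
    radius: float = 1.0
    n: int = 7
    spacing: float | None = None
    cap_radius: float = 6.0
    cap_angle: float = math.pi / 2
    jitter: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gap <= 0 or self.radius <= 0:
            raise ValueError("gap and radius must be positive")
        if self.kind in ("slab_pair", "jittered_interface") and self.n < 1:
            raise ValueError("slab grid extent n must be ≥ 1")
        if self.spacing is not None and self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if not (0 < self.cap_angle <= math.pi / 2):
            raise ValueError("cap_angle must be in (0, π/2]")


def _atoms(points: np.ndarray, radius: float, chain: str) -> list[SphereAtom]:
    return [
        SphereAtom(tuple(p), radius, element="C", chain_id=chain,
                   residue_seq=i + 1, atom_name="C", residue_name="UNK")
        for i, p in enumerate(np.atleast_2d(points))
    ]


def _slab_points(n: int, spacing: float, z: float) -> np.ndarray:
    offs = (np.arange(n) - (n - 1) / 2) * spacing
    xx, yy = np.meshgrid(offs, offs)
    pts = np.column_stack([xx.ravel(), yy.ravel(), np.full(n * n, z)])
    return pts


def _disk_union_area(n: int, spacing: float, r: float) -> float:
    """Exact area of the union of n×n grid disks (pitch ``spacing``, radius r).

    Tangent or separated disks (spacing ≥ 2r) are disjoint: n²πr².  When the
    disks cover the grid square (spacing·√2/2 ≤ r) the union is the
    Minkowski sum of the (n−1)·spacing square with a radius-r disk:
    L² + 4Lr + πr².  Intermediate pitches have no simple closed form and are
    rejected.
    """
    L = (n - 1) * spacing
    if spacing >= 2 * r:
        return n * n * math.pi * r * r
    if spacing * math.sqrt(2) / 2 <= r + 1e-12:
        return L * L + 4 * L * r + math.pi * r * r
    raise ValueError(
        f"no closed-form footprint for pitch {spacing} with radius {r}")


def _envelope_area_factor(spacing: float, r: float, samples: int = 400) -> float:
    """3D-surface / flat-area factor of a covering sphere grid, numerically.

    Integrates sqrt(1 + |∇z|²) of the upper envelope z(x, y) = max over the
    3×3 sphere neighbourhood of c_z + sqrt(r² − ρ²) over one interior grid
    cell.  Valid when the spheres cover the cell (pitch·√2/2 ≤ r).
    """
    if spacing * math.sqrt(2) / 2 > r:
        raise ValueError("envelope factor requires a covering grid")
    ax = np.linspace(-spacing / 2, spacing / 2, samples)
    xx, yy = np.meshgrid(ax, ax)
    z = np.full_like(xx, -np.inf)
    for cx in (-spacing, 0.0, spacing):
        for cy in (-spacing, 0.0, spacing):
            rho2 = (xx - cx) ** 2 + (yy - cy) ** 2
            with np.errstate(invalid="ignore"):
                cand = np.sqrt(np.clip(r * r - rho2, 0.0, None))
            cand[rho2 > r * r] = -np.inf
            z = np.maximum(z, cand)
    dzy, dzx = np.gradient(z, ax, ax)
    return float(np.mean(np.sqrt(1.0 + dzx ** 2 + dzy ** 2)))


def _fibonacci_cap(n_points: int, polar_min: float) -> np.ndarray:
    """Roughly uniform unit directions with polar angle in [polar_min, π]."""
    k = np.arange(n_points)
    cos_lo, cos_hi = -1.0, math.cos(polar_min)
    cosines = cos_lo + (k + 0.5) / n_points * (cos_hi - cos_lo)
    sines = np.sqrt(1.0 - cosines ** 2)
    golden = math.pi * (3.0 - math.sqrt(5.0))
    phi = k * golden
    return np.column_stack([sines * np.cos(phi), sines * np.sin(phi), cosines])


def make_fixture(spec: FixtureSpec) -> tuple[Molecule, Molecule, dict]:
    """Build molecules A (+z side) and B (−z side) plus analytic ground truth.

    The returned dict always holds ``separating_direction``,
    ``binding_direction`` and ``min_gap``; fixture kinds add their analytic
    flattened area (``flat_area``), partner-facing 3-D surface area
    (``surface_area_3d``) and their ratio (``ratio_3d_2d``) where defined.
    """
    gt: dict = {
        "separating_direction": np.array([0.0, 0.0, -1.0]),
        "binding_direction": np.array([0.0, 0.0, 1.0]),
        "min_gap": spec.gap,
    }
    r = spec.radius
    if spec.kind == "two_atom":
        zc = r + spec.gap / 2
        mol_a = Molecule("A", _atoms(np.array([[0.0, 0.0, zc]]), r, "A"))
        mol_b = Molecule("B", _atoms(np.array([[0.0, 0.0, -zc]]), r, "B"))
        gt["center_distance"] = 2 * zc
        gt["flat_area"] = math.pi * r * r
        return mol_a, mol_b, gt

    if spec.kind in ("slab_pair", "jittered_interface"):
        spacing = spec.spacing if spec.spacing is not None else 2 * r
        zc = r + spec.gap / 2
        pa = _slab_points(spec.n, spacing, zc)
        pb = _slab_points(spec.n, spacing, -zc)
        if spec.kind == "jittered_interface":
            rng = np.random.default_rng(spec.seed)
            pa = pa + rng.uniform(-spec.jitter, spec.jitter, pa.shape)
            pb = pb + rng.uniform(-spec.jitter, spec.jitter, pb.shape)
            gt["jitter"] = spec.jitter
        else:
            flat = _disk_union_area(spec.n, spacing, r)
            gt["flat_area"] = flat
            gt["rect_area"] = ((spec.n - 1) * spacing + 2 * r) ** 2
            if spacing >= 2 * r:
                # disjoint spheres: the partner-facing surface over each
                # projected disk is a full hemisphere, 2πr² over πr²
                gt["ratio_3d_2d"] = 2.0
            else:
                gt["ratio_3d_2d"] = _envelope_area_factor(spacing, r)
            gt["surface_area_3d"] = gt["ratio_3d_2d"] * flat
        mol_a = Molecule("A", _atoms(pa, r, "A"))
        mol_b = Molecule("B", _atoms(pb, r, "B"))
        return mol_a, mol_b, gt

    if spec.kind == "cap_and_bowl":
        R = spec.cap_radius
        if R <= 0:
            raise ValueError("cap_radius must be positive")
        shell = R + spec.gap + r
        # bowl: small spheres on the lower cap of the shell around A's centre
        n_pts = max(16, math.ceil(
            4.0 * 2 * math.pi * shell ** 2 * (1 - math.cos(spec.cap_angle)) / (r * r)))
        dirs = _fibonacci_cap(n_pts, math.pi - spec.cap_angle)
        center_a = np.array([0.0, 0.0, 0.0])
        mol_a = Molecule("A", [SphereAtom(tuple(center_a), R, element="C",
                                          chain_id="A", residue_seq=1,
                                          atom_name="C", residue_name="UNK")])
        mol_b = Molecule("B", _atoms(shell * dirs, r, "B"))
        cap_area_3d = 2 * math.pi * R * R * (1 - math.cos(spec.cap_angle))
        flat = math.pi * (R * math.sin(spec.cap_angle)) ** 2
        gt["flat_area"] = flat
        gt["surface_area_3d"] = cap_area_3d
        gt["ratio_3d_2d"] = cap_area_3d / flat  # = 2/(1+cos α)
        return mol_a, mol_b, gt

    raise ValueError(f"unknown fixture kind {spec.kind!r}")


def oracle_swept_collision(mol_b: Molecule, mol_a: Molecule,
                           direction: np.ndarray, distance: float) -> bool:
    """True iff translating B along ``direction`` by up to ``distance`` collides.

    Brute force over all atom pairs with the closed-form point-to-segment
    distance: B's atom sweeps the segment [c_b, c_b + distance·u]; collision
    when it passes strictly within r_a + r_b of A's atom centre.
    """
    u = np.asarray(direction, dtype=float)
    n = np.linalg.norm(u)
    if abs(n - 1.0) > 1e-9:
        raise ValueError("direction must be a unit vector")
    ca, ra = mol_a.centers, mol_a.radii
    cb, rb = mol_b.centers, mol_b.radii
    # w[j, i] = vector from B_j to A_i
    w = ca[None, :, :] - cb[:, None, :]
    s = np.clip(w @ u, 0.0, distance)              # closest sweep parameter
    closest = w - s[:, :, None] * u[None, None, :]
    d2 = np.einsum("jik,jik->ji", closest, closest)
    rsum = rb[:, None] + ra[None, :]
    return bool(np.any(d2 < rsum ** 2 - 1e-12))


def oracle_two_sphere_gap_area(r_a: float, r_b: float,
                               center_distance: float, t: float) -> float:
    """Closed-form sectional contact area of two coaxial spheres at cutoff t.

    The z-gap at in-plane radius ρ is g(ρ) = D − √(r_a²−ρ²) − √(r_b²−ρ²)
    (D the centre distance), increasing in ρ; the contact region is the disk
    ρ ≤ ρ* with g(ρ*) = t, so the area is π·ρ*².  If t exceeds the gap at
    the edge of the common projection the full disk π·min(r_a, r_b)² is
    returned; if t is below the minimum gap the area is 0.
    """
    if center_distance <= 0 or t <= 0:
        raise ValueError("center_distance and t must be positive")
    rmin = min(r_a, r_b)

    def g(rho: float) -> float:
        return (center_distance
                - math.sqrt(max(r_a ** 2 - rho ** 2, 0.0))
                - math.sqrt(max(r_b ** 2 - rho ** 2, 0.0)))

    if t <= g(0.0):
        return 0.0
    if t >= g(rmin):
        return math.pi * rmin ** 2
    rho_star = brentq(lambda rho: g(rho) - t, 0.0, rmin, xtol=1e-12)
    return math.pi * rho_star ** 2
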
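"""Binding direction of a two-molecule complex from blocked-direction cones.

The separating direction of molecule B with respect to molecule A is a unit
vector along which B can translate a distance δ away from A without any
sphere-sphere collision.  For every interface atom pair (a ∈ A, b ∈ B) the
set of translation directions of B that lead toward a collision with a is an
infinite cone with apex at the origin, axis pointing from b toward a, and
half-angle arcsin((r_a + r_b)/‖a−b‖) — or a half-space (half-angle π/2) when
the spheres already interpenetrate.  Accumulating these cones on a sampled
unit sphere and flood-filling the unblocked sample points yields the free
directions; the separating direction is the average of the largest free
patch, and the binding direction is its negation.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .structures import Molecule, SphereAtom

logger = logging.getLogger(__name__)

__all__ = [
    "BlockedCone",
    "DirectionSampling",
    "BindingResult",
    "FullyBlockedError",
    "surface_distance",
    "interface_atoms",
    "blocked_cone",
    "sample_unit_sphere",
    "accumulate_counts",
    "group_free_points",
    "binding_direction",
]

UNGROUPED = -1


class FullyBlockedError(RuntimeError):
    """No sample direction has a blocked-cone count below the threshold."""


@dataclass(frozen=True)
class BlockedCone:
    """Infinite cone of blocked translation directions for one atom pair.

    ``axis`` points from the moving atom (in B) toward the blocking atom
    (in A); ``half_angle`` is in radians, in (0, π/2].
    """

    axis: tuple[float, float, float]
    half_angle: float

    def __post_init__(self) -> None:
        n = float(np.linalg.norm(self.axis))
        if abs(n - 1.0) > 1e-9:
            raise ValueError(f"cone axis must be unit length, |axis| = {n}")
        if not (0.0 < self.half_angle <= np.pi / 2 + 1e-12):
            raise ValueError(f"half_angle {self.half_angle} outside (0, π/2]")

    def contains(self, direction: np.ndarray) -> np.ndarray:
        """Membership test; the cone boundary counts as inside."""
        d = np.atleast_2d(np.asarray(direction, dtype=float))
        dots = d @ np.asarray(self.axis)
        return np.squeeze(dots >= np.cos(self.half_angle))


@dataclass
class DirectionSampling:
    """Unit-sphere sample points with mesh adjacency, counts and groups."""

    points: np.ndarray                      # (n, 3) unit vectors
    neighbors: list[np.ndarray]             # adjacency lists (mesh edges)
    counts: np.ndarray = field(default=None)  # blocked-cone count per point
    group: np.ndarray = field(default=None)   # group id per point, -1 = none

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        norms = np.linalg.norm(self.points, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("sample points must lie on the unit sphere")
        if self.counts is None:
            self.counts = np.zeros(len(self.points), dtype=np.int64)
        if self.group is None:
            self.group = np.full(len(self.points), UNGROUPED, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class BindingResult:
    """Outcome of the binding-direction computation.

    ``groups`` holds (size, representative unit vector) per free patch,
    sorted by size descending; ``free_fraction`` is the fraction of sample
    directions whose blocked count fell below the threshold actually used.
    """

    separating_direction: np.ndarray
    binding_direction: np.ndarray
    groups: list[tuple[int, np.ndarray]]
    free_fraction: float
    delta: float
    count_threshold: int
    relaxed: bool = False

    def to_dict(self) -> dict:
        return {
            "separating_direction": [round(float(v), 6) for v in self.separating_direction],
            "binding_direction": [round(float(v), 6) for v in self.binding_direction],
            "groups": [
                {"size": int(s), "representative": [round(float(v), 6) for v in rep]}
                for s, rep in self.groups
            ],
            "free_fraction": round(float(self.free_fraction), 6),
            "delta": float(self.delta),
            "count_threshold": int(self.count_threshold),
            "relaxed": bool(self.relaxed),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def surface_distance(a: SphereAtom, b: SphereAtom) -> float:
    """Gap between two sphere surfaces in Å (negative if interpenetrating)."""
    d = np.linalg.norm(np.asarray(a.center) - np.asarray(b.center))
    return float(d - a.radius - b.radius)


def _interface_indices(mol_a: Molecule, mol_b: Molecule,
                       delta: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Index pairs (i, j) with surface distance ≤ delta, plus per-side index sets.

    Uses a KD-tree prefilter; the result equals the all-pairs definition
    because the query radius covers the largest possible radius sum.
    """
    ca, cb = mol_a.centers, mol_b.centers
    ra, rb = mol_a.radii, mol_b.radii
    rmax = float(ra.max() + rb.max())
    tree_a = cKDTree(ca)
    tree_b = cKDTree(cb)
    candidates = tree_a.query_ball_tree(tree_b, r=delta + rmax)
    pairs_i: list[int] = []
    pairs_j: list[int] = []
    for i, js in enumerate(candidates):
        if not js:
            continue
        js = np.asarray(js)
        gaps = np.linalg.norm(cb[js] - ca[i], axis=1) - ra[i] - rb[js]
        keep = js[gaps <= delta]
        pairs_i.extend([i] * len(keep))
        pairs_j.extend(keep.tolist())
    pi = np.asarray(pairs_i, dtype=np.int64)
    pj = np.asarray(pairs_j, dtype=np.int64)
    return pi, pj, np.column_stack([pi, pj]) if len(pi) else np.empty((0, 2), np.int64)


def interface_atoms(mol_a: Molecule, mol_b: Molecule,
                    delta: float = 5.0) -> tuple[list[SphereAtom], list[SphereAtom]]:
    """Atoms of each molecule within surface distance δ of the partner.

    Raises ``ValueError`` when either side is empty (no interface within δ).
    """
    if not delta > 0:
        raise ValueError("delta must be positive")
    pi, pj, _ = _interface_indices(mol_a, mol_b, delta)
    if len(pi) == 0:
        raise ValueError(
            f"no interface within δ = {delta} Å between "
            f"{mol_a.label!r} and {mol_b.label!r}")
    ia = np.unique(pi)
    ib = np.unique(pj)
    return [mol_a.atoms[i] for i in ia], [mol_b.atoms[j] for j in ib]


def blocked_cone(a: SphereAtom, b: SphereAtom) -> BlockedCone:
    """Cone of translation directions of ``b`` blocked by ``a``.

    Axis points from b toward a.  Half-angle is arcsin((r_a+r_b)/‖v‖) for
    separated spheres and π/2 once they touch or interpenetrate.  Coincident
    centres leave the axis undefined and raise ``ValueError`` (callers treat
    that degenerate pair as blocking every direction).
    """
    v = np.asarray(a.center, dtype=float) - np.asarray(b.center, dtype=float)
    dist = float(np.linalg.norm(v))
    if dist < 1e-12:
        raise ValueError("coincident atom centers: blocked cone axis undefined")
    axis = tuple(v / dist)
    rsum = a.radius + b.radius
    if dist <= rsum:  # touching or interpenetrating: half-space block
        return BlockedCone(axis, np.pi / 2)
    return BlockedCone(axis, float(np.arcsin(rsum / dist)))


def sample_unit_sphere(level: int = 4) -> DirectionSampling:
    """Icosphere direction sampling: 10·4^level + 2 unit vectors.

    The mesh edges of the subdivided icosahedron provide the neighbor
    relation needed by the flood-fill grouping.
    """
    if level < 0:
        raise ValueError("subdivision level must be ≥ 0")
    mesh = trimesh.creation.icosphere(subdivisions=level, radius=1.0)
    points = np.asarray(mesh.vertices, dtype=float)
    points /= np.linalg.norm(points, axis=1, keepdims=True)
    n = len(points)
    adj: list[set[int]] = [set() for _ in range(n)]
    for u, v in mesh.edges_unique:
        adj[u].add(int(v))
        adj[v].add(int(u))
    neighbors = [np.array(sorted(s), dtype=np.int64) for s in adj]
    return DirectionSampling(points=points, neighbors=neighbors)


def accumulate_counts(sampling: DirectionSampling,
                      cones,
                      chunk: int = 4096) -> DirectionSampling:
    """Count, per sample direction, how many blocked cones contain it.

    A direction exactly on a cone boundary counts as blocked, so the free
    set is open.  Counts add to any counts already present being reset first.
    """
    cones = list(cones)
    sampling.counts = np.zeros(len(sampling), dtype=np.int64)
    if not cones:
        return sampling
    axes = np.array([c.axis for c in cones], dtype=float)
    cos_half = np.cos(np.array([c.half_angle for c in cones], dtype=float))
    pts = sampling.points
    for start in range(0, len(cones), chunk):
        sl = slice(start, start + chunk)
        inside = pts @ axes[sl].T >= cos_half[sl][None, :]
        sampling.counts += inside.sum(axis=1)
    return sampling


def group_free_points(sampling: DirectionSampling,
                      count_threshold: int = 1) -> DirectionSampling:
    """Partition free sample points (count < threshold) into connected patches.

    Two free points share a group exactly when they are connected through
    free points along mesh edges.  The flood fill is iterative (explicit
    stack) so fine samplings cannot overflow the call stack.  Raises
    :class:`FullyBlockedError` when no point is free.
    """
    free = sampling.counts < count_threshold
    sampling.group = np.full(len(sampling), UNGROUPED, dtype=np.int64)
    if not free.any():
        raise FullyBlockedError(
            f"every sampled direction has count ≥ {count_threshold}")
    gid = 0
    group = sampling.group
    for seed in np.flatnonzero(free):
        if group[seed] != UNGROUPED:
            continue
        stack = [int(seed)]
        group[seed] = gid
        while stack:
            p = stack.pop()
            for q in sampling.neighbors[p]:
                if free[q] and group[q] == UNGROUPED:
                    group[q] = gid
                    stack.append(int(q))
        gid += 1
    return sampling


def _group_representatives(sampling: DirectionSampling) -> list[tuple[int, np.ndarray]]:
    reps: list[tuple[int, np.ndarray]] = []
    ngroups = int(sampling.group.max()) + 1
    for g in range(ngroups):
        members = sampling.points[sampling.group == g]
        mean = members.mean(axis=0)
        n = np.linalg.norm(mean)
        # a perfectly symmetric patch (e.g. the whole sphere) has no direction
        rep = members[0] if n < 1e-12 else mean / n
        reps.append((len(members), rep))
    return reps


def binding_direction(mol_a: Molecule, mol_b: Molecule,
                      delta: float = 5.0,
                      level: int = 4,
                      count_threshold: int = 1,
                      sampling: DirectionSampling | None = None) -> BindingResult:
    """Binding direction of ``mol_b`` with respect to ``mol_a``.

    Pipeline: select interface atoms within δ, build one blocked cone per
    pair, accumulate cone membership counts over an icosphere sampling,
    flood-fill the free points into patches, and return the negated
    representative of the largest patch.

    When no direction is free at the requested threshold, the threshold is
    relaxed to (min count + 1) and the result is flagged ``relaxed=True``
    with a warning — the molecules are fully blocked under infinite-cone
    semantics.

    Ties between equally large free patches go to the patch whose
    representative best aligns with the centroid offset (B toward away
    from A).
    """
    if sampling is None:
        sampling = sample_unit_sphere(level)
    pi, pj, _ = _interface_indices(mol_a, mol_b, delta)
    if len(pi) == 0:
        raise ValueError(f"no interface within δ = {delta} Å")

    ca, cb = mol_a.centers, mol_b.centers
    ra, rb = mol_a.radii, mol_b.radii
    v = ca[pi] - cb[pj]                      # from moving atom b toward blocker a
    dist = np.linalg.norm(v, axis=1)
    rsum = ra[pi] + rb[pj]

    degenerate = dist < 1e-12
    n_degen = int(degenerate.sum())
    if n_degen:
        warnings.warn(
            f"{n_degen} atom pair(s) with coincident centers: "
            "treated as blocking all directions", RuntimeWarning)
    ok = ~degenerate
    axes = v[ok] / dist[ok][:, None]
    half = np.where(dist[ok] <= rsum[ok], np.pi / 2,
                    np.arcsin(np.clip(rsum[ok] / dist[ok], 0.0, 1.0)))

    sampling.counts = np.zeros(len(sampling), dtype=np.int64)
    cos_half = np.cos(half)
    pts = sampling.points
    chunk = 4096
    for start in range(0, len(axes), chunk):
        sl = slice(start, start + chunk)
        inside = pts @ axes[sl].T >= cos_half[sl][None, :]
        sampling.counts += inside.sum(axis=1)
    sampling.counts += n_degen                # full-sphere blocks

    threshold = count_threshold
    relaxed = False
    try:
        group_free_points(sampling, threshold)
    except FullyBlockedError:
        threshold = int(sampling.counts.min()) + 1
        relaxed = True
        warnings.warn(
            f"fully blocked at threshold {count_threshold}; "
            f"relaxed to {threshold}", RuntimeWarning)
        group_free_points(sampling, threshold)

    reps = _group_representatives(sampling)
    away = mol_b.centroid() - mol_a.centroid()
    away_norm = np.linalg.norm(away)
    away = away / away_norm if away_norm > 0 else np.array([0.0, 0.0, 1.0])

    def sort_key(item):
        size, rep = item
        return (-size, -float(rep @ away))

    reps.sort(key=sort_key)
    d = reps[0][1]
    free_fraction = float((sampling.counts < threshold).mean())
    return BindingResult(
        separating_direction=d,
        binding_direction=-d,
        groups=reps,
        free_fraction=free_fraction,
        delta=float(delta),
        count_threshold=threshold,
        relaxed=relaxed,
    )
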
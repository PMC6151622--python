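"""Per-pixel inter-surface gap between two aligned molecules.

After the binding axis is rotated onto z, each molecule is rendered into an
orthographic depth buffer by analytic sphere rasterization: for every pixel
centre the exact z of the sphere surface is computed, keeping the extreme
value over the molecule's spheres (the surface facing the partner).
Subtracting the two buffers gives a distance map: the gap in Å along the
binding axis wherever both molecules project, NaN (undefined) elsewhere.
The physical pixel edge length is chosen directly, so the area represented
by one pixel is pixel_size² exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from PIL import Image
from scipy.spatial.transform import Rotation

from .structures import Molecule

__all__ = [
    "ViewVolume",
    "DepthGrid",
    "DistanceMap",
    "align_to_binding_axis",
    "view_volume",
    "rasterize_depth",
    "distance_map",
    "quantized_difference_image",
    "depth_image",
    "save_image",
]

UNDEFINED = np.nan


@dataclass(frozen=True)
class ViewVolume:
    """Axis-aligned bounding box of both molecules plus the pixel raster.

    The box fully contains every sphere (centre ± radius, plus padding).
    ``norm_factor`` is the z extent in Å.
    """

    xmin: float
    xmax: float
    ymin: float
    ymax: float
    zmin: float
    zmax: float
    pixel_size: float

    @property
    def width_px(self) -> int:
        return max(1, math.ceil((self.xmax - self.xmin) / self.pixel_size))

    @property
    def height_px(self) -> int:
        return max(1, math.ceil((self.ymax - self.ymin) / self.pixel_size))

    @property
    def norm_factor(self) -> float:
        return self.zmax - self.zmin

    @property
    def unit_area(self) -> float:
        """Physical area of one pixel, Å²."""
        return self.pixel_size ** 2

    def pixel_centers_x(self) -> np.ndarray:
        return self.xmin + (np.arange(self.width_px) + 0.5) * self.pixel_size

    def pixel_centers_y(self) -> np.ndarray:
        return self.ymin + (np.arange(self.height_px) + 0.5) * self.pixel_size


@dataclass
class DepthGrid:
    """height × width grid of surface z values (Å); NaN where no sphere projects."""

    values: np.ndarray
    side: str  # "-z": surface facing −z (minimum z); "+z": facing +z (maximum z)


@dataclass
class DistanceMap:
    """height × width grid of inter-surface gaps along z (Å); NaN = undefined.

    Negative values mean the surfaces interpenetrate along z (e.g. covalent
    contacts).  ``unit_area`` is the physical area of one pixel in Å².
    """

    values: np.ndarray
    unit_area: float
    volume: ViewVolume | None = None

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.values)


def align_to_binding_axis(mol_a: Molecule, mol_b: Molecule,
                          separating_direction: np.ndarray,
                          ) -> tuple[Molecule, Molecule, Rotation]:
    """Rotate both molecules rigidly so the separating direction becomes −z.

    After the rotation molecule B separates toward −z and molecule A lies on
    the +z side of the interface.  The rotation is the minimal-angle one
    about the axis d × (−z); when d is already along +z (antiparallel to the
    target) a 180° rotation about x is used.  Pairwise distances are
    preserved exactly (orthogonal transform).
    """
    d = np.asarray(separating_direction, dtype=float)
    n = np.linalg.norm(d)
    if not np.isfinite(n) or n < 1e-12:
        raise ValueError("separating direction must be a nonzero vector")
    d = d / n
    target = np.array([0.0, 0.0, -1.0])
    cross = np.cross(d, target)
    sin_angle = np.linalg.norm(cross)
    cos_angle = float(d @ target)
    if sin_angle < 1e-12:
        if cos_angle > 0:
            rot = Rotation.identity()
        else:  # d = +z: flip about x
            rot = Rotation.from_rotvec([np.pi, 0.0, 0.0])
    else:
        axis = cross / sin_angle
        angle = math.atan2(sin_angle, cos_angle)
        rot = Rotation.from_rotvec(axis * angle)
    mat = rot.as_matrix()
    return mol_a.transformed(rotation=mat), mol_b.transformed(rotation=mat), rot


def view_volume(mol_a: Molecule, mol_b: Molecule,
                pixel_size: float = 0.2, padding: float = 2.0) -> ViewVolume:
    """Bounding box of both molecules with sphere extents and padding."""
    if not pixel_size > 0:
        raise ValueError("pixel_size must be positive")
    centers = np.vstack([mol_a.centers, mol_b.centers])
    radii = np.concatenate([mol_a.radii, mol_b.radii])
    lo = (centers - radii[:, None]).min(axis=0) - padding
    hi = (centers + radii[:, None]).max(axis=0) + padding
    return ViewVolume(xmin=float(lo[0]), xmax=float(hi[0]),
                      ymin=float(lo[1]), ymax=float(hi[1]),
                      zmin=float(lo[2]), zmax=float(hi[2]),
                      pixel_size=float(pixel_size))


def rasterize_depth(molecule: Molecule, volume: ViewVolume,
                    facing: str) -> DepthGrid:
    """Orthographic depth buffer of a sphere set, computed analytically.

    For a pixel centre (x, y) each covering sphere contributes
    z = c_z ∓ sqrt(r² − ρ²) with ρ the in-plane distance to the sphere
    centre; ``facing="-z"`` keeps the minimum (the surface seen from
    z = −∞), ``facing="+z"`` the maximum.  Pixels covered by no sphere hold
    NaN.
    """
    if facing not in ("-z", "+z"):
        raise ValueError('facing must be "-z" or "+z"')
    w, h = volume.width_px, volume.height_px
    grid = np.full((h, w), UNDEFINED)
    px = volume.pixel_size
    xs = volume.pixel_centers_x()
    ys = volume.pixel_centers_y()
    reduce_ = np.fmin if facing == "-z" else np.fmax
    sign = -1.0 if facing == "-z" else 1.0
    for (cx, cy, cz), r in zip(molecule.centers, molecule.radii):
        i0 = max(0, int(np.searchsorted(xs, cx - r)))
        i1 = min(w, int(np.searchsorted(xs, cx + r)) + 1)
        j0 = max(0, int(np.searchsorted(ys, cy - r)))
        j1 = min(h, int(np.searchsorted(ys, cy + r)) + 1)
        if i0 >= i1 or j0 >= j1:
            continue
        dx = xs[i0:i1] - cx
        dy = ys[j0:j1] - cy
        rho2 = dx[None, :] ** 2 + dy[:, None] ** 2
        inside = rho2 <= r * r
        if not inside.any():
            continue
        cand = np.full_like(rho2, UNDEFINED)
        cand[inside] = cz + sign * np.sqrt(r * r - rho2[inside])
        sub = grid[j0:j1, i0:i1]
        grid[j0:j1, i0:i1] = reduce_(sub, cand)
    return DepthGrid(values=grid, side=facing)


def distance_map(mol_a: Molecule, mol_b: Molecule,
                 volume: ViewVolume | None = None,
                 pixel_size: float = 0.2, padding: float = 2.0) -> DistanceMap:
    """Gap along z between the partner-facing surfaces of aligned molecules.

    ``mol_a`` must lie on the +z side (its −z-facing surface is used),
    ``mol_b`` on the −z side (+z-facing surface).  Positive values are
    gaps, negative values interpenetration along z.  Raises ``ValueError``
    when the projections share no pixel.
    """
    if volume is None:
        volume = view_volume(mol_a, mol_b, pixel_size=pixel_size, padding=padding)
    da = rasterize_depth(mol_a, volume, "-z")
    db = rasterize_depth(mol_b, volume, "+z")
    gap = da.values - db.values           # NaN propagates to undefined pixels
    if not np.isfinite(gap).any():
        raise ValueError("projections of the two molecules do not overlap")
    return DistanceMap(values=gap, unit_area=volume.unit_area, volume=volume)


def quantized_difference_image(dist_map: DistanceMap, threshold: float) -> np.ndarray:
    """Boolean contact mask: defined pixels whose gap is ≤ threshold (Å)."""
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    with np.errstate(invalid="ignore"):
        return np.where(dist_map.defined, dist_map.values <= threshold, False)


def depth_image(grid: DepthGrid, background: int = 128) -> np.ndarray:
    """8-bit grayscale rendering of a depth buffer; background is mid-gray."""
    vals = grid.values
    finite = np.isfinite(vals)
    img = np.full(vals.shape, background, dtype=np.uint8)
    if finite.any():
        lo, hi = vals[finite].min(), vals[finite].max()
        span = hi - lo if hi > lo else 1.0
        img[finite] = np.round(255 * (vals[finite] - lo) / span).astype(np.uint8)
    return img


def save_image(array: np.ndarray, path) -> None:
    """Write a 2-D uint8 or boolean array as PGM or PNG (by file suffix)."""
    if array.dtype == bool:
        array = (array * 255).astype(np.uint8)
    # flip so +y points up in the written image
    Image.fromarray(np.flipud(array)).save(str(path))
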
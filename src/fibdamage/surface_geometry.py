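"""Interpolated milling-surface sheets and per-particle depth computation.

A lamella is a thin slab bounded by two milling surfaces ("front" = lower
height along the beam axis, "back" = upper). The surfaces are annotated
manually on sparse slices and interpolated here into height fields
h(u, v) on a regular lateral grid, then triangulated. Each particle's
damage-relevant depth is the unsigned shortest 3-D distance to the nearer
triangulated sheet — not the vertical distance — converted to nm.

Coordinates: u and v are the two lateral voxel axes (u is the in-slice
axis of an annotation polyline, v the slice axis), heights are voxel
positions along the beam axis. All distances are computed in voxels
(isotropic) and converted with ``pixel_size_A`` (nm = voxels * Å/px / 10).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numba
import numpy as np
import pandas as pd

from .io_formats import AnnotationSet, ParticleTable

logger = logging.getLogger(__name__)

__all__ = [
    "SurfaceSheet",
    "DepthRecord",
    "interpolate_surface",
    "particle_depth",
    "particle_depths",
    "local_thickness",
    "thickness_summary",
    "point_triangle_distance",
]


@dataclass
class SurfaceSheet:
    """One milling surface as a height field over a regular lateral grid.

    ``heights[i, j]`` is the surface height (voxels) at lateral position
    ``(u0 + i * grid_step, v0 + j * grid_step)``. The implied triangulation
    splits each grid cell along the (0,0)-(1,1) diagonal, which makes the
    sheet a watertight piecewise-linear surface over the grid interior.
    """

    heights: np.ndarray
    u0: float
    v0: float
    grid_step: float
    role: str = "front"

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2 or min(self.heights.shape) < 2:
            raise ValueError(f"height field needs a 2-D grid >= 2x2, got {self.heights.shape}")
        if not np.all(np.isfinite(self.heights)):
            raise ValueError("height field contains non-finite values")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        if self.role not in ("front", "back"):
            raise ValueError(f"sheet role must be 'front' or 'back', got {self.role!r}")

    @property
    def u_max(self) -> float:
        return self.u0 + (self.heights.shape[0] - 1) * self.grid_step

    @property
    def v_max(self) -> float:
        return self.v0 + (self.heights.shape[1] - 1) * self.grid_step

    def contains_lateral(self, u, v) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        return (u >= self.u0) & (u <= self.u_max) & (v >= self.v0) & (v <= self.v_max)

    def height_at(self, u, v) -> np.ndarray:
        """Height of the triangulated surface at lateral positions (u, v).

        Uses the same piecewise-linear interpolation as the triangulation
        (cells split along the main diagonal), so the returned point lies
        exactly on the surface.
        """
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        nu, nv = self.heights.shape
        gu = np.clip((u - self.u0) / self.grid_step, 0.0, nu - 1 - 1e-12)
        gv = np.clip((v - self.v0) / self.grid_step, 0.0, nv - 1 - 1e-12)
        iu = np.floor(gu).astype(int)
        iv = np.floor(gv).astype(int)
        fu = gu - iu
        fv = gv - iv
        h00 = self.heights[iu, iv]
        h10 = self.heights[iu + 1, iv]
        h01 = self.heights[iu, iv + 1]
        h11 = self.heights[iu + 1, iv + 1]
        # lower triangle (fu >= fv): plane through h00, h10, h11
        lower = h00 + fu * (h10 - h00) + fv * (h11 - h10)
        # upper triangle (fu < fv): plane through h00, h11, h01
        upper = h00 + fv * (h01 - h00) + fu * (h11 - h01)
        return np.where(fu >= fv, lower, upper)

    def nearest_distance(self, points: np.ndarray) -> np.ndarray:
        """Unsigned shortest distance (voxels) from 3-D points to the sheet.

        Exact with respect to the triangulation. Grid cells are visited in
        rings of increasing lateral distance from each point; a ring whose
        lateral lower bound exceeds the best distance found so far cannot
        contain a closer triangle, so the search terminates after a handful
        of cells for smooth sheets while remaining exact for rough ones.
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.full(len(points), np.nan)
        inside = self.contains_lateral(points[:, 0], points[:, 1])
        if not inside.any():
            return out
        out[inside] = _nearest_distance_kernel(
            self.heights,
            float(self.u0),
            float(self.v0),
            float(self.grid_step),
            np.ascontiguousarray(points[inside], dtype=np.float64),
        )
        return out


@dataclass
class DepthRecord:
    """Shortest distance of one particle to the nearer milling surface."""

    particle_id: str
    depth_nm: float
    thickness_nm: float
    inside: bool
    in_bounds: bool = True


def point_triangle_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Distance from points ``p`` to triangles ``(a, b, c)``, broadcast over
    leading dimensions (standard closest-point-on-triangle construction)."""
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.sum(ab * ap, axis=-1)
    d2 = np.sum(ac * ap, axis=-1)
    bp = p - b
    d3 = np.sum(ab * bp, axis=-1)
    d4 = np.sum(ac * bp, axis=-1)
    cp = p - c
    d5 = np.sum(ab * cp, axis=-1)
    d6 = np.sum(ac * cp, axis=-1)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2
    denom = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(denom != 0, vb / denom, 0.0)
        w = np.where(denom != 0, vc / denom, 0.0)
    closest = a + v[..., None] * ab + w[..., None] * ac  # interior case

    # vertex regions
    closest = np.where(((d1 <= 0) & (d2 <= 0))[..., None], a, closest)
    closest = np.where(((d3 >= 0) & (d4 <= d3))[..., None], b, closest)
    closest = np.where(((d6 >= 0) & (d5 <= d6))[..., None], c, closest)
    # edge AB
    with np.errstate(divide="ignore", invalid="ignore"):
        t_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
    on_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    closest = np.where(on_ab[..., None], a + t_ab[..., None] * ab, closest)
    # edge AC
    with np.errstate(divide="ignore", invalid="ignore"):
        t_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
    on_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    closest = np.where(on_ac[..., None], a + t_ac[..., None] * ac, closest)
    # edge BC
    with np.errstate(divide="ignore", invalid="ignore"):
        t_bc = np.where((d4 - d3) + (d5 - d6) != 0, (d4 - d3) / ((d4 - d3) + (d5 - d6)), 0.0)
    on_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    closest = np.where(on_bc[..., None], b + t_bc[..., None] * (c - b), closest)

    return np.linalg.norm(p - closest, axis=-1)


@numba.njit(cache=True, fastmath=False)
def _tri_dist_sq(px, py, pz, ax, ay, az, bx, by, bz, cx, cy, cz):  # pragma: no cover
    """Squared distance from a point to one triangle (scalar Ericson)."""
    abx, aby, abz = bx - ax, by - ay, bz - az
    acx, acy, acz = cx - ax, cy - ay, cz - az
    apx, apy, apz = px - ax, py - ay, pz - az
    d1 = abx * apx + aby * apy + abz * apz
    d2 = acx * apx + acy * apy + acz * apz
    if d1 <= 0.0 and d2 <= 0.0:
        return apx * apx + apy * apy + apz * apz
    bpx, bpy, bpz = px - bx, py - by, pz - bz
    d3 = abx * bpx + aby * bpy + abz * bpz
    d4 = acx * bpx + acy * bpy + acz * bpz
    if d3 >= 0.0 and d4 <= d3:
        return bpx * bpx + bpy * bpy + bpz * bpz
    vc = d1 * d4 - d3 * d2
    if vc <= 0.0 and d1 >= 0.0 and d3 <= 0.0:
        t = d1 / (d1 - d3)
        qx, qy, qz = apx - t * abx, apy - t * aby, apz - t * abz
        return qx * qx + qy * qy + qz * qz
    cpx, cpy, cpz = px - cx, py - cy, pz - cz
    d5 = abx * cpx + aby * cpy + abz * cpz
    d6 = acx * cpx + acy * cpy + acz * cpz
    if d6 >= 0.0 and d5 <= d6:
        return cpx * cpx + cpy * cpy + cpz * cpz
    vb = d5 * d2 - d1 * d6
    if vb <= 0.0 and d2 >= 0.0 and d6 <= 0.0:
        t = d2 / (d2 - d6)
        qx, qy, qz = apx - t * acx, apy - t * acy, apz - t * acz
        return qx * qx + qy * qy + qz * qz
    va = d3 * d6 - d5 * d4
    if va <= 0.0 and d4 - d3 >= 0.0 and d5 - d6 >= 0.0:
        t = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        qx = bpx - t * (cx - bx)
        qy = bpy - t * (cy - by)
        qz = bpz - t * (cz - bz)
        return qx * qx + qy * qy + qz * qz
    denom = va + vb + vc
    v = vb / denom
    w = vc / denom
    qx = apx - (v * abx + w * acx)
    qy = apy - (v * aby + w * acy)
    qz = apz - (v * abz + w * acz)
    return qx * qx + qy * qy + qz * qz


@numba.njit(cache=True)
def _cell_min_dist_sq(H, u0, v0, s, iu, iv, px, py, pz):  # pragma: no cover
    """Min squared distance to the two triangles of grid cell (iu, iv)."""
    ax = u0 + iu * s
    ay = v0 + iv * s
    h00 = H[iu, iv]
    h10 = H[iu + 1, iv]
    h01 = H[iu, iv + 1]
    h11 = H[iu + 1, iv + 1]
    d1 = _tri_dist_sq(px, py, pz, ax, ay, h00, ax + s, ay, h10, ax + s, ay + s, h11)
    d2 = _tri_dist_sq(px, py, pz, ax, ay, h00, ax + s, ay + s, h11, ax, ay + s, h01)
    return min(d1, d2)


@numba.njit(cache=True)
def _nearest_distance_kernel(H, u0, v0, s, pts):  # pragma: no cover
    nu, nv = H.shape
    n = pts.shape[0]
    out = np.empty(n)
    max_ring = max(nu, nv)
    for i in range(n):
        px, py, pz = pts[i, 0], pts[i, 1], pts[i, 2]
        iu = int((px - u0) / s)
        iv = int((py - v0) / s)
        if iu > nu - 2:
            iu = nu - 2
        if iv > nv - 2:
            iv = nv - 2
        if iu < 0:
            iu = 0
        if iv < 0:
            iv = 0
        best = _cell_min_dist_sq(H, u0, v0, s, iu, iv, px, py, pz)
        for r in range(1, max_ring):
            # cells on Chebyshev ring r are laterally >= (r-1)*s away
            lb = (r - 1) * s
            if best <= lb * lb:
                break
            lo_u, hi_u = iu - r, iu + r
            lo_v, hi_v = iv - r, iv + r
            any_cell = False
            for cu in range(max(lo_u, 0), min(hi_u, nu - 2) + 1):
                for cv in range(max(lo_v, 0), min(hi_v, nv - 2) + 1):
                    if cu != lo_u and cu != hi_u and cv != lo_v and cv != hi_v:
                        continue  # interior of the ring already visited
                    any_cell = True
                    d = _cell_min_dist_sq(H, u0, v0, s, cu, cv, px, py, pz)
                    if d < best:
                        best = d
            if not any_cell:
                break
        out[i] = np.sqrt(best)
    return out


def interpolate_surface(
    annotation_slices: list[tuple[int, np.ndarray]],
    grid_step: float = 10.0,
    role: str = "front",
    u_range: tuple[float, float] | None = None,
    v_range: tuple[float, float] | None = None,
) -> SurfaceSheet:
    """Interpolate sparse slice annotations into a continuous sheet.

    Within each annotated slice the polyline is linearly interpolated along
    u (clamped to the end heights beyond the polyline). Between annotated
    slices, heights are blended linearly along v; beyond the first/last
    annotated slice the nearest slice's profile is extended unchanged.
    """
    if len(annotation_slices) < 1:
        raise ValueError("annotation has no slices")
    profiles = []
    slice_idx = []
    u_lo = np.inf
    u_hi = -np.inf
    for s, pts in annotation_slices:
        pts = np.asarray(pts, dtype=float)
        if pts.ndim != 2 or pts.shape[0] < 2:
            raise ValueError(f"slice {s}: need >= 2 annotation points")
        order = np.argsort(pts[:, 0])
        profiles.append(pts[order])
        slice_idx.append(float(s))
        u_lo = min(u_lo, pts[:, 0].min())
        u_hi = max(u_hi, pts[:, 0].max())
    if u_range is not None:
        u_lo, u_hi = u_range
    if v_range is None:
        v_lo, v_hi = slice_idx[0], slice_idx[-1]
    else:
        v_lo, v_hi = v_range
    if v_hi <= v_lo:
        v_hi = v_lo + grid_step  # single annotated slice: constant extrusion

    def cover(lo: float, hi: float) -> np.ndarray:
        # grid must reach hi so every lateral position in [lo, hi] is covered
        n_steps = max(int(np.ceil((hi - lo) / grid_step - 1e-9)), 1)
        return lo + grid_step * np.arange(n_steps + 1)

    u_grid = cover(u_lo, u_hi)
    v_grid = cover(v_lo, v_hi)

    # per-slice height profile on the u grid (edge-clamped linear interp)
    slice_heights = np.stack(
        [np.interp(u_grid, prof[:, 0], prof[:, 1]) for prof in profiles]
    )  # (n_slices, nu)
    # blend along v, nearest-slice clamped outside [first, last]
    heights = np.empty((len(u_grid), len(v_grid)))
    for j, vpos in enumerate(v_grid):
        heights[:, j] = _blend_slices(vpos, slice_idx, slice_heights)
    return SurfaceSheet(heights, u0=u_grid[0], v0=v_grid[0], grid_step=grid_step, role=role)


def _blend_slices(v: float, slice_idx: list[float], slice_heights: np.ndarray) -> np.ndarray:
    if v <= slice_idx[0]:
        return slice_heights[0]
    if v >= slice_idx[-1]:
        return slice_heights[-1]
    j = int(np.searchsorted(slice_idx, v, side="right")) - 1
    t = (v - slice_idx[j]) / (slice_idx[j + 1] - slice_idx[j])
    return (1 - t) * slice_heights[j] + t * slice_heights[j + 1]


def sheets_from_annotations(
    annotations: AnnotationSet,
    grid_step: float = 10.0,
    lateral_bounds: dict[str, tuple[float, float, float, float]] | None = None,
) -> dict[str, tuple["SurfaceSheet", "SurfaceSheet"]]:
    """Interpolate front/back sheets for every annotated tomogram.

    ``lateral_bounds`` maps tomogram id to (u_lo, u_hi, v_lo, v_hi) so the
    interpolated grids can cover the particles' full lateral extent;
    beyond the annotated slices the nearest slice's profile is extended
    (clamped). Without bounds the grids cover the annotated extent only.
    """
    sheets = {}
    for tomo in annotations.tomograms():
        if lateral_bounds is not None and tomo in lateral_bounds:
            u_lo, u_hi, v_lo, v_hi = lateral_bounds[tomo]
            u_range, v_range = (u_lo, u_hi), (v_lo, v_hi)
        else:
            u_range = v_range = None
        sheets[tomo] = tuple(
            interpolate_surface(
                annotations.sheet(tomo, role),
                grid_step,
                role=role,
                u_range=u_range,
                v_range=v_range,
            )
            for role in ("front", "back")
        )
    return sheets


def particle_depths(
    table: ParticleTable,
    sheets: dict[str, tuple[SurfaceSheet, SurfaceSheet]],
    pixel_size_A: float | None = None,
) -> pd.DataFrame:
    """Depth and local thickness for every particle in a table.

    ``sheets`` maps tomogram id to its (front, back) surfaces. Returns the
    particle table's frame with ``depth_nm``, ``thickness_nm``, ``inside``
    and ``in_bounds`` columns added. Particles laterally outside the sheet
    grids get NaN depth and ``in_bounds=False``; their count is logged.
    """
    pix = table.pixel_size_A if pixel_size_A is None else pixel_size_A
    nm = pix / 10.0
    df = table.df.copy()
    depth = np.full(len(df), np.nan)
    thickness = np.full(len(df), np.nan)
    inside = np.zeros(len(df), dtype=bool)
    in_bounds = np.zeros(len(df), dtype=bool)
    for tomo, sub in df.groupby("tomogram_id", sort=False):
        if tomo not in sheets:
            logger.warning("no surfaces for tomogram %s: %d particles skipped", tomo, len(sub))
            continue
        front, back = sheets[tomo]
        idx = sub.index.to_numpy()
        pts = sub[["x", "y", "z"]].to_numpy(dtype=float)
        ok = front.contains_lateral(pts[:, 0], pts[:, 1]) & back.contains_lateral(
            pts[:, 0], pts[:, 1]
        )
        in_bounds[df.index.get_indexer(idx)] = ok
        if not ok.any():
            continue
        d_front = front.nearest_distance(pts[ok])
        d_back = back.nearest_distance(pts[ok])
        hf = front.height_at(pts[ok, 0], pts[ok, 1])
        hb = back.height_at(pts[ok, 0], pts[ok, 1])
        pos = df.index.get_indexer(idx[ok])
        depth[pos] = np.minimum(d_front, d_back) * nm
        thickness[pos] = (hb - hf) * nm
        inside[pos] = (pts[ok, 2] >= hf) & (pts[ok, 2] <= hb)
    n_out = int((~in_bounds).sum())
    if n_out:
        logger.info("%d of %d particles laterally outside the surface grids", n_out, len(df))
    df["depth_nm"] = depth
    df["thickness_nm"] = thickness
    df["inside"] = inside
    df["in_bounds"] = in_bounds
    return df


def particle_depth(
    particle_xyz: np.ndarray,
    front_sheet: SurfaceSheet,
    back_sheet: SurfaceSheet,
    pixel_size_A: float,
    particle_id: str = "p0",
) -> DepthRecord:
    """Depth record for a single particle (see :func:`particle_depths`)."""
    p = np.asarray(particle_xyz, dtype=float).reshape(1, 3)
    nm = pixel_size_A / 10.0
    ok = bool(
        front_sheet.contains_lateral(p[0, 0], p[0, 1])
        and back_sheet.contains_lateral(p[0, 0], p[0, 1])
    )
    if not ok:
        return DepthRecord(particle_id, float("nan"), float("nan"), False, in_bounds=False)
    d = min(front_sheet.nearest_distance(p)[0], back_sheet.nearest_distance(p)[0]) * nm
    hf = float(front_sheet.height_at(p[0, 0], p[0, 1]))
    hb = float(back_sheet.height_at(p[0, 0], p[0, 1]))
    return DepthRecord(particle_id, d, (hb - hf) * nm, hf <= p[0, 2] <= hb)


def local_thickness(
    front_sheet: SurfaceSheet,
    back_sheet: SurfaceSheet,
    lateral_position: tuple[float, float],
    pixel_size_A: float,
) -> float:
    """Vertical separation of the two sheets at a lateral position, in nm.

    Crossing sheets (back below front) yield NaN with a logged warning.
    """
    u, v = lateral_position
    if not (front_sheet.contains_lateral(u, v) and back_sheet.contains_lateral(u, v)):
        raise ValueError(f"lateral position {lateral_position} outside sheet grids")
    sep = (float(back_sheet.height_at(u, v)) - float(front_sheet.height_at(u, v))) * (
        pixel_size_A / 10.0
    )
    if sep < 0:
        logger.warning("sheets cross at %s: separation %.2f nm", lateral_position, sep)
        return float("nan")
    return sep


def thickness_summary(depth_df: pd.DataFrame) -> dict:
    """Thickness summary over per-tomogram mean thicknesses.

    Mirrors how lamella thickness distributions are reported for tomogram
    sets: each tomogram contributes its mean local thickness; the summary
    is the mean, median and sample SD over tomograms. A single tomogram
    has undefined SD, reported as 0 with ``sd_defined=False``.
    """
    valid = depth_df.dropna(subset=["thickness_nm"])
    if len(valid) == 0:
        raise ValueError("no valid thickness records")
    per_tomo = valid.groupby("tomogram_id")["thickness_nm"].mean()
    sd_defined = len(per_tomo) > 1
    return {
        "mean_nm": float(per_tomo.mean()),
        "median_nm": float(per_tomo.median()),
        "sd_nm": float(per_tomo.std(ddof=1)) if sd_defined else 0.0,
        "n_tomograms": int(len(per_tomo)),
        "sd_defined": sd_defined,
    }
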
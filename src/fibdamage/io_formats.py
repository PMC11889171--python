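"""Readers and writers for the formats the damage pipeline touches.

Particle metadata travels in STAR files (the interchange format of the
subtomogram-averaging ecosystem: Warp, RELION, M), half maps in MRC, and
surface annotations / resolution series / reports in plain CSV.

The STAR support here is deliberately small: a single particle loop block,
read either from a RELION-3.1-style named block (``data_particles``) or a
legacy bare ``data_`` block. Column names are matched case-sensitively and
unknown columns are carried through opaquely so that round-tripping a file
written by an upstream tool loses nothing.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "ParticleTable",
    "VolumeGrid",
    "AnnotationSet",
    "StarFormatError",
    "read_particle_star",
    "write_particle_star",
    "read_volume",
    "write_volume",
    "read_annotations",
    "write_annotations",
    "read_resolution_series",
    "write_resolution_series",
]

# Canonical STAR column names (RELION dialect) for the fields we interpret.
COORD_COLUMNS = ("rlnCoordinateX", "rlnCoordinateY", "rlnCoordinateZ")
TOMO_COLUMNS = ("rlnTomoName", "rlnMicrographName")
PIXEL_COLUMNS = ("rlnDetectorPixelSize", "rlnImagePixelSize")

# Derived per-particle quantities are emitted with a tool-specific prefix,
# mirroring how Warp (wrp*) and RELION (rln*) namespace their columns.
DERIVED_STAR_COLUMNS = {
    "particle_id": "fibParticleId",
    "depth_nm": "fibDepthNm",
    "thickness_nm": "fibThicknessNm",
    "backside_um": "fibBacksideUm",
    "cohort_label": "fibCohort",
    "inside": "fibInsideLamella",
}


class StarFormatError(ValueError):
    """Raised when a STAR file cannot be interpreted as a particle table."""


@dataclass
class ParticleTable:
    """Per-particle records for one dataset.

    ``df`` holds one row per particle with at least ``particle_id``,
    ``tomogram_id`` and voxel coordinates ``x, y, z`` (0-based, at the
    binning the table was produced at). Optional derived columns:
    ``depth_nm``, ``thickness_nm``, ``backside_um``, ``cohort_label``,
    ``inside``. Physical distances are always voxels * ``pixel_size_A``.
    """

    df: pd.DataFrame
    pixel_size_A: float
    extra_columns: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        required = ("particle_id", "tomogram_id", "x", "y", "z")
        for col in required:
            if col not in self.df.columns:
                raise ValueError(f"particle table missing column {col!r}")
        if len(self.df) == 0:
            raise ValueError("particle table is empty")
        if not np.isfinite(self.pixel_size_A) or self.pixel_size_A <= 0:
            raise ValueError(f"pixel_size_A must be positive, got {self.pixel_size_A}")
        coords = self.df[["x", "y", "z"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(coords)):
            raise ValueError("particle coordinates must be finite")
        if self.df["tomogram_id"].astype(str).str.len().min() == 0:
            raise ValueError("tomogram_id must be non-empty")
        if self.df["particle_id"].duplicated().any():
            dup = self.df["particle_id"][self.df["particle_id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate particle_id {dup!r}")

    def __len__(self) -> int:
        return len(self.df)

    def copy(self) -> "ParticleTable":
        return ParticleTable(
            self.df.copy(), self.pixel_size_A, {k: v.copy() for k, v in self.extra_columns.items()}
        )


@dataclass
class VolumeGrid:
    """3-D density grid with a physical voxel size (carrier for half maps)."""

    data: np.ndarray
    voxel_size_A: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"not a volume: expected 3 dimensions, got {self.data.ndim}")
        if min(self.data.shape) < 2:
            raise ValueError(f"not a volume: degenerate shape {self.data.shape}")
        if not self.voxel_size_A > 0:
            raise ValueError(f"voxel_size_A must be positive, got {self.voxel_size_A}")


@dataclass
class AnnotationSet:
    """Sparse manual annotations of the two milling surfaces.

    For each (tomogram, sheet) pair a list of annotated slices. Slices are
    taken along one lateral axis (``v``); each annotated slice carries an
    ordered polyline of (u, height) points in the orthogonal plane, in
    voxels. ``sheet`` is "front" (lower height) or "back" (upper height).
    """

    slices: dict[tuple[str, str], list[tuple[int, np.ndarray]]]
    slice_spacing: int = 100

    def __post_init__(self) -> None:
        for (tomo, sheet), entries in self.slices.items():
            if sheet not in ("front", "back"):
                raise ValueError(f"unknown sheet role {sheet!r} for tomogram {tomo!r}")
            if len(entries) < 1:
                raise ValueError(f"no annotated slices for ({tomo!r}, {sheet!r})")
            idx = [s for s, _ in entries]
            if any(b <= a for a, b in zip(idx, idx[1:])):
                raise ValueError(f"slice indices not strictly increasing for ({tomo!r}, {sheet!r})")
            for s, pts in entries:
                pts = np.asarray(pts, dtype=float)
                if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
                    raise ValueError(
                        f"slice {s} of ({tomo!r}, {sheet!r}) needs >= 2 (u, height) points"
                    )

    def tomograms(self) -> list[str]:
        return sorted({t for t, _ in self.slices})

    def sheet(self, tomogram_id: str, sheet: str) -> list[tuple[int, np.ndarray]]:
        try:
            return self.slices[(tomogram_id, sheet)]
        except KeyError:
            raise KeyError(f"no annotation for ({tomogram_id!r}, {sheet!r})") from None


# ---------------------------------------------------------------------------
# STAR
# ---------------------------------------------------------------------------

def _parse_star_blocks(text: str) -> dict[str, pd.DataFrame]:
    """Parse every loop block of a STAR file into a DataFrame (values as str)."""
    blocks: dict[str, pd.DataFrame] = {}
    lines = text.splitlines()
    i, n = 0, len(lines)
    current_block = ""
    while i < n:
        line = lines[i].strip()
        if line.startswith("data_"):
            current_block = line[5:]
            i += 1
        elif line == "loop_":
            i += 1
            columns = []
            while i < n:
                s = lines[i].strip()
                if s.startswith("_"):
                    columns.append(s.split()[0].lstrip("_"))
                    i += 1
                else:
                    break
            rows = []
            while i < n:
                s = lines[i].strip()
                if not s or s.startswith(("data_", "loop_", "#")):
                    break
                rows.append(s.split())
                i += 1
            if columns:
                bad = [r for r in rows if len(r) != len(columns)]
                if bad:
                    raise StarFormatError(
                        f"row with {len(bad[0])} fields in loop with {len(columns)} columns"
                    )
                blocks[current_block] = pd.DataFrame(rows, columns=columns)
        else:
            i += 1
    return blocks


def _coerce_numeric(series: pd.Series) -> pd.Series:
    out = pd.to_numeric(series, errors="coerce")
    if out.isna().any():
        return series
    return out


def read_particle_star(
    path: str | os.PathLike,
    required_columns: Sequence[str] = COORD_COLUMNS,
    pixel_size_A: float | None = None,
) -> ParticleTable:
    """Read a particle STAR file into a :class:`ParticleTable`.

    The particle block is located as the loop block containing coordinate
    columns (named ``data_particles`` or bare). ``pixel_size_A`` overrides
    or supplies the pixel size when the table has no pixel-size column.
    """
    with open(path) as fh:
        blocks = _parse_star_blocks(fh.read())
    if not blocks:
        raise StarFormatError(f"no loop block found in {path}")

    particle_block = None
    for name, df in blocks.items():
        if "rlnCoordinateX" in df.columns:
            particle_block = df
            break
    if particle_block is None:
        # fall back to the largest block so the error names the right column
        particle_block = max(blocks.values(), key=len)
    df = particle_block
    if len(df) == 0:
        raise StarFormatError(f"particle table in {path} is empty")

    for col in required_columns:
        if col not in df.columns:
            raise StarFormatError(f"missing required column {col!r} in {path}")

    tomo_col = next((c for c in TOMO_COLUMNS if c in df.columns), None)
    if tomo_col is None:
        raise StarFormatError(
            f"missing tomogram name column (one of {TOMO_COLUMNS}) in {path}"
        )

    if pixel_size_A is None:
        pix_col = next((c for c in PIXEL_COLUMNS if c in df.columns), None)
        if pix_col is None:
            raise StarFormatError(
                f"no pixel size column in {path}; pass pixel_size_A explicitly"
            )
        pixel_size_A = float(df[pix_col].astype(float).iloc[0])

    out = pd.DataFrame()
    if DERIVED_STAR_COLUMNS["particle_id"] in df.columns:
        out["particle_id"] = df[DERIVED_STAR_COLUMNS["particle_id"]].astype(str)
    else:
        out["particle_id"] = [f"p{i:07d}" for i in range(len(df))]
    out["tomogram_id"] = df[tomo_col].astype(str)
    for axis, col in zip(("x", "y", "z"), COORD_COLUMNS):
        if col in df.columns:
            out[axis] = df[col].astype(float)
        elif col in required_columns:  # pragma: no cover - caught above
            raise StarFormatError(f"missing required column {col!r}")
        else:
            out[axis] = 0.0
    for internal, star_name in DERIVED_STAR_COLUMNS.items():
        if internal == "particle_id" or star_name not in df.columns:
            continue
        if internal in ("cohort_label",):
            out[internal] = df[star_name].astype(str)
        elif internal == "inside":
            out[internal] = df[star_name].astype(int).astype(bool)
        else:
            out[internal] = df[star_name].astype(float)

    consumed = set(COORD_COLUMNS) | {tomo_col} | set(DERIVED_STAR_COLUMNS.values())
    extra = {
        c: _coerce_numeric(df[c]).to_numpy()
        for c in df.columns
        if c not in consumed
    }
    return ParticleTable(out, float(pixel_size_A), extra)


def write_particle_star(table: ParticleTable, path: str | os.PathLike) -> None:
    """Write a :class:`ParticleTable` as a single ``data_particles`` loop.

    Derived columns (depth, thickness, backside distance, cohort) present in
    the table are emitted as additional named columns; opaque extra columns
    are carried through unchanged.
    """
    if len(table.df) == 0:
        raise ValueError("refusing to write an empty particle table")
    df = table.df
    cols: dict[str, Sequence] = {}
    cols[DERIVED_STAR_COLUMNS["particle_id"]] = df["particle_id"].astype(str)
    cols["rlnTomoName"] = df["tomogram_id"].astype(str)
    for axis, col in zip(("x", "y", "z"), COORD_COLUMNS):
        cols[col] = [_fmt_float(v) for v in df[axis]]
    cols["rlnDetectorPixelSize"] = [_fmt_float(table.pixel_size_A)] * len(df)
    for internal, star_name in DERIVED_STAR_COLUMNS.items():
        if internal == "particle_id" or internal not in df.columns:
            continue
        if internal == "cohort_label":
            cols[star_name] = df[internal].astype(str)
        elif internal == "inside":
            cols[star_name] = df[internal].astype(int).astype(str)
        else:
            cols[star_name] = [_fmt_float(v) for v in df[internal]]
    for name, values in table.extra_columns.items():
        cols[name] = [
            _fmt_float(v) if isinstance(v, (float, np.floating)) else str(v) for v in values
        ]

    buf = io.StringIO()
    buf.write("\ndata_particles\n\nloop_\n")
    for i, name in enumerate(cols, start=1):
        buf.write(f"_{name} #{i}\n")
    matrix = list(cols.values())
    for row in zip(*matrix):
        buf.write(" ".join(str(v) for v in row) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def _fmt_float(v: float) -> str:
    if isinstance(v, (bool, np.bool_)):
        return str(int(v))
    if v != v:  # NaN
        return "nan"
    return f"{float(v):.6f}"


# ---------------------------------------------------------------------------
# MRC volumes (via gemmi's CCP4/MRC map support)
# ---------------------------------------------------------------------------

def read_volume(path: str | os.PathLike, voxel_size_A: float | None = None) -> VolumeGrid:
    """Read an MRC/CCP4 volume. ``voxel_size_A`` overrides a zero header value."""
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot read MRC volume {path}: {exc}") from exc
    data = np.array(ccp4.grid, copy=True)
    if data.ndim != 3 or min(data.shape) < 2:
        raise ValueError(f"not a volume: {path} has shape {data.shape}")
    spacings = np.array(ccp4.grid.spacing)
    if np.any(spacings <= 0):
        if voxel_size_A is None:
            raise ValueError(f"{path} has zero voxel size in header; pass voxel_size_A")
        vox = float(voxel_size_A)
    else:
        if not np.allclose(spacings, spacings[0], rtol=1e-3):
            raise ValueError(f"anisotropic voxels {spacings} not supported")
        vox = float(spacings[0]) if voxel_size_A is None else float(voxel_size_A)
    return VolumeGrid(data, vox)


def write_volume(volume: VolumeGrid, path: str | os.PathLike) -> None:
    """Write a :class:`VolumeGrid` as a mode-2 (float32) MRC map."""
    grid = gemmi.FloatGrid(np.ascontiguousarray(volume.data, dtype=np.float32))
    n0, n1, n2 = volume.data.shape
    v = volume.voxel_size_A
    grid.set_unit_cell(gemmi.UnitCell(n0 * v, n1 * v, n2 * v, 90.0, 90.0, 90.0))
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    ccp4.write_ccp4_map(str(path))


# ---------------------------------------------------------------------------
# CSV: annotations and resolution series
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = ["tomogram_id", "sheet", "slice_index", "point_u", "point_v"]


def read_annotations(path: str | os.PathLike, slice_spacing: int = 100) -> AnnotationSet:
    """Read surface annotations from CSV.

    Schema: ``tomogram_id, sheet, slice_index, point_u, point_v`` where
    ``point_v`` is the surface height at lateral position ``point_u`` on the
    annotated slice. Point order within a slice follows file order.
    """
    df = pd.read_csv(path)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation CSV {path} missing columns {missing}")
    if len(df) == 0:
        raise ValueError(f"annotation CSV {path} is empty")
    slices: dict[tuple[str, str], list[tuple[int, np.ndarray]]] = {}
    for (tomo, sheet), sub in df.groupby(["tomogram_id", "sheet"], sort=True):
        entries = []
        for s, pts in sub.groupby("slice_index", sort=True):
            entries.append((int(s), pts[["point_u", "point_v"]].to_numpy(dtype=float)))
        slices[(str(tomo), str(sheet))] = entries
    return AnnotationSet(slices, slice_spacing=slice_spacing)


def write_annotations(annotations: AnnotationSet, path: str | os.PathLike) -> None:
    rows = []
    for (tomo, sheet), entries in sorted(annotations.slices.items()):
        for s, pts in entries:
            for u, v in np.asarray(pts, dtype=float):
                rows.append((tomo, sheet, s, u, v))
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, index=False)


RESOLUTION_COLUMNS = ["group", "repeat", "n_particles", "resolution_A"]


def read_resolution_series(path: str | os.PathLike) -> pd.DataFrame:
    """Read a resolution series CSV: ``group, repeat, n_particles, resolution_A``."""
    df = pd.read_csv(path)
    missing = [c for c in RESOLUTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"resolution series CSV {path} missing columns {missing}")
    df["n_particles"] = df["n_particles"].astype(int)
    df["resolution_A"] = df["resolution_A"].astype(float)
    if (df["resolution_A"] <= 0).any():
        raise ValueError("resolutions must be positive")
    return df[RESOLUTION_COLUMNS].copy()


def write_resolution_series(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df[RESOLUTION_COLUMNS].to_csv(path, index=False)
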
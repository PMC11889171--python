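"""Synthetic lamella datasets with known ground truth.

Generates every input the damage pipeline consumes: slab-shaped lamella
geometry (two gently tilted, sinusoidally rough milling surfaces per
tomogram), particles placed uniformly through the slab, sparse surface
annotations sampled from the true sheets, backside acquisition distances,
Rosenthal-Henderson-distributed resolution series, and FSC-controlled
half-map pairs.

The damage model is a multiplicative exponential inflation of the bulk
B-factor towards the milling surfaces,

    B(d) = B_bulk * (1 + (dB / B_bulk) * exp(-d / lambda)),

an invention consistent with the expectation that collision-cascade
damage decays exponentially with depth; it is ground truth for recovery
tests, not a claim about mechanism. Defaults echo the regime of the
xenon PFIB ribosome study: bulk B ~ 300 A^2, shallow-bin B ~ 1400 A^2,
decay length lambda = 1/0.185 ~ 5.4 nm, ~200 +- 30 nm lamellae at
15.2 A/px (binning 8), ~80,000 particles over 167 tomograms.

Every stochastic output is a pure function of (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    AnnotationSet,
    ParticleTable,
    VolumeGrid,
    write_annotations,
    write_particle_star,
)
from .surface_geometry import SurfaceSheet

__all__ = [
    "SyntheticConfig",
    "bfactor_at_depth",
    "simulate_geometry",
    "simulate_particles",
    "simulate_resolution_series",
    "simulate_half_maps",
    "build_fixture_bundle",
]


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic generator (units in field names)."""

    n_tomograms: int = 167
    particles_per_tomogram: int = 490
    thickness_mean_nm: float = 200.0
    thickness_sd_nm: float = 30.0
    tilt_max_deg: float = 5.0
    roughness_amp_nm: float = 2.0
    roughness_wavelength_vox: float = 130.0
    pixel_size_A: float = 15.2
    tomo_shape: tuple[int, int, int] = (512, 512, 386)  # (u, v, beam axis)
    grid_step_vox: float = 10.0
    annotation_interval: int = 100
    annotation_point_interval: int = 10
    b_bulk_A2: float = 300.0
    delta_b_A2: float = 1100.0
    decay_length_nm: float = 5.4
    resolution_noise_sd: float = 8e-4  # Gaussian, on the 1/res^2 scale
    intercept_y0: float = 0.0  # shared intercept of the generative lines
    backside_acq_min_um: float = 0.0
    backside_acq_max_um: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "thickness_mean_nm",
            "pixel_size_A",
            "grid_step_vox",
            "b_bulk_A2",
            "decay_length_nm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.thickness_sd_nm < 0 or self.roughness_amp_nm < 0:
            raise ValueError("spread parameters must be >= 0")


def bfactor_at_depth(depth_nm: float | np.ndarray, config: SyntheticConfig) -> np.ndarray:
    """Ground-truth B(d) of the exponential surface-damage model."""
    d = np.asarray(depth_nm, dtype=float)
    rel = config.delta_b_A2 / config.b_bulk_A2
    return config.b_bulk_A2 * (1.0 + rel * np.exp(-d / config.decay_length_nm))


def _vox_per_nm(config: SyntheticConfig) -> float:
    return 10.0 / config.pixel_size_A


def simulate_geometry(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[dict[str, tuple[SurfaceSheet, SurfaceSheet]], AnnotationSet]:
    """Per-tomogram surface sheet pairs plus sparse annotations of them.

    Each tomogram draws a thickness (redrawn while non-positive, hard
    error after 100 attempts), a tilt per lateral axis, and sinusoidal
    roughness phases. Annotations sample the true sheets every
    ``annotation_interval`` slices with points every
    ``annotation_point_interval`` voxels.
    """
    nu, nv, nz = config.tomo_shape
    vox = _vox_per_nm(config)
    step = config.grid_step_vox
    sheets: dict[str, tuple[SurfaceSheet, SurfaceSheet]] = {}
    ann: dict[tuple[str, str], list[tuple[int, np.ndarray]]] = {}
    u_grid = np.arange(0.0, nu - 1 + 0.5 * step, step)
    v_grid = np.arange(0.0, nv - 1 + 0.5 * step, step)
    ann_slices = list(range(0, nv, config.annotation_interval))
    ann_u = np.arange(0.0, nu - 1 + 0.5, config.annotation_point_interval, dtype=float)

    for t in range(config.n_tomograms):
        tomo = f"tomo_{t:04d}"
        thickness_nm = -1.0
        for attempt in range(100):
            thickness_nm = rng.normal(config.thickness_mean_nm, config.thickness_sd_nm)
            if thickness_nm > 0:
                break
        else:  # pragma: no cover - requires pathological config
            raise ValueError("could not draw a positive thickness in 100 attempts")
        half_vox = 0.5 * thickness_nm * vox
        z_mid = nz / 2.0
        slope_u = np.tan(np.deg2rad(rng.uniform(-config.tilt_max_deg, config.tilt_max_deg)))
        slope_v = np.tan(np.deg2rad(rng.uniform(-config.tilt_max_deg, config.tilt_max_deg)))
        amp_vox = config.roughness_amp_nm * vox
        phases = rng.uniform(0, 2 * np.pi, size=4)
        wl = config.roughness_wavelength_vox

        def height(u, v, sign, ph0, ph1):
            base = z_mid + sign * half_vox
            tiltz = slope_u * (np.asarray(u) - nu / 2.0) + slope_v * (np.asarray(v) - nv / 2.0)
            rough = amp_vox * np.sin(2 * np.pi * np.asarray(u) / wl + ph0) * np.cos(
                2 * np.pi * np.asarray(v) / wl + ph1
            )
            return base + tiltz + rough

        uu, vv = np.meshgrid(u_grid, v_grid, indexing="ij")
        front = SurfaceSheet(
            height(uu, vv, -1.0, phases[0], phases[1]), u0=0.0, v0=0.0, grid_step=step, role="front"
        )
        back = SurfaceSheet(
            height(uu, vv, +1.0, phases[2], phases[3]), u0=0.0, v0=0.0, grid_step=step, role="back"
        )
        sheets[tomo] = (front, back)
        for sheet_name, sign, p0, p1 in (
            ("front", -1.0, phases[0], phases[1]),
            ("back", +1.0, phases[2], phases[3]),
        ):
            entries = []
            for s in ann_slices:
                h = height(ann_u, float(s), sign, p0, p1)
                entries.append((s, np.column_stack([ann_u, h])))
            ann[(tomo, sheet_name)] = entries
    return sheets, AnnotationSet(ann, slice_spacing=config.annotation_interval)


def simulate_particles(
    config: SyntheticConfig,
    sheets: dict[str, tuple[SurfaceSheet, SurfaceSheet]],
    rng: np.random.Generator,
    margin_nm: float = 0.0,
) -> ParticleTable:
    """Particles uniform between the sheets, with stored true depths.

    True depth is the exact shortest distance to the nearer triangulated
    true sheet (the same geometric definition the pipeline later measures
    on interpolated annotations), stored as ``true_depth_nm`` so geometry
    recovery can be validated. ``margin_nm`` keeps particles away from the
    surfaces; a margin of half the local thickness leaves no volume.
    """
    if not sheets:
        raise ValueError("no sheets to place particles in")
    if config.particles_per_tomogram <= 0:
        raise ValueError("zero particle density")
    vox = _vox_per_nm(config)
    margin_vox = margin_nm * vox
    frames = []
    for tomo, (front, back) in sorted(sheets.items()):
        n = config.particles_per_tomogram
        u = rng.uniform(front.u0, front.u_max, size=n)
        v = rng.uniform(front.v0, front.v_max, size=n)
        hf = front.height_at(u, v) + margin_vox
        hb = back.height_at(u, v) - margin_vox
        if np.any(hb <= hf):
            bad = hb <= hf
            if bad.all():
                raise ValueError(f"margin {margin_nm} nm leaves no interior volume in {tomo}")
            u, v, hf, hb = u[~bad], v[~bad], hf[~bad], hb[~bad]
        z = rng.uniform(hf, hb)
        pts = np.column_stack([u, v, z])
        d = np.minimum(front.nearest_distance(pts), back.nearest_distance(pts)) / vox
        frames.append(
            pd.DataFrame(
                {
                    "particle_id": [f"{tomo}_p{i:05d}" for i in range(len(u))],
                    "tomogram_id": tomo,
                    "x": u,
                    "y": v,
                    "z": z,
                    "true_depth_nm": d,
                    "true_thickness_nm": (back.height_at(u, v) - front.height_at(u, v)) / vox,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    return ParticleTable(df, config.pixel_size_A)


def simulate_resolution_series(
    depth_nm: float,
    sizes: list[int],
    config: SyntheticConfig,
    rng: np.random.Generator,
    repeats: int = 3,
    group: str = "",
) -> pd.DataFrame:
    """Resolution series drawn from the generative Rosenthal-Henderson model.

    y = (2 / B(d)) ln(n) + y0 + eps with eps ~ N(0, resolution_noise_sd);
    resolutions are 1/sqrt(y). Draws with y <= 0 are redrawn (error after
    100 attempts)."""
    B = float(bfactor_at_depth(depth_nm, config))
    rows = []
    for rep in range(1, repeats + 1):
        for n in sizes:
            y0 = (2.0 / B) * np.log(n) + config.intercept_y0
            y = -1.0
            for _ in range(100):
                y = y0 + rng.normal(0.0, config.resolution_noise_sd)
                if y > 0:
                    break
            else:
                raise ValueError(f"could not draw positive 1/res^2 at n={n}, B={B:.0f}")
            rows.append((group, rep, n, 1.0 / np.sqrt(y)))
    return pd.DataFrame(rows, columns=["group", "repeat", "n_particles", "resolution_A"])


class SyntheticRefiner:
    """Stand-in for subset refinement: resolution of any particle subset.

    The effective B of a subset is the mean ground-truth B(d) over its
    members, fed through the generative line with Gaussian noise on the
    1/res^2 scale. This emulates what an actual refinement of that subset
    would report, without image data.
    """

    def __init__(self, config: SyntheticConfig, true_depth_by_id: pd.Series):
        self.config = config
        self.depths = true_depth_by_id
        self._index = pd.Index(true_depth_by_id.index)
        self._b_of_d = bfactor_at_depth(true_depth_by_id.to_numpy(dtype=float), config)

    def subset_resolution(self, member_ids: np.ndarray, rng: np.random.Generator) -> float:
        pos = self._index.get_indexer(member_ids)
        if np.any(pos < 0):
            raise KeyError("subset contains particle ids unknown to the refiner")
        B = float(np.mean(self._b_of_d[pos]))
        y0 = (2.0 / B) * np.log(len(member_ids)) + self.config.intercept_y0
        for _ in range(100):
            y = y0 + rng.normal(0.0, self.config.resolution_noise_sd)
            if y > 0:
                return float(1.0 / np.sqrt(y))
        raise ValueError("could not draw positive 1/res^2 for subset")


def simulate_half_maps(
    target_crossover_frequency: float,
    size: int,
    voxel_size_A: float,
    seed: int,
    noise: bool = True,
) -> tuple[VolumeGrid, VolumeGrid]:
    """Half-map pair whose expected FSC crosses 0.143 at a target frequency.

    A shared Gaussian random signal plus independent per-half noise, with
    per-shell noise variance set so the expected FSC = SSNR/(SSNR+1)
    follows 0.143**((f/f_x)^4), equal to 0.143 at f_x =
    ``target_crossover_frequency`` (1/A). With ``noise=False`` the halves
    are identical and the FSC is 1 everywhere.
    """
    nyq = 0.5 / voxel_size_A
    if target_crossover_frequency >= nyq:
        raise ValueError(
            f"crossover {target_crossover_frequency:.4f} 1/A is at or beyond Nyquist {nyq:.4f}"
        )
    rng = np.random.default_rng(seed)
    shape = (size, size, size)
    freqs = np.fft.fftfreq(size, d=voxel_size_A)
    radius = np.sqrt(
        freqs[:, None, None] ** 2 + freqs[None, :, None] ** 2 + freqs[None, None, :] ** 2
    )
    signal = np.fft.fftn(rng.standard_normal(shape))
    if not noise:
        vol = np.real(np.fft.ifftn(signal)).astype(np.float32)
        return (VolumeGrid(vol, voxel_size_A), VolumeGrid(vol.copy(), voxel_size_A))
    with np.errstate(divide="ignore"):
        fsc_target = 0.143 ** ((radius / target_crossover_frequency) ** 4)
    fsc_target = np.clip(fsc_target, 1e-6, 1.0 - 1e-9)
    noise_scale = np.sqrt((1.0 - fsc_target) / fsc_target)  # sigma_noise / sigma_signal
    halves = []
    for _ in range(2):
        noise_f = np.fft.fftn(rng.standard_normal(shape)) * noise_scale
        halves.append(np.real(np.fft.ifftn(signal + noise_f)).astype(np.float32))
    return VolumeGrid(halves[0], voxel_size_A), VolumeGrid(halves[1], voxel_size_A)


def build_fixture_bundle(config: SyntheticConfig, out_dir: str | os.PathLike) -> Path:
    """Write a self-contained input set for the full pipeline.

    Emits ``particles.star`` (positions only), ``annotations.csv``,
    ``tomograms.csv`` (acquisition distances to the backside boundary),
    ``truth/particles_truth.csv`` (per-particle true depths) and
    ``truth/ground_truth.json`` (the damage-model parameters). On a
    partial write the directory's fresh files are removed and the error
    re-raised.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    written: list[Path] = []
    rng = np.random.default_rng(config.seed)
    try:
        sheets, annotations = simulate_geometry(config, rng)
        table = simulate_particles(config, sheets, rng)
        tomo_ids = sorted(sheets)
        acq = rng.uniform(
            config.backside_acq_min_um, config.backside_acq_max_um, size=len(tomo_ids)
        )

        public = ParticleTable(
            table.df[["particle_id", "tomogram_id", "x", "y", "z"]].copy(),
            config.pixel_size_A,
        )
        p = out / "particles.star"
        write_particle_star(public, p)
        written.append(p)
        p = out / "annotations.csv"
        write_annotations(annotations, p)
        written.append(p)
        p = out / "tomograms.csv"
        pd.DataFrame({"tomogram_id": tomo_ids, "acquisition_distance_um": acq}).to_csv(
            p, index=False
        )
        written.append(p)
        p = out / "truth" / "particles_truth.csv"
        table.df[["particle_id", "true_depth_nm", "true_thickness_nm"]].to_csv(p, index=False)
        written.append(p)
        truth = {
            "config": dataclasses.asdict(config),
            "b_bulk_A2": config.b_bulk_A2,
            "delta_b_A2": config.delta_b_A2,
            "decay_length_nm": config.decay_length_nm,
            "decay_rate_per_nm": 1.0 / config.decay_length_nm,
            "seed": config.seed,
        }
        p = out / "truth" / "ground_truth.json"
        with open(p, "w") as fh:
            json.dump(truth, fh, indent=2)
        written.append(p)
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise
    return out
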
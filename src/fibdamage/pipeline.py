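"""End-to-end orchestration of the depth and backside damage profiles.

A run takes a particle table plus surface annotations (or a synthetic
fixture bundle), builds depth cohorts and tomogram-matched controls,
obtains a resolution series for every cohort — either from a precomputed
CSV (real data, where subset refinement happens in external software) or
from the synthetic refiner bundled with a fixture — fits per-cohort
B-factors, and summarizes damage as ratio and extrapolated-resolution
curves with weighted exponential-decay fits.

Reports are plain CSV/JSON; every random choice derives from the run
seed, so identical inputs and config give byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bfactor as bf
from . import cohorts as ch
from . import damage_curves as dc
from .io_formats import read_annotations, read_particle_star
from .surface_geometry import (
    SurfaceSheet,
    particle_depths,
    sheets_from_annotations,
    thickness_summary,
)
from .synthetic import SyntheticConfig, SyntheticRefiner

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "validate_config",
    "run_depth_profile",
    "run_backside_profile",
    "run_depth_profile_from_bundle",
    "run_backside_profile_from_bundle",
    "DepthProfileReport",
    "BacksideProfileReport",
]


@dataclass
class RunConfig:
    """Fixed constants of the damage analysis, with the study's defaults."""

    depth_bin_width_nm: float = 5.0
    depth_max_nm: float = 60.0
    backside_bin_width_um: float = 1.0
    backside_max_um: float = 5.0
    min_particles: int = 400
    repeats: int = 3
    extrapolation_n: int = 5000
    threshold_nm: float = 30.0
    threshold_set_n: int = 10000
    eligibility_floor_nm: float | None = None
    grid_step_vox: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth_max_nm % self.depth_bin_width_nm:
            raise ValueError(
                f"depth bin width {self.depth_bin_width_nm} does not divide "
                f"max depth {self.depth_max_nm}"
            )
        if self.backside_max_um % self.backside_bin_width_um:
            raise ValueError(
                f"backside bin width {self.backside_bin_width_um} does not divide "
                f"max distance {self.backside_max_um}"
            )
        for name in ("min_particles", "repeats", "extrapolation_n", "threshold_set_n"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


_CONFIG_KEYS = {f.name for f in dataclasses.fields(RunConfig)}


def validate_config(source: str | os.PathLike | dict | None) -> RunConfig:
    """Normalize a YAML file or mapping into a :class:`RunConfig`.

    Empty input yields all defaults; unknown keys raise an error naming
    the valid ones. Idempotent: normalizing a normalized config is a
    no-op."""
    if source is None:
        data: dict = {}
    elif isinstance(source, RunConfig):
        return source
    elif isinstance(source, dict):
        data = dict(source)
    else:
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config {source} must be a mapping")
    unknown = set(data) - _CONFIG_KEYS
    if unknown:
        raise ValueError(
            f"unknown config keys {sorted(unknown)}; valid keys: {sorted(_CONFIG_KEYS)}"
        )
    return RunConfig(**data)


# ---------------------------------------------------------------------------
# resolution providers
# ---------------------------------------------------------------------------

class PrecomputedSeries:
    """Resolution series read from CSV, keyed by cohort label.

    Used on real data, where the per-subset resolutions come from external
    refinement software. Control series use the label ``<group>_control``.
    """

    def __init__(self, series: pd.DataFrame):
        bf.validate_series(series, min_particles=1)
        self.series = series

    def group_series(self, label: str) -> pd.DataFrame:
        sub = self.series[self.series["group"] == label]
        if len(sub) == 0:
            raise KeyError(f"no resolution series for group {label!r}")
        return sub


def _series_from_refiner(
    refiner: SyntheticRefiner,
    member_ids: np.ndarray,
    sizes: list[int],
    repeats: int,
    rng: np.random.Generator,
    label: str,
) -> pd.DataFrame:
    """Independent seeded redraws of every subset, ``repeats`` times over."""
    rows = []
    for rep in range(1, repeats + 1):
        for n in sizes:
            ids = rng.choice(member_ids, size=n, replace=False)
            rows.append((label, rep, n, refiner.subset_resolution(ids, rng)))
    return pd.DataFrame(rows, columns=["group", "repeat", "n_particles", "resolution_A"])


# ---------------------------------------------------------------------------
# depth profile
# ---------------------------------------------------------------------------

@dataclass
class DepthProfileReport:
    bfactor_table: pd.DataFrame
    ratio_points: list[dc.DepthPoint]
    dres_points: list[dc.DepthPoint]
    ratio_fit: dc.DecayFit | None
    dres_fit: dc.DecayFit | None
    thickness: dict
    threshold_bfactors: pd.DataFrame | None
    series: pd.DataFrame
    excluded_groups: list[str] = field(default_factory=list)
    seed: int = 0

    def write(self, out_dir: str | os.PathLike, plots: bool = False) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.bfactor_table.to_csv(out / "bfactors_depth.csv", index=False)
        self.series.to_csv(out / "resolution_series.csv", index=False)
        points = pd.DataFrame(
            [
                (p.label, p.x_nm, p.value, p.se, kind)
                for kind, pts in (("ratio", self.ratio_points), ("dres", self.dres_points))
                for p in pts
            ],
            columns=["bin", "x_mid_nm", "value", "se", "kind"],
        )
        points.to_csv(out / "damage_curves.csv", index=False)
        fits = {}
        for name, fit in (("ratio", self.ratio_fit), ("dres", self.dres_fit)):
            if fit is not None:
                fits[name] = dataclasses.asdict(fit)
        if self.threshold_bfactors is not None:
            self.threshold_bfactors.to_csv(out / "threshold_sets.csv", index=False)
        with open(out / "depth_profile.json", "w") as fh:
            json.dump(
                {
                    "decay_fits": fits,
                    "thickness": self.thickness,
                    "excluded_groups": self.excluded_groups,
                    "seed": self.seed,
                },
                fh,
                indent=2,
            )
        if plots:
            from .plots import plot_bfactor_series, plot_damage_curve

            plot_damage_curve(
                self.ratio_points, self.ratio_fit, out / "bfactor_ratio.png",
                ylabel="B-factor ratio (group / control)",
            )
            plot_damage_curve(
                self.dres_points, self.dres_fit, out / "resolution_difference.png",
                ylabel=r"$\Delta$ extrapolated resolution ($\mathrm{\AA}$)",
            )
            if len(self.series):
                plot_bfactor_series(self.series, out / "bfactor_series.png")


def run_depth_profile(
    particles: pd.DataFrame,
    config: RunConfig,
    refiner: SyntheticRefiner | None = None,
    series_provider: PrecomputedSeries | None = None,
) -> DepthProfileReport:
    """Depth cohorts, matched controls, per-cohort B-factors, damage curves.

    ``particles`` must carry ``depth_nm`` (and ideally ``thickness_nm`` /
    ``inside``) columns. Exactly one resolution source must be given.
    """
    if (refiner is None) == (series_provider is None):
        raise ValueError("pass exactly one of refiner or series_provider")
    rng = np.random.default_rng(config.seed)

    cohorts = ch.assign_depth_bins(particles, config.depth_bin_width_nm, config.depth_max_nm)
    rows = []
    all_series = []
    ratio_points: list[dc.DepthPoint] = []
    dres_points: list[dc.DepthPoint] = []
    excluded: list[str] = []
    for group in cohorts:
        if len(group) < config.min_particles:
            excluded.append(group.label)
            logger.info(
                "group %s excluded: %d particles < minimum %d",
                group.label,
                len(group),
                config.min_particles,
            )
            continue
        control_seed = int(rng.integers(2**31))
        control, group_eq = ch.draw_matched_control(
            group, particles, config.eligibility_floor_nm, seed=control_seed
        )
        if len(group_eq) < config.min_particles:
            excluded.append(group.label)
            logger.info("group %s excluded after control equalization", group.label)
            continue
        try:
            if series_provider is not None:
                series_g = series_provider.group_series(group.label)
                series_c = series_provider.group_series(f"{group.label}_control")
            else:
                sizes = bf.subset_series(len(group_eq), config.min_particles)
                if len(sizes) < 2:
                    excluded.append(group.label)
                    logger.info(
                        "group %s excluded: halving series from %d particles has a "
                        "single subset size",
                        group.label,
                        len(group_eq),
                    )
                    continue
                series_g = _series_from_refiner(
                    refiner, group_eq.member_ids, sizes, config.repeats, rng, group.label
                )
                series_c = _series_from_refiner(
                    refiner,
                    control.member_ids,
                    sizes,
                    config.repeats,
                    rng,
                    f"{group.label}_control",
                )
            res_g = bf.fit_group(series_g, group.label)
            res_c = bf.fit_group(series_c, f"{group.label}_control")
        except (ValueError, KeyError) as exc:
            raise RuntimeError(f"B-factor stage failed for group {group.label}: {exc}") from exc
        all_series.extend([series_g, series_c])
        rows.append(
            {
                "group": group.label,
                "n_particles": len(group_eq),
                "B": res_g.B,
                "sigma_B": res_g.sigma_B,
                "B_control": res_c.B,
                "sigma_B_control": res_c.sigma_B,
                "control_seed": control_seed,
            }
        )
        mid = group.midpoint
        ratio, s_ratio = dc.bfactor_ratio(res_g.B, res_g.sigma_B, res_c.B, res_c.sigma_B)
        ratio_points.append(dc.DepthPoint(group.label, mid, ratio, s_ratio))
        rg, sg = dc.extrapolate_resolution(res_g.fit, config.extrapolation_n)
        rc, sc = dc.extrapolate_resolution(res_c.fit, config.extrapolation_n)
        d, sd = dc.resolution_difference(rg, sg, rc, sc)
        dres_points.append(dc.DepthPoint(group.label, mid, d, sd))

    ratio_fit = dres_fit = None
    if len(ratio_points) >= 4:
        ratio_fit = dc.fit_exponential_decay(ratio_points)
        dres_fit = dc.fit_exponential_decay(dres_points)

    threshold_table = None
    try:
        sets = ch.split_threshold_sets(
            particles,
            config.threshold_nm,
            config.threshold_set_n,
            seed=int(rng.integers(2**31)),
        )
        if refiner is not None:
            trows = []
            sizes = bf.subset_series(config.threshold_set_n, config.min_particles)
            for label, cohort in sets.items():
                s = _series_from_refiner(
                    refiner, cohort.member_ids, sizes, config.repeats, rng, label
                )
                r = bf.fit_group(s, label)
                trows.append({"group": label, "B": r.B, "sigma_B": r.sigma_B})
            threshold_table = pd.DataFrame(trows)
    except ValueError as exc:
        logger.info("threshold sets skipped: %s", exc)

    thick = (
        thickness_summary(particles)
        if "thickness_nm" in particles.columns and particles["thickness_nm"].notna().any()
        else {}
    )
    return DepthProfileReport(
        bfactor_table=pd.DataFrame(rows),
        ratio_points=ratio_points,
        dres_points=dres_points,
        ratio_fit=ratio_fit,
        dres_fit=dres_fit,
        thickness=thick,
        threshold_bfactors=threshold_table,
        series=pd.concat(all_series, ignore_index=True) if all_series else pd.DataFrame(),
        excluded_groups=excluded,
        seed=config.seed,
    )


# ---------------------------------------------------------------------------
# backside profile
# ---------------------------------------------------------------------------

@dataclass
class BacksideProfileReport:
    bfactor_table: pd.DataFrame
    summary: dict
    series: pd.DataFrame
    seed: int = 0

    def write(self, out_dir: str | os.PathLike) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.bfactor_table.to_csv(out / "bfactors_backside.csv", index=False)
        self.series.to_csv(out / "resolution_series_backside.csv", index=False)
        with open(out / "backside_profile.json", "w") as fh:
            json.dump({"summary": self.summary, "seed": self.seed}, fh, indent=2)


def run_backside_profile(
    particles: pd.DataFrame,
    config: RunConfig,
    refiner: SyntheticRefiner | None = None,
    series_provider: PrecomputedSeries | None = None,
) -> BacksideProfileReport:
    """1-um backside bins, per-bin B-factors, extremes and Spearman trend.

    ``particles`` must carry a ``backside_um`` column (per-particle
    distance to the amorphous boundary)."""
    if (refiner is None) == (series_provider is None):
        raise ValueError("pass exactly one of refiner or series_provider")
    rng = np.random.default_rng(config.seed)
    bins = ch.assign_backside_bins(
        particles, config.backside_bin_width_um, config.backside_max_um
    )
    results = []
    rows = []
    all_series = []
    for cohort in bins:
        if len(cohort) < config.min_particles:
            logger.info("backside bin %s skipped: %d particles", cohort.label, len(cohort))
            continue
        if series_provider is not None:
            series = series_provider.group_series(cohort.label)
        else:
            sizes = bf.subset_series(len(cohort), config.min_particles)
            if len(sizes) < 2:
                logger.info("backside bin %s skipped: single subset size", cohort.label)
                continue
            series = _series_from_refiner(
                refiner, cohort.member_ids, sizes, config.repeats, rng, cohort.label
            )
        res = bf.fit_group(series, cohort.label)
        results.append(res)
        all_series.append(series)
        rows.append(
            {"group": cohort.label, "n_particles": len(cohort), "B": res.B, "sigma_B": res.sigma_B}
        )
    if not rows:
        raise ValueError("no backside bin had enough particles")
    summary = dc.backside_group_summary(results) if len(results) >= 2 else {}
    return BacksideProfileReport(
        bfactor_table=pd.DataFrame(rows),
        summary=summary,
        series=pd.concat(all_series, ignore_index=True) if all_series else pd.DataFrame(),
        seed=config.seed,
    )


# ---------------------------------------------------------------------------
# bundle-driven entry points
# ---------------------------------------------------------------------------

def _load_bundle(bundle_dir: str | os.PathLike, config: RunConfig):
    bundle = Path(bundle_dir)
    star = bundle / "particles.star"
    ann_path = bundle / "annotations.csv"
    for path in (star, ann_path):
        if not path.exists():
            raise FileNotFoundError(f"bundle input missing: {path}")
    with open(bundle / "truth" / "ground_truth.json") as fh:
        truth = json.load(fh)
    syn_cfg = SyntheticConfig(
        **{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in truth["config"].items()
        }
    )
    table = read_particle_star(star)
    annotations = read_annotations(ann_path, slice_spacing=syn_cfg.annotation_interval)
    bounds = {
        tomo: (
            float(sub["x"].min()),
            float(sub["x"].max()),
            float(sub["y"].min()),
            float(sub["y"].max()),
        )
        for tomo, sub in table.df.groupby("tomogram_id")
    }
    sheets: dict[str, tuple[SurfaceSheet, SurfaceSheet]] = sheets_from_annotations(
        annotations, config.grid_step_vox, bounds
    )
    measured = particle_depths(table, sheets)
    truth_df = pd.read_csv(bundle / "truth" / "particles_truth.csv")
    depths_by_id = truth_df.set_index("particle_id")["true_depth_nm"]
    refiner = SyntheticRefiner(syn_cfg, depths_by_id)
    return measured, refiner, syn_cfg, bundle


def run_depth_profile_from_bundle(
    bundle_dir: str | os.PathLike, config: RunConfig | None = None
) -> DepthProfileReport:
    """Full depth profile on a synthetic fixture bundle.

    Depths are measured from the bundle's annotations (not its ground
    truth); only the resolution oracle uses the true damage model, playing
    the role refinement software plays on real data."""
    config = validate_config(config)
    measured, refiner, _, _ = _load_bundle(bundle_dir, config)
    return run_depth_profile(measured, config, refiner=refiner)


def run_backside_profile_from_bundle(
    bundle_dir: str | os.PathLike, config: RunConfig | None = None
) -> BacksideProfileReport:
    """Backside profile on a synthetic fixture bundle."""
    config = validate_config(config)
    measured, refiner, syn_cfg, bundle = _load_bundle(bundle_dir, config)
    tomo_df = pd.read_csv(bundle / "tomograms.csv").set_index("tomogram_id")
    center = (syn_cfg.tomo_shape[0] - 1) / 2.0
    offset_um = (measured["x"] - center) * syn_cfg.pixel_size_A * 1e-4
    acq = measured["tomogram_id"].map(tomo_df["acquisition_distance_um"]).to_numpy()
    measured = measured.copy()
    measured["backside_um"] = ch.backside_particle_distance(acq, offset_um.to_numpy())
    return run_backside_profile(measured, config, refiner=refiner)
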
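"""Depth/backside cohorts, tomogram-matched controls, and threshold sets.

Particles are grouped by distance to the nearest milling surface in
half-open 5-nm bins up to 60 nm (depth cohorts), or by distance to the
backside amorphous boundary in half-open 1-um bins up to 5 um. For every
depth cohort a matched control is drawn: the same number of particles per
tomogram, randomly selected from the same tomograms but farther from the
milling surfaces, which controls for per-tomogram confounders (local
thickness, tilt-series alignment quality, motion). All draws are
reproducible from a seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CohortAssignment",
    "MatchedControl",
    "assign_depth_bins",
    "assign_backside_bins",
    "backside_particle_distance",
    "draw_matched_control",
    "split_threshold_sets",
]

DEFAULT_ELIGIBILITY_FLOOR_NM = 60.0


@dataclass
class CohortAssignment:
    """One particle group: label, members, per-tomogram counts, bin edges."""

    label: str
    member_ids: np.ndarray
    per_tomogram: dict[str, int]
    bin_edges: tuple[float, float] | None = None
    units: str = "nm"
    seed: int | None = None

    def __post_init__(self) -> None:
        self.member_ids = np.asarray(self.member_ids)
        if sum(self.per_tomogram.values()) != len(self.member_ids):
            raise ValueError(
                f"{self.label}: per-tomogram counts sum to "
                f"{sum(self.per_tomogram.values())}, expected {len(self.member_ids)}"
            )

    def __len__(self) -> int:
        return len(self.member_ids)

    @property
    def midpoint(self) -> float:
        if self.bin_edges is None:
            raise ValueError(f"{self.label} has no bin edges")
        return 0.5 * (self.bin_edges[0] + self.bin_edges[1])


@dataclass
class MatchedControl:
    """Control particle set matched per-tomogram to a source cohort."""

    source_label: str
    member_ids: np.ndarray
    per_tomogram: dict[str, int]
    eligibility_floor_nm: float
    seed: int
    relaxed_tomograms: list[str] = field(default_factory=list)
    dropped_tomograms: list[str] = field(default_factory=list)


def _per_tomogram_counts(df: pd.DataFrame) -> dict[str, int]:
    return df.groupby("tomogram_id").size().to_dict()


def assign_depth_bins(
    particles: pd.DataFrame,
    bin_width_nm: float = 5.0,
    max_depth_nm: float = 60.0,
) -> list[CohortAssignment]:
    """Assign particles to half-open depth bins [lower, upper) in nm.

    Particles with missing depth, depth >= ``max_depth_nm``, or flagged as
    outside the lamella slab are excluded from the bins (they remain
    available as the matched-control pool). Raises if every bin is empty.
    """
    if "depth_nm" not in particles.columns:
        raise ValueError("particles need a depth_nm column")
    if max_depth_nm % bin_width_nm:
        raise ValueError(f"bin width {bin_width_nm} does not divide max depth {max_depth_nm}")
    eligible = particles.dropna(subset=["depth_nm"])
    if "inside" in eligible.columns:
        eligible = eligible[eligible["inside"]]
    edges = np.arange(0.0, max_depth_nm + 0.5 * bin_width_nm, bin_width_nm)
    cohorts = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        members = eligible[(eligible["depth_nm"] >= lo) & (eligible["depth_nm"] < hi)]
        label = f"depth_{int(lo):02d}_{int(hi):02d}"
        cohorts.append(
            CohortAssignment(
                label=label,
                member_ids=members["particle_id"].to_numpy(),
                per_tomogram=_per_tomogram_counts(members),
                bin_edges=(float(lo), float(hi)),
                units="nm",
            )
        )
    if all(len(c) == 0 for c in cohorts):
        raise ValueError("no particle falls in any depth bin")
    return cohorts


def backside_particle_distance(
    acquisition_distance_um: float | np.ndarray,
    particle_x_offset_um: float | np.ndarray,
) -> np.ndarray:
    """Per-particle distance to the backside amorphous boundary.

    The tilt-series acquisition area's distance to the boundary, corrected
    by the particle's signed displacement from the tomogram centre along
    the milling (x) axis. Negative results are returned as NaN (flagged,
    excluded from bins downstream).
    """
    acq = np.asarray(acquisition_distance_um, dtype=float)
    if np.any(acq < 0):
        raise ValueError("acquisition distance must be >= 0")
    d = acq + np.asarray(particle_x_offset_um, dtype=float)
    n_neg = int(np.sum(d < 0))
    if n_neg:
        logger.warning("%d particles with negative backside distance flagged", n_neg)
    return np.where(d < 0, np.nan, d)


def assign_backside_bins(
    particles: pd.DataFrame,
    bin_width_um: float = 1.0,
    max_distance_um: float = 5.0,
) -> list[CohortAssignment]:
    """Half-open 1-um backside-distance bins (``backside_um`` column)."""
    if "backside_um" not in particles.columns:
        raise ValueError("particles need a backside_um column")
    if max_distance_um % bin_width_um:
        raise ValueError(
            f"bin width {bin_width_um} does not divide max distance {max_distance_um}"
        )
    eligible = particles.dropna(subset=["backside_um"])
    edges = np.arange(0.0, max_distance_um + 0.5 * bin_width_um, bin_width_um)
    cohorts = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        members = eligible[(eligible["backside_um"] >= lo) & (eligible["backside_um"] < hi)]
        cohorts.append(
            CohortAssignment(
                label=f"backside_{int(lo)}_{int(hi)}um",
                member_ids=members["particle_id"].to_numpy(),
                per_tomogram=_per_tomogram_counts(members),
                bin_edges=(float(lo), float(hi)),
                units="um",
            )
        )
    if all(len(c) == 0 for c in cohorts):
        raise ValueError("no particle falls in any backside bin")
    return cohorts


def draw_matched_control(
    group: CohortAssignment,
    particles: pd.DataFrame,
    eligibility_floor_nm: float | None = None,
    seed: int = 0,
) -> tuple[MatchedControl, CohortAssignment]:
    """Draw a tomogram-matched control for a depth cohort.

    For each tomogram the control takes, without replacement, as many
    particles as the group has there, from particles with depth strictly
    greater than the eligibility floor (default: the larger of the group's
    upper bin edge and 60 nm, so controls lie beyond the deepest studied
    damage bin). Where the eligible pool is short the control takes all it
    can and the group is randomly downsampled to the same count, so group
    and control stay equal per tomogram. If the floor empties a tomogram's
    pool entirely, the floor is relaxed to the group's upper edge for that
    tomogram (logged); if still empty, that tomogram's group particles are
    dropped (logged).
    """
    if eligibility_floor_nm is None:
        upper = group.bin_edges[1] if group.bin_edges else 0.0
        eligibility_floor_nm = max(upper, DEFAULT_ELIGIBILITY_FLOOR_NM)
    rng = np.random.default_rng(seed)
    group_ids = set(group.member_ids.tolist())
    pool = particles.dropna(subset=["depth_nm"])
    pool = pool[~pool["particle_id"].isin(group_ids)]
    if "inside" in pool.columns:
        pool = pool[pool["inside"]]

    control_ids: list[np.ndarray] = []
    kept_group_ids: list[np.ndarray] = []
    control_counts: dict[str, int] = {}
    kept_counts: dict[str, int] = {}
    relaxed, dropped = [], []
    group_members = particles[particles["particle_id"].isin(group_ids)]
    pool_by_tomo = {
        tomo: (sub["particle_id"].to_numpy(), sub["depth_nm"].to_numpy(dtype=float))
        for tomo, sub in pool.groupby("tomogram_id", sort=False)
    }
    empty = (np.array([], dtype=object), np.array([], dtype=float))
    for tomo, sub in group_members.groupby("tomogram_id", sort=True):
        want = len(sub)
        pool_ids, pool_depths = pool_by_tomo.get(tomo, empty)
        eligible = pool_ids[pool_depths > eligibility_floor_nm]
        if len(eligible) == 0 and group.bin_edges is not None:
            relaxed_floor = group.bin_edges[1]
            eligible = pool_ids[pool_depths > relaxed_floor]
            if len(eligible) > 0:
                relaxed.append(tomo)
                logger.warning(
                    "tomogram %s: eligibility floor relaxed to %.1f nm for matched control",
                    tomo,
                    relaxed_floor,
                )
        if len(eligible) == 0:
            dropped.append(tomo)
            logger.warning(
                "tomogram %s: no eligible control particles; %d group particles dropped",
                tomo,
                want,
            )
            continue
        take = min(want, len(eligible))
        chosen = rng.choice(eligible, size=take, replace=False)
        control_ids.append(chosen)
        control_counts[tomo] = take
        ids = sub["particle_id"].to_numpy()
        if take < want:
            ids = rng.choice(ids, size=take, replace=False)
        kept_group_ids.append(ids)
        kept_counts[tomo] = take

    control = MatchedControl(
        source_label=group.label,
        member_ids=np.concatenate(control_ids) if control_ids else np.array([], dtype=object),
        per_tomogram=control_counts,
        eligibility_floor_nm=float(eligibility_floor_nm),
        seed=seed,
        relaxed_tomograms=relaxed,
        dropped_tomograms=dropped,
    )
    equalized = CohortAssignment(
        label=group.label,
        member_ids=np.concatenate(kept_group_ids) if kept_group_ids else np.array([], dtype=object),
        per_tomogram=kept_counts,
        bin_edges=group.bin_edges,
        units=group.units,
        seed=seed,
    )
    return control, equalized


def split_threshold_sets(
    particles: pd.DataFrame,
    threshold_nm: float = 30.0,
    n: int = 10000,
    seed: int = 0,
) -> dict[str, CohortAssignment]:
    """Three seeded uniform samples of exactly ``n`` particles each:
    from all particles, from those shallower than the threshold, and from
    those at or beyond it."""
    if "depth_nm" not in particles.columns:
        raise ValueError("particles need a depth_nm column")
    valid = particles.dropna(subset=["depth_nm"])
    if "inside" in valid.columns:
        valid = valid[valid["inside"]]
    strata = {
        "all": valid,
        "lt_threshold": valid[valid["depth_nm"] < threshold_nm],
        "gt_threshold": valid[valid["depth_nm"] >= threshold_nm],
    }
    rng = np.random.default_rng(seed)
    out = {}
    for label, sub in strata.items():
        if len(sub) < n:
            raise ValueError(
                f"stratum {label!r} has only {len(sub)} particles, need {n}"
            )
        chosen = rng.choice(sub["particle_id"].to_numpy(), size=n, replace=False)
        members = sub[sub["particle_id"].isin(set(chosen.tolist()))]
        out[label] = CohortAssignment(
            label=label,
            member_ids=chosen,
            per_tomogram=_per_tomogram_counts(members),
            bin_edges=None,
            units="nm",
            seed=seed,
        )
    return out
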
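"""Published reference tables for xenon PFIB lamella damage, as worked examples.

These are the printed per-cohort B-factor tables from a xenon plasma
FIB-milling study of the *E. coli* 70S ribosome (subtomogram averaging on
high-pressure frozen lamellae). They serve as deterministic inputs: the raw
particle data behind them are not needed to exercise the downstream
arithmetic (extrapolation, ratio curves, decay fits, rank trends).

Backside table: ribosomes grouped by distance to the backside amorphous
boundary in 1-um bins. Surface-depth table: ribosomes grouped by distance
to the milling surfaces in 5-nm bins with tomogram-matched controls; the
0-5 nm pair carries no B-factor (too few particles, n = 25).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .bfactor import LinearFit
from .damage_curves import (
    DecayFit,
    DepthPoint,
    bfactor_ratio,
    extrapolate_resolution,
    fit_exponential_decay,
    resolution_difference,
)

__all__ = [
    "backside_table",
    "surface_depth_table",
    "amorphous_region_summaries",
    "row_to_linear_fit",
    "reconstruct_depth_curves",
]

ACQUISITION_PIXEL_SIZE_A = 1.90  # calibrated detector sampling of the study
TOMOGRAM_PIXEL_SIZE_A = 15.2  # tomogram sampling at binning 8

# Backside bins: label, n particles, n tomograms, mean thickness +- SD (nm),
# B +- SE (A^2), global resolution (A, one of three repeats)
_BACKSIDE_ROWS = [
    ("backside_0_1um", 5702, 18, 213, 29, 321, 21, 6.8),
    ("backside_1_2um", 8655, 26, 214, 28, 284, 13, 6.2),
    ("backside_2_3um", 6941, 21, 216, 27, 321, 11, 6.8),
    ("backside_3_4um", 7623, 26, 205, 30, 311, 13, 6.6),
    ("backside_4_5um", 7146, 25, 195, 25, 299, 17, 6.8),
]

# Surface-depth bins and matched controls. The 0-5 nm pair (n = 25) has no
# B-factor and is excluded from curve reconstruction.
_DEPTH_ROWS = [
    # label, n, n_tomo, thick, thick_sd, B, B_se, res, B_ctl, B_ctl_se, res_ctl
    ("depth_05_10", 1243, 152, 188, 30, 1390, 160, 15.8, 417, 30, 9.7),
    ("depth_10_15", 2967, 162, 186, 29, 504, 33, 9.9, 320, 19, 7.6),
    ("depth_15_20", 4143, 161, 189, 30, 434, 20, 8.2, 311, 15, 7.1),
    ("depth_20_25", 4795, 163, 191, 30, 340, 16, 7.2, 307, 10, 6.9),
    ("depth_25_30", 4946, 162, 192, 31, 334, 14, 7.2, 299, 17, 6.7),
    ("depth_30_35", 5119, 162, 192, 31, 317, 16, 7.0, 293, 19, 6.7),
    ("depth_35_40", 5048, 161, 192, 31, 312, 12, 7.1, 308, 14, 6.9),
    ("depth_40_45", 5163, 162, 192, 32, 297, 16, 6.9, 307, 14, 6.8),
    ("depth_45_50", 5076, 163, 193, 32, 305, 13, 6.8, 318, 15, 7.2),
    ("depth_50_55", 5170, 161, 191, 31, 309, 18, 6.8, 291, 12, 6.8),
    ("depth_55_60", 5235, 162, 194, 30, 305, 16, 6.8, 315, 16, 6.8),
]

# Threshold sets (10,000 particles each): all / <30 nm / >30 nm
THRESHOLD_SET_ROWS = [
    ("all", 10000, 163, 218, 17, 5.8),
    ("lt_threshold", 10000, 163, 276, 14, 6.7),
    ("gt_threshold", 10000, 163, 188, 10, 5.5),
]

# Amorphous backside region lengths (um): overall, and trench-current groups
AMORPHOUS_OVERALL = (0.72, 0.22, 15)  # mean, SD, n
AMORPHOUS_4NA = (0.5, 0.07, 5)
AMORPHOUS_60NA = (0.79, 0.18, 21)


def backside_table() -> pd.DataFrame:
    """Backside 1-um bin B-factors (reference measurements)."""
    return pd.DataFrame(
        _BACKSIDE_ROWS,
        columns=[
            "group",
            "n_particles",
            "n_tomograms",
            "thickness_nm",
            "thickness_sd_nm",
            "B",
            "sigma_B",
            "resolution_A",
        ],
    )


def surface_depth_table() -> pd.DataFrame:
    """Surface-depth 5-nm bin B-factors with matched controls."""
    return pd.DataFrame(
        _DEPTH_ROWS,
        columns=[
            "group",
            "n_particles",
            "n_tomograms",
            "thickness_nm",
            "thickness_sd_nm",
            "B",
            "sigma_B",
            "resolution_A",
            "B_control",
            "sigma_B_control",
            "resolution_control_A",
        ],
    )


def amorphous_region_summaries() -> dict[str, tuple[float, float, int]]:
    """(mean um, SD um, n) summaries of amorphous-region lengths."""
    return {"overall": AMORPHOUS_OVERALL, "4nA": AMORPHOUS_4NA, "60nA": AMORPHOUS_60NA}


def row_to_linear_fit(n_particles: int, B: float, sigma_B: float, resolution_A: float) -> LinearFit:
    """Reconstruct a group's Rosenthal-Henderson line from its printed row.

    The slope follows from the printed B-factor (m = 2/B, with the SE
    inverted through the same propagation, sigma_m = 2 sigma_B / B^2); the
    intercept anchors the line at the printed (particle count, global
    resolution) point, with its SE propagated from the slope through the
    anchor. n_points/R^2 are not recoverable from the row and set to 0/NaN.
    """
    m = 2.0 / B
    sigma_m = 2.0 * sigma_B / B**2
    ln_n = math.log(n_particles)
    y_anchor = 1.0 / resolution_A**2
    c = y_anchor - m * ln_n
    sigma_c = sigma_m * ln_n
    return LinearFit(
        slope=m,
        intercept=c,
        sigma_slope=sigma_m,
        sigma_intercept=sigma_c,
        n_points=0,
        r_squared=float("nan"),
    )


def reconstruct_depth_curves(target_n: int = 5000) -> dict:
    """Rebuild both damage curves from the printed surface-depth table.

    For every depth bin with a B-factor, the group and matched-control
    lines are reconstructed from the printed rows, extrapolated to
    ``target_n`` particles and differenced; B-factor ratios are formed
    directly. Both point sets (at bin midpoints) are then fitted with the
    weighted three-parameter exponential decay.
    """
    table = surface_depth_table()
    ratio_points: list[DepthPoint] = []
    dres_points: list[DepthPoint] = []
    for _, row in table.iterrows():
        lo, hi = (float(v) for v in row["group"].split("_")[1:3])
        mid = 0.5 * (lo + hi)
        ratio, s_ratio = bfactor_ratio(
            row["B"], row["sigma_B"], row["B_control"], row["sigma_B_control"]
        )
        ratio_points.append(DepthPoint(row["group"], mid, ratio, s_ratio))
        fit_g = row_to_linear_fit(row["n_particles"], row["B"], row["sigma_B"], row["resolution_A"])
        fit_c = row_to_linear_fit(
            row["n_particles"],
            row["B_control"],
            row["sigma_B_control"],
            row["resolution_control_A"],
        )
        rg, sg = extrapolate_resolution(fit_g, target_n)
        rc, sc = extrapolate_resolution(fit_c, target_n)
        d, sd = resolution_difference(rg, sg, rc, sc)
        dres_points.append(DepthPoint(row["group"], mid, d, sd))

    ratio_fit: DecayFit = fit_exponential_decay(ratio_points)
    dres_fit: DecayFit = fit_exponential_decay(dres_points)
    return {
        "ratio_points": ratio_points,
        "dres_points": dres_points,
        "ratio_fit": ratio_fit,
        "dres_fit": dres_fit,
    }
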
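"""Rosenthal-Henderson B-factor estimation from subset-resolution series.

For a particle group, random subsets of decreasing size are refined and
their resolutions recorded; on the transformed scale y = 1/resolution^2
against ln(particle number) the points are linear with slope m, and the
group's B-factor is B = 2/m. The standard error of B follows from the
standard error of the slope: sigma_B = 2 sigma_m / m^2.

The fit pools all repeats' points in one ordinary least squares
regression; per-size means and SEs over repeats are only used for
plotting. Subset sizes follow a halving series truncated at a minimum
particle count (default 400), below which resolutions are too unstable
to anchor the fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LinearFit",
    "BFactorResult",
    "subset_series",
    "inverse_sq_transform",
    "rh_fit",
    "bfactor_from_fit",
    "fit_group",
    "validate_series",
]

MIN_PARTICLES = 400
REPEATS = 3


@dataclass
class LinearFit:
    """OLS fit of y = m * ln(n) + c with standard errors."""

    slope: float
    intercept: float
    sigma_slope: float
    sigma_intercept: float
    n_points: int
    r_squared: float

    def predict(self, ln_n: float) -> float:
        return self.slope * ln_n + self.intercept


@dataclass
class BFactorResult:
    """B-factor (A^2) with propagated SE and the underlying linear fit."""

    group: str
    B: float
    sigma_B: float
    fit: LinearFit

    def __post_init__(self) -> None:
        if not np.isfinite(self.B) or self.B == 0:
            raise ValueError(f"non-finite or zero B-factor for group {self.group!r}")
        if np.sign(self.B) != np.sign(self.fit.slope):
            raise ValueError("B-factor sign inconsistent with slope")
        if self.sigma_B < 0:
            raise ValueError("sigma_B must be >= 0")


def subset_series(total_n: int, min_particles: int = MIN_PARTICLES) -> list[int]:
    """Halving subset-size series: total_n, total_n//2, ... >= min_particles."""
    if total_n < min_particles:
        raise ValueError(
            f"group of {total_n} particles is below the minimum of {min_particles} "
            "needed for a resolution estimate"
        )
    sizes = []
    n = total_n
    while n >= min_particles:
        sizes.append(int(n))
        n //= 2
    return sizes


def inverse_sq_transform(
    resolution_A: float | np.ndarray, sigma_res: float | np.ndarray | None = None
):
    """y = 1/resolution^2 (A^-2), with SE propagated as sigma_y = 2 sigma/res^3."""
    res = np.asarray(resolution_A, dtype=float)
    if np.any(res <= 0):
        raise ValueError("resolution must be positive")
    y = 1.0 / res**2
    if sigma_res is None:
        if np.ndim(resolution_A) == 0:
            return float(y)
        return y
    sigma_y = 2.0 * np.asarray(sigma_res, dtype=float) / res**3
    if np.ndim(resolution_A) == 0:
        return float(y), float(sigma_y)
    return y, sigma_y


def validate_series(series: pd.DataFrame, min_particles: int = MIN_PARTICLES) -> None:
    required = {"n_particles", "resolution_A"}
    missing = required - set(series.columns)
    if missing:
        raise ValueError(f"resolution series missing columns {sorted(missing)}")
    if (series["resolution_A"] <= 0).any():
        raise ValueError("resolutions must be positive")
    if (series["n_particles"] < min_particles).any():
        bad = int(series["n_particles"].min())
        raise ValueError(f"series contains a subset of {bad} particles (< {min_particles})")


def rh_fit(series: pd.DataFrame) -> LinearFit:
    """Pooled OLS of 1/resolution^2 on ln(particle number).

    ``series`` holds one group's points over all repeats, with columns
    ``n_particles`` and ``resolution_A``. Requires >= 3 points spanning
    >= 2 distinct subset sizes.
    """
    validate_series(series, min_particles=1)
    x = np.log(series["n_particles"].to_numpy(dtype=float))
    y = inverse_sq_transform(series["resolution_A"].to_numpy(dtype=float))
    if len(np.unique(x)) < 2:
        raise ValueError("degenerate abscissa: all points at one subset size")
    if len(x) < 3:
        raise ValueError(f"need >= 3 points for a fit with standard errors, got {len(x)}")
    res = stats.linregress(x, y)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        sigma_slope=float(res.stderr),
        sigma_intercept=float(res.intercept_stderr),
        n_points=len(x),
        r_squared=float(res.rvalue**2),
    )


def bfactor_from_fit(fit: LinearFit, group: str = "") -> BFactorResult:
    """B = 2/slope, sigma_B = 2 sigma_slope / slope^2."""
    if fit.slope == 0:
        raise ValueError("zero slope: B-factor undefined")
    B = 2.0 / fit.slope
    sigma_B = 2.0 * fit.sigma_slope / fit.slope**2
    return BFactorResult(group=group, B=float(B), sigma_B=abs(float(sigma_B)), fit=fit)


def fit_group(series: pd.DataFrame, group: str = "") -> BFactorResult:
    """Convenience: pooled fit plus B-factor for one group's series."""
    return bfactor_from_fit(rh_fit(series), group=group)
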
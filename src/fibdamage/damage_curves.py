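"""Depth-damage statistics built on per-cohort B-factor fits.

Two complementary damage curves over the depth bins:

* the ratio of each depth cohort's B-factor to its matched control's,
  with the SE propagated in quadrature on the relative scale;
* the difference in resolution extrapolated to a fixed particle number
  (default 5000) between cohort and control, where the extrapolation
  error uses sigma_y = sqrt((sigma_m * x)^2 + sigma_c^2) — deliberately
  without the slope-intercept covariance term, reproducing the error
  model of the upstream B-factor analysis — and is then propagated
  through y = 1/resolution^2.

Both curves are summarized by a weighted three-parameter exponential
decay y = A exp(-k x) + c over the bin midpoints. The backside analysis
uses the Spearman rank trend of B-factors over 1-um bins and a Welch
two-sample test for the amorphous-region length comparison.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from shapely.geometry import Polygon

from .bfactor import BFactorResult, LinearFit

logger = logging.getLogger(__name__)

__all__ = [
    "DepthPoint",
    "DecayFit",
    "bfactor_ratio",
    "extrapolate_resolution",
    "resolution_difference",
    "fit_exponential_decay",
    "spearman_trend",
    "backside_group_summary",
    "amorphous_length",
    "compare_length_groups",
]

EXTRAPOLATION_N = 5000


@dataclass
class DepthPoint:
    """One damage-curve point: bin midpoint (nm), value, SE."""

    label: str
    x_nm: float
    value: float
    se: float

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("SE must be >= 0")


@dataclass
class DecayFit:
    """Weighted fit of y = A exp(-k x) + c."""

    A: float
    k: float
    c: float
    se_A: float
    se_k: float
    se_c: float
    r_squared: float
    r_squared_weighted: float
    converged: bool

    def predict(self, x) -> np.ndarray:
        return self.A * np.exp(-self.k * np.asarray(x, dtype=float)) + self.c


def bfactor_ratio(
    b_group: float, sigma_group: float, b_control: float, sigma_control: float
) -> tuple[float, float]:
    """Ratio of cohort to matched-control B-factor with propagated SE."""
    if b_control == 0:
        raise ValueError("control B-factor is zero")
    ratio = b_group / b_control
    sigma = abs(ratio) * math.sqrt(
        (sigma_group / b_group) ** 2 + (sigma_control / b_control) ** 2
    )
    return ratio, sigma


def extrapolate_resolution(
    fit: LinearFit, target_n: int = EXTRAPOLATION_N
) -> tuple[float, float]:
    """Resolution (A) predicted at ``target_n`` particles from a linear fit.

    y* = m ln(n) + c must be positive; its error omits the slope-intercept
    covariance and is converted via sigma_res = sigma_y / (2 y*^{3/2}).
    """
    x = math.log(target_n)
    y = fit.predict(x)
    if y <= 0:
        raise ValueError(
            f"extrapolation beyond validity: predicted 1/res^2 = {y:.3g} <= 0 "
            f"at n = {target_n}"
        )
    sigma_y = math.sqrt((fit.sigma_slope * x) ** 2 + fit.sigma_intercept**2)
    resolution = 1.0 / math.sqrt(y)
    sigma_res = sigma_y / (2.0 * y**1.5)
    return resolution, sigma_res


def resolution_difference(
    res_group: float, sigma_group: float, res_control: float, sigma_control: float
) -> tuple[float, float]:
    """Cohort minus control extrapolated resolution, SEs added in quadrature."""
    return res_group - res_control, math.hypot(sigma_group, sigma_control)


def fit_exponential_decay(points: list[DepthPoint], max_iter: int = 10000) -> DecayFit:
    """Weighted least-squares fit of y = A exp(-k x) + c to damage points.

    Weights are 1/SE^2 (all SEs must be positive). Initial values: A from
    the first-minus-last value, k from the log-ratio of the first two
    baseline-subtracted values, c from the last value. R^2 is reported
    unweighted; a weighted R^2 is emitted alongside for transparency.
    """
    if len(points) < 4:
        raise ValueError(f"need >= 4 points for a 3-parameter fit, got {len(points)}")
    x = np.array([p.x_nm for p in points], dtype=float)
    y = np.array([p.value for p in points], dtype=float)
    se = np.array([p.se for p in points], dtype=float)
    if np.any(se <= 0):
        raise ValueError("all point SEs must be > 0 for weighting")
    if np.ptp(y) == 0:
        raise ValueError("no decay signal: all values equal")

    c0 = y[-1]
    A0 = y[0] - y[-1]
    num, den = y[0] - c0, y[1] - c0
    if A0 != 0 and num > 0 and den > 0 and x[1] != x[0]:
        k0 = math.log(num / den) / (x[1] - x[0])
    else:
        k0 = 0.1
    k0 = abs(k0) if k0 != 0 else 0.1

    def model(xv, A, k, c):
        return A * np.exp(-k * xv) + c

    try:
        popt, pcov = optimize.curve_fit(
            model,
            x,
            y,
            p0=[A0 if A0 != 0 else 1.0, k0, c0],
            sigma=se,
            absolute_sigma=True,
            maxfev=max_iter,
            xtol=1e-10,
            ftol=1e-10,
        )
        converged = True
    except RuntimeError as exc:
        logger.warning("exponential decay fit did not converge: %s", exc)
        popt = np.array([A0, k0, c0])
        pcov = np.full((3, 3), np.nan)
        converged = False
    A, k, c = popt
    if k <= 0:
        logger.warning("fitted decay rate k = %.4g <= 0: flagged as unconverged", k)
        converged = False
    perr = np.sqrt(np.diag(pcov))
    resid = y - model(x, *popt)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else float("nan")
    w = 1.0 / se**2
    ybar_w = np.sum(w * y) / np.sum(w)
    ss_tot_w = np.sum(w * (y - ybar_w) ** 2)
    r2_w = 1.0 - np.sum(w * resid**2) / ss_tot_w if ss_tot_w > 0 else float("nan")
    return DecayFit(
        A=float(A),
        k=float(k),
        c=float(c),
        se_A=float(perr[0]),
        se_k=float(perr[1]),
        se_c=float(perr[2]),
        r_squared=float(r2),
        r_squared_weighted=float(r2_w),
        converged=converged,
    )


def spearman_trend(values: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation of bin-ordered values against bin order.

    Average ranks for ties. The two-sided p-value is exact (full
    permutation enumeration) for n <= 8 and the t-approximation beyond.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 3:
        raise ValueError(f"need >= 3 bins for a trend, got {n}")
    order = np.arange(n, dtype=float)
    r = float(stats.spearmanr(order, values).statistic)
    if n <= 8:
        ranks = stats.rankdata(values)
        rank_x = stats.rankdata(order)
        perms = np.array(list(itertools.permutations(ranks)))
        rx = (rank_x - rank_x.mean()) / rank_x.std()
        centered = perms - perms.mean(axis=1, keepdims=True)
        sd = centered.std(axis=1)
        rhos = centered @ rx / (n * sd)
        p = float(np.mean(np.abs(rhos) >= abs(r) - 1e-12))
    else:
        p = float(stats.spearmanr(order, values).pvalue)
    return r, p


def backside_group_summary(results: list[BFactorResult]) -> dict:
    """Extremes and rank trend of backside-bin B-factors."""
    if len(results) < 2:
        raise ValueError("need >= 2 backside bins")
    bs = np.array([r.B for r in results], dtype=float)
    if len(results) >= 3:
        r, p = spearman_trend(bs)
    else:
        r, p = float("nan"), float("nan")
    return {
        "min_B": float(bs.min()),
        "max_B": float(bs.max()),
        "spearman_r": r,
        "spearman_p": p,
        "groups": [res.group for res in results],
    }


def amorphous_length(
    region_polygon: np.ndarray, milling_axis: int = 0
) -> float:
    """Mean extent of an amorphous backside region along the milling axis.

    Computed as the segmented region's area divided by its length
    perpendicular to the milling direction (coordinates in um).
    """
    pts = np.asarray(region_polygon, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 2:
        raise ValueError("region polygon needs >= 3 (x, y) vertices")
    if milling_axis not in (0, 1):
        raise ValueError("milling_axis must be 0 (x) or 1 (y)")
    poly = Polygon(pts)
    if not poly.is_valid:
        raise ValueError("self-intersecting region polygon")
    perp_axis = 1 - milling_axis
    lo = pts[:, perp_axis].min()
    hi = pts[:, perp_axis].max()
    extent = hi - lo
    if extent <= 0:
        raise ValueError("zero extent perpendicular to the milling direction")
    return float(poly.area / extent)


def compare_length_groups(
    lengths_a: np.ndarray | None = None,
    lengths_b: np.ndarray | None = None,
    summary_a: tuple[float, float, int] | None = None,
    summary_b: tuple[float, float, int] | None = None,
    method: str = "welch",
) -> tuple[float, float, float]:
    """Two-sample comparison of amorphous-region lengths: (t, df, p).

    Accepts raw values or (mean, sd, n) summaries. ``method`` is "welch"
    (default), "pooled", or "ranksum" (raw values only; df is NaN).
    """
    if summary_a is not None and summary_b is not None:
        m1, s1, n1 = summary_a
        m2, s2, n2 = summary_b
    elif lengths_a is not None and lengths_b is not None:
        a = np.asarray(lengths_a, dtype=float)
        b = np.asarray(lengths_b, dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError("each group needs n >= 2")
        if method == "ranksum":
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            return float(res.statistic), float("nan"), float(res.pvalue)
        m1, s1, n1 = a.mean(), a.std(ddof=1), len(a)
        m2, s2, n2 = b.mean(), b.std(ddof=1), len(b)
    else:
        raise ValueError("pass either raw values or both summaries")
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if method == "ranksum":
        raise ValueError("ranksum needs raw values")
    equal_var = method == "pooled"
    res = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=equal_var)
    if equal_var:
        dof = n1 + n2 - 2
    else:
        va, vb = s1**2 / n1, s2**2 / n2
        dof = (va + vb) ** 2 / (va**2 / (n1 - 1) + vb**2 / (n2 - 1))
    return float(res.statistic), float(dof), float(res.pvalue)
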
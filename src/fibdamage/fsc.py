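"""Fourier shell correlation between half maps and threshold resolution.

The FSC between two independently refined half maps is the normalized
cross-correlation of their Fourier transforms over spherical shells;
resolution is read at the first downward crossing of the 0.143 criterion,
capped at the Nyquist limit of the sampling (2 x voxel size).

Shells are integer-radius bins one Fourier voxel wide with the DC term
excluded; no masking or phase-randomization correction is applied. This
keeps the estimator deterministic and self-contained — it exists so the
pipeline can be exercised on synthetic half-map fixtures, not to reproduce
a particular refinement package's masked FSC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import VolumeGrid

logger = logging.getLogger(__name__)

__all__ = ["FSCCurve", "fsc_curve", "resolution_at_threshold", "nyquist_resolution"]

FSC_THRESHOLD = 0.143


@dataclass
class FSCCurve:
    """Ordered FSC shells: spatial frequency (1/A), correlation, voxel count."""

    frequency: np.ndarray
    fsc: np.ndarray
    n_voxels: np.ndarray
    voxel_size_A: float
    zero_variance_shells: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.frequency = np.asarray(self.frequency, dtype=float)
        self.fsc = np.asarray(self.fsc, dtype=float)
        self.n_voxels = np.asarray(self.n_voxels, dtype=int)
        if len(self.frequency) == 0:
            raise ValueError("empty FSC curve")
        if np.any(np.diff(self.frequency) <= 0):
            raise ValueError("shell frequencies must be strictly increasing")
        if np.any(np.abs(self.fsc) > 1 + 1e-9):
            raise ValueError("FSC values must lie in [-1, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frequency_invA": self.frequency, "fsc": self.fsc, "n_voxels": self.n_voxels}
        )


def nyquist_resolution(voxel_size_A: float) -> float:
    """Best representable resolution at a given sampling: 2 x voxel size."""
    if not voxel_size_A > 0:
        raise ValueError(f"voxel size must be positive, got {voxel_size_A}")
    return 2.0 * voxel_size_A


def fsc_curve(half_a: VolumeGrid, half_b: VolumeGrid) -> FSCCurve:
    """FSC between two half maps of identical geometry."""
    if half_a.data.shape != half_b.data.shape:
        raise ValueError(
            f"half map shapes differ: {half_a.data.shape} vs {half_b.data.shape}"
        )
    if not np.isclose(half_a.voxel_size_A, half_b.voxel_size_A, rtol=1e-6):
        raise ValueError(
            f"half map voxel sizes differ: {half_a.voxel_size_A} vs {half_b.voxel_size_A}"
        )
    vox = half_a.voxel_size_A
    fa = np.fft.fftn(half_a.data)
    fb = np.fft.fftn(half_b.data)
    shape = half_a.data.shape
    freqs = [np.fft.fftfreq(n, d=vox) for n in shape]
    radius = np.sqrt(
        freqs[0][:, None, None] ** 2 + freqs[1][None, :, None] ** 2 + freqs[2][None, None, :] ** 2
    )
    base = 1.0 / (max(shape) * vox)  # one Fourier voxel of the largest axis
    shell = np.rint(radius / base).astype(int)
    n_shells = int(np.floor((0.5 / vox) / base + 0.5))

    cross = np.real(fa * np.conj(fb))
    pa = np.abs(fa) ** 2
    pb = np.abs(fb) ** 2
    flat = shell.ravel()
    num = np.bincount(flat, weights=cross.ravel(), minlength=n_shells + 1)
    da = np.bincount(flat, weights=pa.ravel(), minlength=n_shells + 1)
    db = np.bincount(flat, weights=pb.ravel(), minlength=n_shells + 1)
    counts = np.bincount(flat, minlength=n_shells + 1)

    idx = np.arange(1, n_shells + 1)  # DC excluded
    idx = idx[counts[idx] > 0]
    denom = np.sqrt(da[idx] * db[idx])
    fsc = np.zeros(len(idx))
    zero_var = denom <= 0
    good = ~zero_var
    fsc[good] = num[idx][good] / denom[good]
    fsc = np.clip(fsc, -1.0, 1.0)
    if zero_var.any():
        logger.warning("%d zero-variance shells recorded as FSC 0", int(zero_var.sum()))
    return FSCCurve(
        frequency=idx * base,
        fsc=fsc,
        n_voxels=counts[idx],
        voxel_size_A=vox,
        zero_variance_shells=idx[zero_var],
    )


def resolution_at_threshold(
    curve: FSCCurve, threshold: float = FSC_THRESHOLD, voxel_size_A: float | None = None
) -> float:
    """Resolution (A) at the first downward threshold crossing.

    The crossing frequency is located by linear interpolation between the
    adjacent shells; a value exactly at the threshold counts as crossed.
    A curve that never falls below the threshold returns the Nyquist
    resolution; a curve already below the threshold at its first shell
    returns NaN (resolution worse than the first shell — no estimate).
    """
    vox = curve.voxel_size_A if voxel_size_A is None else voxel_size_A
    fsc = curve.fsc
    freq = curve.frequency
    if fsc[0] < threshold:
        logger.warning("FSC below %.3f at the first shell: no resolution estimate", threshold)
        return float("nan")
    below = np.nonzero(fsc <= threshold)[0]
    if len(below) == 0:
        return nyquist_resolution(vox)
    i = int(below[0])
    if i == 0:  # exactly at threshold in the first shell
        return 1.0 / freq[0]
    f_lo, f_hi = freq[i - 1], freq[i]
    y_lo, y_hi = fsc[i - 1], fsc[i]
    t = (y_lo - threshold) / (y_lo - y_hi)
    f_star = f_lo + t * (f_hi - f_lo)
    return float(1.0 / f_star)
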
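"""Slant-axis, slant-magnitude and anisotropy from orientation distributions.

The orientation distribution at a surface location is the module II
activity summed over frequency bands, one value per orientation bin.
Because orientation is axial (theta and theta + pi are the same filter),
circular statistics are computed on *doubled* angles:

    R       = sum_o d_o * exp(i * 2 * theta_o) / sum_o d_o
    Theta   = atan2(Im R, Re R) / 2          (axis of anisotropy, in [0, pi);
                                              the slant direction is
                                              Theta + pi/2, axis only)
    ||R||   = |R|  in [0, 1]                 (proportional to slant)
    A       = 1 - min_o d_o / max_o d_o      (anisotropy, in [0, 1])

Flat, isotropically textured patches give flat distributions (R ~ 0,
A ~ 0); strongly foreshortened patches concentrate activity in the bins
along the compression axis (||R|| and A near 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "resultant",
    "slant_axis",
    "slant_magnitude",
    "anisotropy",
    "orientation_map",
    "SurfaceOrientationMap",
]


@dataclass
class SurfaceOrientationMap:
    """Per-location slant axis (radians, [0, pi)), magnitude and anisotropy.

    ``valid`` is False where the local distribution was all-zero (isotropic /
    empty); Theta, ||R|| and A are reported as 0 there.
    """

    theta: np.ndarray
    magnitude: np.ndarray
    anisotropy: np.ndarray
    valid: np.ndarray
    orientations: np.ndarray


def _dist(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("orientation distribution must be nonnegative")
    return d


def resultant(d: np.ndarray, orientations: np.ndarray) -> complex:
    """Normalized doubled-angle resultant of one orientation distribution.

    Returns nan+nan*j for an all-zero (undefined / isotropic-empty)
    distribution.
    """
    d = _dist(d)
    orientations = np.asarray(orientations, dtype=float)
    if d.shape[-1] != orientations.shape[0]:
        raise ValueError("distribution length must equal number of orientations")
    total = d.sum()
    if total <= 0:
        return complex(np.nan, np.nan)
    return complex(np.sum(d * np.exp(2j * orientations)) / total)


def slant_axis(R: complex) -> float:
    """Axis of anisotropy: the halved argument of R, mapped into [0, pi)."""
    th = float(np.mod(np.arctan2(np.imag(R), np.real(R)) / 2.0, np.pi))
    return 0.0 if th >= np.pi - 1e-12 else th


def slant_magnitude(R: complex) -> float:
    """|R| in [0, 1]; proportional to surface slant."""
    return float(np.hypot(np.real(R), np.imag(R)))


def anisotropy(d: np.ndarray) -> float:
    """A = 1 - min/max of the distribution; nan if the maximum is zero."""
    d = _dist(d)
    mx = d.max()
    if mx <= 0:
        return float("nan")
    return float(1.0 - d.min() / mx)


def orientation_map(per_orientation: np.ndarray, orientations: np.ndarray,
                    patch_sigma: float = 8.0) -> SurfaceOrientationMap:
    """Pixelwise slant/tilt estimation from locally pooled distributions.

    ``per_orientation`` is the frequency-summed module II stack
    (H, W, n_theta).  Each orientation plane is pooled with a Gaussian
    window (sigma ``patch_sigma`` pixels) before applying the doubled-angle
    statistics, because single-pixel histograms are noise dominated.
    """
    r = np.asarray(per_orientation, dtype=float)
    if r.ndim != 3 or r.shape[2] != len(orientations):
        raise ValueError("per_orientation must be (H, W, n_theta)")
    pooled = gaussian_filter(r, (patch_sigma, patch_sigma, 0), mode="reflect")
    total = pooled.sum(axis=2)
    valid = total > 1e-12
    safe_total = np.where(valid, total, 1.0)
    z = np.tensordot(pooled, np.exp(2j * np.asarray(orientations)), axes=([2], [0]))
    z = z / safe_total
    theta = np.mod(np.angle(z) / 2.0, np.pi)
    mag = np.abs(z)
    mx = pooled.max(axis=2)
    mn = pooled.min(axis=2)
    a = 1.0 - mn / np.where(mx > 0, mx, 1.0)
    zero = ~valid
    for arr in (theta, mag, a):
        arr[zero] = 0.0
    return SurfaceOrientationMap(theta=theta, magnitude=mag, anisotropy=a,
                                 valid=valid, orientations=np.asarray(orientations))
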
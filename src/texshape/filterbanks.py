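"""Receptive-field kernel families for the four model cortical areas.

Every model area filters its input with a parametric family of 2D kernels
laid out on a log-polar grid: orientations spaced linearly on [0, pi) and
spatial frequencies spaced logarithmically (octaves).  The families are

* ``gabor``              — quadrature (even/odd) Gabor pairs, model V1;
* ``bipole_lobes``       — two displaced anisotropic Gaussian lobes
                           ("figure-eight"), long-range grouping, model V2;
* ``second_derivative``  — three alternating anisotropic Gaussians, an
                           oriented edge/line detector, model V4 (sketch);
* ``dog``                — isotropic difference-of-Gaussians enhancement;
* ``first_derivative``   — two opposite-sign displaced Gaussians, a signed
                           directional-derivative operator, model V4 (depth);
* ``it_signed_lobes``    — two large, sigmoid-truncated, opposite-sign
                           lobes performing one-sided directed integration,
                           model IT.

Conventions
-----------
theta is the axis of elongation (the stripe orientation a kernel responds
to), in radians, identified modulo pi.  Image arrays are row-major with
origin top-left; within kernel grids ``x`` is the column offset and ``y``
the row offset.  All kernels have odd side lengths so the center is a pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple, Union

import numpy as np

__all__ = [
    "KernelGrid",
    "FilterBankSpec",
    "FilterBank",
    "gabor_sigma",
    "make_gabor_bank",
    "make_bipole_lobes",
    "make_second_derivative_bank",
    "make_dog_kernel",
    "make_first_derivative_bank",
    "make_it_integration_bank",
]

KernelLike = Union["KernelGrid", Tuple["KernelGrid", "KernelGrid"]]


@dataclass
class KernelGrid:
    """A single 2D kernel: weights grid, center pixel, support radius."""

    weights: np.ndarray
    center: Tuple[int, int]
    support_radius: int

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2:
            raise ValueError("kernel weights must be 2D")
        if w.shape[0] % 2 == 0 or w.shape[1] % 2 == 0:
            raise ValueError("kernel side lengths must be odd")
        if not np.all(np.isfinite(w)):
            raise ValueError("kernel weights must be finite")
        self.weights = w


@dataclass
class FilterBankSpec:
    """Grid and shape parameters for one kernel family.

    Orientations are derived linearly on [0, pi); frequencies
    logarithmically on [freq_min, freq_max] (cycles/pixel).
    """

    n_orientations: int = 8
    n_frequencies: int = 4
    freq_min: float = 0.03
    freq_max: float = 0.24
    aspect_ratio: float = 1.0
    lobe_separation: float = 1.2  # in units of the lobe's major sigma
    sigmoid_sharpness: float = 1.0  # IT bank only; 1/pixels

    def __post_init__(self) -> None:
        if self.n_orientations < 2:
            raise ValueError("need at least 2 orientations")
        if self.n_frequencies < 1:
            raise ValueError("need at least 1 frequency band")
        if not (0 < self.freq_min < self.freq_max):
            raise ValueError("require 0 < freq_min < freq_max")

    @property
    def orientations(self) -> np.ndarray:
        return np.linspace(0.0, np.pi, self.n_orientations, endpoint=False)

    @property
    def frequencies(self) -> np.ndarray:
        if self.n_frequencies == 1:
            return np.array([self.freq_min])
        return np.geomspace(self.freq_min, self.freq_max, self.n_frequencies)


@dataclass
class FilterBank:
    """A complete family of kernels over the (orientation, frequency) grid."""

    kind: str
    spec: FilterBankSpec
    kernels: Dict[Tuple[int, int], KernelLike] = field(default_factory=dict)

    def __getitem__(self, key: Tuple[int, int]) -> KernelLike:
        return self.kernels[key]


# ---------------------------------------------------------------------------
# grid helpers

def _odd_support(radius: float) -> int:
    """Half-size rounded up; full side = 2*half + 1 (odd)."""
    return int(np.ceil(radius))


def _grids(half: int) -> Tuple[np.ndarray, np.ndarray]:
    c = np.arange(-half, half + 1, dtype=float)
    x, y = np.meshgrid(c, c)
    return x, y


def _aniso_gaussian(x, y, theta, sigma_along, sigma_across,
                    cx=0.0, cy=0.0) -> np.ndarray:
    """Unnormalized anisotropic Gaussian elongated along theta, center (cx, cy)."""
    u = (x - cx) * np.cos(theta) + (y - cy) * np.sin(theta)      # along axis
    v = -(x - cx) * np.sin(theta) + (y - cy) * np.cos(theta)     # across axis
    return np.exp(-0.5 * ((u / sigma_along) ** 2 + (v / sigma_across) ** 2))


def gabor_sigma(freq: float, bandwidth_octaves: float = 1.0) -> float:
    """Gaussian envelope sigma for a Gabor of given carrier frequency.

    Chosen so the half-amplitude frequency bandwidth is the requested number
    of octaves (~1 octave gives sigma ~ 0.56 / freq).
    """
    b = bandwidth_octaves
    return (1.0 / (np.pi * freq)) * np.sqrt(np.log(2) / 2.0) * (2**b + 1) / (2**b - 1)


def _check_support(half: int, sigma_max: float) -> None:
    if half < 3.0 * sigma_max - 1e-9:
        raise ValueError(
            f"kernel support (half-size {half}) truncates the Gaussian "
            f"envelope below 3 sigma (sigma={sigma_max:.2f})"
        )


# ---------------------------------------------------------------------------
# V1: quadrature Gabor pairs

def make_gabor_bank(spec: FilterBankSpec, support_half: int | None = None) -> FilterBank:
    """Even/odd quadrature Gabor pair per (theta, omega).

    The carrier varies perpendicular to theta, so theta is the orientation of
    the stripes the kernel responds to.  The odd kernel sums to zero by
    antisymmetry; the even kernel is DC-corrected to zero mean so constant
    images produce no texture energy.
    """
    bank = FilterBank(kind="gabor", spec=spec)
    for j, freq in enumerate(spec.frequencies):
        sig = gabor_sigma(freq)
        sig_along = spec.aspect_ratio * sig
        half = support_half if support_half is not None else _odd_support(3.0 * max(sig, sig_along))
        _check_support(half, max(sig, sig_along))
        x, y = _grids(half)
        for i, theta in enumerate(spec.orientations):
            env = _aniso_gaussian(x, y, theta, sig_along, sig)
            # carrier along the direction perpendicular to the stripes
            u = x * np.cos(theta + np.pi / 2) + y * np.sin(theta + np.pi / 2)
            carrier = 2.0 * np.pi * freq * u
            even = np.cos(carrier) * env
            even -= env * (even.sum() / env.sum())  # exact zero mean
            odd = np.sin(carrier) * env
            # L1 normalization equalizes the gain across frequency bands:
            # the amplitude response to a matched grating of unit contrast
            # is then scale invariant, so relative energy between bands
            # reflects the texture, not the kernel size.
            even /= np.abs(even).sum()
            odd /= np.abs(odd).sum()
            bank.kernels[(i, j)] = (
                KernelGrid(even, (half, half), half),
                KernelGrid(odd, (half, half), half),
            )
    return bank


# ---------------------------------------------------------------------------
# V2: bipole lobes

def make_bipole_lobes(spec: FilterBankSpec, length_factor: float = 2.5,
                      across_ratio: float = 3.0,
                      max_overlap: float = 0.25) -> FilterBank:
    """Two displaced anisotropic Gaussian lobes per (theta, omega).

    Each lobe is nonnegative and normalized to unit sum; the pair is mirror
    symmetric through the center and displaced +/- along the theta axis so
    that multiplicative combination fires only for aligned input on *both*
    sides (gap bridging).  Lobe length defaults to ``length_factor`` times
    the Gabor envelope at the same frequency so lobes span texture gaps.
    """
    if spec.lobe_separation <= 0:
        raise ValueError("lobe_separation must be positive")
    bank = FilterBank(kind="bipole_lobes", spec=spec)
    for j, freq in enumerate(spec.frequencies):
        sig_along = length_factor * gabor_sigma(freq)
        sig_across = sig_along / across_ratio
        d = spec.lobe_separation * sig_along
        half = _odd_support(d + 3.0 * sig_along)
        x, y = _grids(half)
        for i, theta in enumerate(spec.orientations):
            dx, dy = d * np.cos(theta), d * np.sin(theta)
            lobe1 = _aniso_gaussian(x, y, theta, sig_along, sig_across, dx, dy)
            lobe2 = _aniso_gaussian(x, y, theta, sig_along, sig_across, -dx, -dy)
            lobe1 /= lobe1.sum()
            lobe2 /= lobe2.sum()
            overlap = np.minimum(lobe1, lobe2).sum()
            if overlap > max_overlap:
                raise ValueError(
                    f"bipole lobes overlap {overlap:.2f} > {max_overlap}: "
                    "separation too small for scale"
                )
            bank.kernels[(i, j)] = (
                KernelGrid(lobe1, (half, half), half),
                KernelGrid(lobe2, (half, half), half),
            )
    return bank


# ---------------------------------------------------------------------------
# V4 (sketch): second-derivative-like triple Gaussian

def make_second_derivative_bank(spec: FilterBankSpec, length_ratio: float = 3.0) -> FilterBank:
    """Central lobe flanked by two opposite-sign lobes across the theta axis.

    Approximates a second directional derivative taken perpendicular to the
    elongation axis; total weight is exactly zero so constants are
    annihilated.
    """
    bank = FilterBank(kind="second_derivative", spec=spec)
    for j, freq in enumerate(spec.frequencies):
        sig_across = 0.4 / freq
        sig_along = length_ratio * sig_across
        d = 1.6 * sig_across
        half = _odd_support(d + 3.0 * sig_along)
        x, y = _grids(half)
        for i, theta in enumerate(spec.orientations):
            # flank displacement is perpendicular to the elongation axis
            px, py = d * np.cos(theta + np.pi / 2), d * np.sin(theta + np.pi / 2)
            center = _aniso_gaussian(x, y, theta, sig_along, sig_across)
            f1 = _aniso_gaussian(x, y, theta, sig_along, sig_across, px, py)
            f2 = _aniso_gaussian(x, y, theta, sig_along, sig_across, -px, -py)
            flank = f1 + f2
            k = center - flank * (center.sum() / flank.sum())  # exact zero sum
            k /= np.abs(k).sum()  # band-equalized gain, as in the Gabor bank
            bank.kernels[(i, j)] = KernelGrid(k, (half, half), half)
    return bank


# ---------------------------------------------------------------------------
# DoG enhancement kernel

def make_dog_kernel(sigma_center: float, sigma_surround: float) -> KernelGrid:
    """Isotropic zero-mean center-surround (difference of Gaussians) kernel."""
    if not sigma_center < sigma_surround:
        raise ValueError("require sigma_center < sigma_surround")
    half = _odd_support(3.5 * sigma_surround)
    x, y = _grids(half)
    r2 = x**2 + y**2
    gc = np.exp(-0.5 * r2 / sigma_center**2)
    gs = np.exp(-0.5 * r2 / sigma_surround**2)
    k = gc / gc.sum() - gs / gs.sum()
    return KernelGrid(k, (half, half), half)


# ---------------------------------------------------------------------------
# V4 (depth): first-derivative pair

def make_first_derivative_bank(spec: FilterBankSpec, length_ratio: float = 2.0) -> FilterBank:
    """Signed directional-derivative kernels.

    One positive and one negative anisotropic Gaussian lobe displaced along
    the gradient direction phi = theta + pi/2 (perpendicular to the
    elongation axis).  Applied in a single contrast polarity, so the
    response sign encodes whether activity increases or decreases along phi.
    The convolution response is positive where the input increases along
    (cos phi, sin phi).
    """
    bank = FilterBank(kind="first_derivative", spec=spec)
    for j, freq in enumerate(spec.frequencies):
        sig_across = 0.5 / freq
        sig_along = length_ratio * sig_across
        d = 1.0 * sig_across
        half = _odd_support(d + 3.0 * sig_along)
        x, y = _grids(half)
        for i, theta in enumerate(spec.orientations):
            phi = theta + np.pi / 2
            px, py = d * np.cos(phi), d * np.sin(phi)
            # convolution flips the kernel: put the positive lobe at -phi so
            # that responses are positive for input increasing along +phi.
            pos = _aniso_gaussian(x, y, theta, sig_along, sig_across, -px, -py)
            neg = _aniso_gaussian(x, y, theta, sig_along, sig_across, px, py)
            k = pos / pos.sum() - neg / neg.sum()  # exact zero sum
            k /= np.abs(k).sum()
            bank.kernels[(i, j)] = KernelGrid(k, (half, half), half)
    return bank


# ---------------------------------------------------------------------------
# IT: one-sided signed integration lobes

def make_it_integration_bank(spec: FilterBankSpec,
                             sigma_dir: float | None = None,
                             perp_ratio: float = 1.0,
                             support_sigmas: float = 2.0) -> FilterBank:
    """Signed pair of large, sigmoid-truncated integration lobes.

    For channel theta the integration direction is phi = theta + pi/2 (IT
    integrates perpendicular to the orientation of the gradient cells it
    reads).  Each lobe is an anisotropic Gaussian multiplied by a 2D sigmoid
    of the coordinate along phi, which suppresses weight on the far side of
    the center: the positive lobe keeps the +phi side, the negative lobe
    (weights <= 0) the -phi side.  Via convolution the positive lobe
    accumulates positive gradient responses lying *behind* a location along
    phi, the negative lobe accumulates negative responses lying *ahead* —
    the two opposite paths of integration.

    ``spec.frequencies`` act as inverse length scales: sigma along the
    integration direction is ``0.5 / freq`` unless ``sigma_dir`` overrides.
    """
    if spec.sigmoid_sharpness <= 0:
        raise ValueError("sigmoid_sharpness must be positive")
    bank = FilterBank(kind="it_signed_lobes", spec=spec)
    for j, freq in enumerate(spec.frequencies):
        s_dir = sigma_dir if sigma_dir is not None else 0.5 / freq
        s_perp = perp_ratio * s_dir
        # IT lobes must stay heavy across the whole object: support is
        # truncated earlier than for the small banks (these fields are flat
        # rather than sharply tuned), keeping kernels tractable.
        half = _odd_support(support_sigmas * max(s_dir, s_perp))
        x, y = _grids(half)
        for i, theta in enumerate(spec.orientations):
            phi = theta + np.pi / 2
            w = x * np.cos(phi) + y * np.sin(phi)  # coordinate along phi
            env = _aniso_gaussian(x, y, theta, s_perp, s_dir)
            trunc = 1.0 / (1.0 + np.exp(-np.clip(spec.sigmoid_sharpness * w, -60, 60)))
            pos = env * trunc
            neg = env * (1.0 - trunc)
            pos /= pos.sum()
            neg = -neg / neg.sum()
            bank.kernels[(i, j)] = (
                KernelGrid(pos, (half, half), half),
                KernelGrid(neg, (half, half), half),
            )
    return bank
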
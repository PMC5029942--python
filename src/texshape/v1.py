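"""Module I — multi-frequency, multi-orientation texture-energy decomposition.

Model area V1.  The input image is filtered with quadrature Gabor pairs and
the texture energy is the amplitude of the complex response,
``sqrt(even^2 + odd^2)`` per (orientation, frequency) channel.  Because the
kernels are zero-mean, the decomposition is invariant to illumination
offsets.  The energy stack is then passed through the standard cascade
stage (normalization, optional feedback).
"""

from __future__ import annotations

import numpy as np

from ._conv import conv2
from .cascade import CascadeParams, check_stack, run_stage
from .filterbanks import FilterBank

__all__ = ["texture_energy", "band_normalize", "frequency_weights", "module_I"]


def _check_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2D grayscale image")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    return image


def texture_energy(image: np.ndarray, bank: FilterBank) -> np.ndarray:
    """Quadrature Gabor amplitude per (theta, omega): the texture energy."""
    image = _check_image(image)
    if bank.kind != "gabor":
        raise ValueError(f"texture_energy needs a gabor bank, got {bank.kind!r}")
    spec = bank.spec
    out = np.empty(image.shape + (spec.n_orientations, spec.n_frequencies))
    for (i, j), (even, odd) in bank.kernels.items():
        re = conv2(image, even.weights)
        im = conv2(image, odd.weights)
        out[:, :, i, j] = np.hypot(re, im)
    return out


def band_normalize(stack: np.ndarray, floor: float = 0.2) -> np.ndarray:
    """Normalize each frequency band by its mean response over the image.

    Divides every band by (band mean + floor * grand mean), so the bands
    contribute on a common footing regardless of how kernel scale and image
    contrast distribute absolute energy: what survives is the *relative*
    frequency energy, which is the depth-bearing signal (a compressed,
    foreshortened patch concentrates energy in bands that are quiet
    elsewhere and therefore stands out after normalization).  The floor
    keeps near-empty bands from amplifying their noise.
    """
    stack = check_stack(stack, "band_normalize input")
    band_mean = stack.mean(axis=(0, 1, 2), keepdims=True)
    grand = stack.mean()
    return stack / (band_mean + floor * grand + 1e-12)


def frequency_weights(freqs: np.ndarray, exponent: float = 1.0) -> np.ndarray:
    """Increasing per-band weights (f / f_min) ** exponent.

    Energy appearing in finer-scale bands contributes more summed activity:
    a compressed (receding or strongly slanted) patch spreads its spectrum
    into high bands and therefore drives the model harder, which is what
    lets spatial *gradients* of the summed activity point away from the
    viewer.
    """
    f = np.asarray(freqs, dtype=float)
    return (f / f.min()) ** exponent


def module_I(image: np.ndarray, bank: FilterBank, params: CascadeParams,
             feedback: np.ndarray | None = None,
             r_prev: np.ndarray | None = None,
             drive_gain: float = 1.0,
             band_norm_floor: float = 0.2,
             freq_weight_exp: float = 1.0,
             n_cycles: int = 2) -> np.ndarray:
    """Full module I stage: texture energy -> cascade normalization.

    ``feedback`` (from module II, matching feature grid) modulates the drive;
    ``r_prev`` is this module's activity from the previous model cycle and
    enters the feedback gate.  ``drive_gain`` scales the band-normalized
    Gabor amplitudes into the working range of the cascade.
    """
    w = frequency_weights(bank.spec.frequencies, freq_weight_exp)
    drive = drive_gain * band_normalize(texture_energy(image, bank),
                                        floor=band_norm_floor) * w
    drive = check_stack(drive, "module I drive")
    return run_stage(drive, params, feedback_source=feedback,
                     r_own_prev=r_prev, n_cycles=n_cycles)
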
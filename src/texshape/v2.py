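"""Module II — bipole long-range grouping of oriented texture energy.

Model area V2.  Each (theta, omega) channel of the module I stack is
filtered by the two lobes of the matching bipole kernel; the lobe outputs
are passed through a saturating transfer and *multiplied*, so a cell fires
only when both collinear subfields receive aligned input.  This bridges
gaps in dashed/ dotted structure and suppresses isolated responses.  The
summed module II activity is the quantity whose spatial gradients drive the
depth pathway, and whose orientation distribution yields slant/tilt.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._conv import conv2
from .cascade import CascadeParams, check_stack, run_stage
from .filterbanks import FilterBank

__all__ = ["bipole_combine", "module_II", "summarize", "V2Summary"]


def saturating_transfer(x: np.ndarray, scale: float = 1.0,
                        threshold: float = 0.0) -> np.ndarray:
    """Linear-above-threshold with soft (Naka-Rushton style) saturation."""
    y = np.maximum(x - threshold, 0.0)
    return y / (1.0 + y / scale)


def bipole_combine(v1: np.ndarray, lobes: FilterBank,
                   transfer_scale: float = 1.0) -> np.ndarray:
    """Multiplicative combination of the two bipole lobe responses.

    Zero whenever either subfield receives no input; maximal for input
    aligned along the cell's orientation on both sides.
    """
    v1 = check_stack(v1, "bipole_combine input")
    if lobes.kind != "bipole_lobes":
        raise ValueError(f"bipole_combine needs bipole lobes, got {lobes.kind!r}")
    spec = lobes.spec
    if v1.shape[2:] != (spec.n_orientations, spec.n_frequencies):
        raise ValueError(
            f"feature-grid mismatch: stack {v1.shape[2:]} vs bank "
            f"({spec.n_orientations}, {spec.n_frequencies})"
        )
    out = np.empty_like(v1)
    for (i, j), (l1, l2) in lobes.kernels.items():
        a = conv2(v1[:, :, i, j], l1.weights)
        b = conv2(v1[:, :, i, j], l2.weights)
        out[:, :, i, j] = (saturating_transfer(a, transfer_scale)
                           * saturating_transfer(b, transfer_scale))
    return out


def module_II(v1: np.ndarray, lobes: FilterBank, params: CascadeParams,
              feedback: np.ndarray | None = None,
              r_prev: np.ndarray | None = None,
              drive_gain: float = 4.0,
              n_cycles: int = 2) -> np.ndarray:
    """Full module II stage: bipole grouping -> cascade normalization."""
    drive = drive_gain * bipole_combine(v1, lobes)
    return run_stage(drive, params, feedback_source=feedback,
                     r_own_prev=r_prev, n_cycles=n_cycles)


@dataclass
class V2Summary:
    """Summed views of the module II stack.

    per_orientation — r^{II,S}: summed over frequency, shape (H, W, n_theta);
    total           — summed over all channels, shape (H, W);
    per_band        — the unchanged stack.
    """

    per_orientation: np.ndarray
    total: np.ndarray
    per_band: np.ndarray


def summarize(v2: np.ndarray) -> V2Summary:
    v2 = check_stack(v2, "summarize input")
    per_orientation = v2.sum(axis=3)
    return V2Summary(per_orientation=per_orientation,
                     total=per_orientation.sum(axis=2),
                     per_band=v2)
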
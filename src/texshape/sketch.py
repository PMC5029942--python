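"""Module III — the 2D sketch: borderlines of orientation-grouped regions.

Model area V4 (sketch pathway).  Per (theta, omega) channel, the grouped
module II activity is filtered with a second-derivative-like kernel (an
oriented edge/line detector), rectified into the cascade, sharpened with a
difference-of-Gaussians, and normalized.  The sketch is the maximum over
orientation and frequency: bright pixels mark boundaries and ridges —
occlusion borders and lines of minimal surface curvature.
"""

from __future__ import annotations

import numpy as np

from ._conv import conv2
from .cascade import CascadeParams, check_stack, run_stage
from .filterbanks import FilterBank, KernelGrid

__all__ = ["edge_line_responses", "dog_enhance", "sketch_from_v2"]


def edge_line_responses(v2: np.ndarray, bank: FilterBank,
                        routing: str = "per_channel") -> np.ndarray:
    """Oriented second-derivative responses to grouped activity, rectified.

    ``routing='per_channel'`` filters each (theta, omega) plane with its
    matching kernel; ``routing='per_band'`` filters the orientation-summed
    map of each frequency band with every orientation's kernel.
    """
    v2 = check_stack(v2, "edge_line_responses input")
    if bank.kind != "second_derivative":
        raise ValueError(f"expected second_derivative bank, got {bank.kind!r}")
    spec = bank.spec
    if v2.shape[2:] != (spec.n_orientations, spec.n_frequencies):
        raise ValueError("feature-grid mismatch between stack and bank")
    out = np.empty_like(v2)
    for (i, j), kern in bank.kernels.items():
        if routing == "per_channel":
            src = v2[:, :, i, j]
        elif routing == "per_band":
            src = v2[:, :, :, j].sum(axis=2)
        else:
            raise ValueError(f"unknown routing {routing!r}")
        out[:, :, i, j] = np.maximum(conv2(src, kern.weights), 0.0)
    return out


def dog_enhance(resp: np.ndarray, dog: KernelGrid) -> np.ndarray:
    """Center-surround sharpening of each channel, rectified."""
    resp = check_stack(resp, "dog_enhance input")
    out = np.empty_like(resp)
    for i in range(resp.shape[2]):
        for j in range(resp.shape[3]):
            out[:, :, i, j] = np.maximum(conv2(resp[:, :, i, j], dog.weights), 0.0)
    return out


def sketch_from_v2(v2: np.ndarray, bank: FilterBank, dog: KernelGrid,
                   params: CascadeParams,
                   feedback: np.ndarray | None = None,
                   r_prev: np.ndarray | None = None,
                   drive_gain: float = 40.0,
                   routing: str = "per_band",
                   pool_sigma: float = 6.0,
                   n_cycles: int = 2,
                   return_stack: bool = False):
    """Full module III cascade, then max over (theta, omega).

    The grouped input is spatially pooled first (``pool_sigma``): model V4
    receptive fields are larger than V1/V2 ones, and the sketch should mark
    boundaries between grouped *regions*, not individual texture elements.
    Returns the 2D sketch map (values in [0, beta/gamma], bright =
    boundary/ridge); with ``return_stack`` also the normalized stack, which
    is the module's feedback output to module II.
    """
    if pool_sigma > 0:
        from scipy.ndimage import gaussian_filter
        v2 = gaussian_filter(v2, (pool_sigma, pool_sigma, 0, 0), mode="reflect")
    resp = edge_line_responses(v2, bank, routing=routing)
    resp = dog_enhance(resp, dog)
    r = run_stage(drive_gain * resp, params, feedback_source=feedback,
                  r_own_prev=r_prev, n_cycles=n_cycles)
    sk = r.max(axis=(2, 3))
    return (sk, r) if return_stack else sk
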
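"""2D convolution helpers shared by all model areas.

All filtering uses true convolution (kernel flipped), "same" output size,
with reflect padding so that border responses do not masquerade as texture
gradients.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import fftconvolve

__all__ = ["conv2", "conv2_stack"]


def conv2(image: np.ndarray, kernel: np.ndarray, pad: str = "reflect") -> np.ndarray:
    """Convolve a 2D image with a 2D kernel, same size.

    ``pad='reflect'`` (default) avoids spurious border energy for the local
    filter banks; ``pad='zero'`` treats the world beyond the image as empty,
    which is what the large directed-integration fields require (reflection
    would mirror whole scene structure into the integration path).
    """
    if image.ndim != 2 or kernel.ndim != 2:
        raise ValueError("conv2 expects 2D arrays")
    if pad == "zero":
        return fftconvolve(image, kernel, mode="same")
    ph, pw = kernel.shape[0] // 2, kernel.shape[1] // 2
    padded = np.pad(image, ((ph, ph), (pw, pw)), mode="reflect")
    out = fftconvolve(padded, kernel, mode="valid")
    if out.shape != image.shape:  # even-sized kernel guard
        out = out[: image.shape[0], : image.shape[1]]
    return out


def conv2_stack(stack: np.ndarray, kernels) -> np.ndarray:
    """Convolve stack[..., i, j] channelwise with kernels[(i, j)]."""
    out = np.empty_like(stack, dtype=float)
    for i in range(stack.shape[2]):
        for j in range(stack.shape[3]):
            out[:, :, i, j] = conv2(stack[:, :, i, j], kernels[(i, j)])
    return out
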
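"""Module IV and whole-model orchestration: texture-energy gradients,
directed integration, feedback cycles and depth finalization.

The depth pathway reads the *total* module II activity (texture energy
grouped and summed over all orientations and frequencies).  Signed
first-derivative kernels measure its local change along each direction;
large one-sided IT lobes then integrate those signed responses along the
direction perpendicular to the gradient cells' orientation — one lobe
accumulating positive changes from one side, the opposite-sign lobe
accumulating negative changes from the other, with the maximum of the two
paths retained.  Summing all channels yields a raw activity field in which
larger values mean larger distance from the viewer; inversion, smoothing
and normalization produce the relative depth map (1 = nearest).

Because both integration paths are weighted equally, a surface patch that
could be convex or concave (e.g. a hemisphere) is resolved toward the
interpretation whose activity minimum — the near point — lies at its
center: the model prefers convexity, moving from regions of low activity to
high.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
from scipy.ndimage import gaussian_filter

from ._conv import conv2
from .cascade import CascadeParams, check_stack, feedback_signal, rect, run_stage, steady_state, inhibitory_pool
from .config import ModelConfig
from .filterbanks import (FilterBank, make_bipole_lobes, make_dog_kernel,
                          make_first_derivative_bank, make_gabor_bank,
                          make_it_integration_bank, make_second_derivative_bank)
from .orientation import SurfaceOrientationMap, orientation_map
from .sketch import sketch_from_v2
from .v1 import module_I
from .v2 import module_II, summarize

__all__ = [
    "DepthMap",
    "ModelOutput",
    "energy_gradient",
    "directed_integration",
    "depth_combine",
    "depth_finalize",
    "run_model",
    "contour_mode",
]


@dataclass
class DepthMap:
    """Relative depth: ``values`` in [0, 1] inside the mask (1 = nearest,
    NaN outside), the pre-inversion raw activity (higher = farther), and
    the binary object mask."""

    values: np.ndarray
    raw: np.ndarray
    mask: np.ndarray


@dataclass
class ModelOutput:
    depth: DepthMap
    sketch: np.ndarray
    orientation: SurfaceOrientationMap
    diagnostics: Dict[str, dict] = field(default_factory=dict)


# ---------------------------------------------------------------------------

def energy_gradient(total: np.ndarray, bank: FilterBank) -> np.ndarray:
    """Signed directional-derivative responses of the summed grouped energy.

    Channel (theta, scale) responds positively where the input increases
    along phi = theta + pi/2; zero over spatially constant activity, however
    anisotropic the underlying texture.
    """
    total = np.asarray(total, dtype=float)
    if total.ndim != 2:
        raise ValueError("energy_gradient expects the 2D summed activity map")
    if bank.kind != "first_derivative":
        raise ValueError(f"expected first_derivative bank, got {bank.kind!r}")
    spec = bank.spec
    out = np.empty(total.shape + (spec.n_orientations, spec.n_frequencies))
    for (i, j), kern in bank.kernels.items():
        out[:, :, i, j] = conv2(total, kern.weights)
    return out


def directed_integration(grad: np.ndarray, it_bank: FilterBank,
                         weights: Optional[np.ndarray] = None,
                         combine: str = "max",
                         softmax_beta: float = 8.0) -> np.ndarray:
    """One-sided integration of signed gradient responses by the IT lobes.

    The two lobes are the two opposite paths of integration.  Each lobe
    integrates the full *signed* gradient over its one-sided support: the
    positive lobe sums the changes lying behind a location along the
    integration direction (an activity estimate anchored on that side), and
    the negative-weight lobe the changes ahead — its sign flip makes
    activity *decreases* ahead count as positive depth, matching the sign
    of the gradient responses it reads.  The maximum of the two anchored
    estimates is kept and rectified, so depth at each point is measured
    from whichever side carries lower activity: ambiguous surfaces resolve
    toward convexity, climbing from low summed activity to high.

    ``weights`` (n_theta, n_scales, 2) optionally re-weights the two paths
    per channel (used by the contour-texture mode).  Result is nonnegative.
    """
    grad = check_stack(grad, "directed_integration input")
    if it_bank.kind != "it_signed_lobes":
        raise ValueError(f"expected it_signed_lobes bank, got {it_bank.kind!r}")
    spec = it_bank.spec
    if grad.shape[2:] != (spec.n_orientations, spec.n_frequencies):
        raise ValueError("feature-grid mismatch between gradient stack and IT bank")
    out = np.empty_like(grad)
    for (i, j), (pos, neg) in it_bank.kernels.items():
        g = grad[:, :, i, j]
        a = conv2(g, pos.weights, pad="zero")  # anchored behind, along +phi
        b = conv2(g, neg.weights, pad="zero")  # anchored ahead (sign-matched)
        wa, wb = (1.0, 1.0) if weights is None else weights[i, j]
        a, b = wa * a, wb * b
        if combine == "max":
            out[:, :, i, j] = rect(np.maximum(a, b))
        elif combine == "softmax":
            m = np.maximum(a, b)
            soft = m + np.log(
                np.exp(softmax_beta * (a - m)) + np.exp(softmax_beta * (b - m))
            ) / softmax_beta - np.log(2.0) / softmax_beta
            out[:, :, i, j] = rect(soft)
        else:
            raise ValueError(f"unknown combine {combine!r}")
    return out


def depth_combine(per_channel: np.ndarray, how: str = "sum") -> np.ndarray:
    """Combine integrated channels into the raw depth activity (nonnegative).

    ``how='sum'`` adds every (theta, scale) channel.  ``how='max_orientation'``
    takes the maximum over orientations before summing scales: each
    orientation channel is a path-based depth estimate that is only
    informative where its integration path actually crosses structure, and
    the best-informed direction should not be diluted by the silent ones
    (summing makes every enclosed region read as far simply because it is
    surrounded).
    """
    per_channel = check_stack(per_channel, "depth_combine input")
    if how == "sum":
        return per_channel.sum(axis=(2, 3))
    if how == "max_orientation":
        return per_channel.max(axis=2).sum(axis=2)
    raise ValueError(f"unknown combination {how!r}")


def depth_finalize(raw: np.ndarray, mask: np.ndarray,
                   smooth_sigma: float = 3.0) -> DepthMap:
    """Smooth, invert and normalize the raw activity into relative depth.

    Higher raw activity means farther away; the finalized map subtracts the
    smoothed activity from its in-mask maximum and divides by that maximum:
    1 marks the nearest point, and a spatially uniform activity field stays
    uniform (a frontoparallel plane finalizes flat rather than being
    stretched to full range).  Smoothing is mask-normalized so background
    zeros do not bleed in.  A constant raw field finalizes to a constant 0.
    """
    raw = np.asarray(raw, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if raw.shape != mask.shape:
        raise ValueError("raw field and mask shapes differ")
    if not mask.any():
        raise ValueError("empty mask")
    if not np.any(raw != 0):
        raise ValueError("all-zero raw depth field")
    if smooth_sigma > 0:
        m = mask.astype(float)
        num = gaussian_filter(raw * m, smooth_sigma, mode="reflect")
        den = gaussian_filter(m, smooth_sigma, mode="reflect")
        sm = np.where(den > 1e-9, num / np.maximum(den, 1e-9), 0.0)
    else:
        sm = raw.copy()
    inside = sm[mask]
    hi = inside.max()
    values = np.full(raw.shape, np.nan)
    values[mask] = 0.0 if hi < 1e-12 else (hi - sm[mask]) / hi
    return DepthMap(values=values, raw=raw, mask=mask)


# ---------------------------------------------------------------------------
# whole-model orchestration

@dataclass
class _Banks:
    gabor: FilterBank
    bipole: FilterBank
    secderiv: FilterBank
    dog: object
    grad: FilterBank
    it: FilterBank


def _build_banks(config: ModelConfig, mask: np.ndarray,
                 field_scale: float = 1.0) -> _Banks:
    it_sigma = config.it_sigma_dir
    if it_sigma is None:
        # IT fields cover a large part of the visual field: the anchored
        # integration must span the whole object *and* its background so
        # both paths can reach a low-activity anchor.
        it_sigma = max(config.it_sigma_factor * max(mask.shape), 8.0)
    return _Banks(
        gabor=make_gabor_bank(config.gabor_spec()),
        bipole=make_bipole_lobes(config.bipole_spec(),
                                 length_factor=config.bipole_length_factor),
        secderiv=make_second_derivative_bank(config.sketch_spec()),
        dog=make_dog_kernel(config.dog_sigma_center, config.dog_sigma_surround),
        grad=make_first_derivative_bank(config.grad_spec()),
        it=make_it_integration_bank(config.it_spec(),
                                    sigma_dir=it_sigma * field_scale,
                                    perp_ratio=config.it_perp_ratio,
                                    support_sigmas=config.it_support_sigmas),
    )


def _map_scales_to(stack: np.ndarray, src_freqs: np.ndarray,
                   dst_freqs: np.ndarray) -> np.ndarray:
    """Resample the frequency axis of a stack to another module's bands by
    nearest log-frequency match (feedback is delivered to matching features)."""
    idx = [int(np.argmin(np.abs(np.log(src_freqs) - np.log(f)))) for f in dst_freqs]
    return stack[:, :, :, idx]


def _stage_with_net(drive: np.ndarray, p: CascadeParams, net,
                    n_inner: int = 2) -> np.ndarray:
    """Cascade stage with a precomputed (possibly summed) feedback net."""
    r = steady_state(drive, net, 0.0, p)
    for _ in range(n_inner - 1):
        q = inhibitory_pool(r, p)
        r = steady_state(drive, net, q, p)
    return r


def _module_IV(total: np.ndarray, banks: _Banks, config: ModelConfig,
               weights: Optional[np.ndarray] = None) -> tuple[np.ndarray, np.ndarray]:
    # V4 receptive fields are larger than V1's: pool the summed activity
    # before differentiation so texture-element granularity does not
    # masquerade as depth structure.
    if config.total_pool_sigma > 0:
        total = gaussian_filter(total, config.total_pool_sigma, mode="reflect")
    grad = energy_gradient(total, banks.grad)
    integ = directed_integration(grad, banks.it, weights=weights,
                                 combine=config.it_combine,
                                 softmax_beta=config.it_softmax_beta)
    r4 = run_stage(config.gain_IV * integ, config.params_IV, n_cycles=2)
    return r4, grad


def run_model(image: np.ndarray, mask: Optional[np.ndarray] = None,
              config: Optional[ModelConfig] = None,
              feedback: Optional[bool] = None,
              n_cycles: Optional[int] = None,
              it_weights: Optional[np.ndarray] = None,
              field_scale: float = 1.0) -> ModelOutput:
    """Run the full hierarchy I -> II -> {III, IV} with feedback cycles.

    Deterministic given (image, mask, config).  Cycle 1 is the pure
    feedforward sweep; subsequent cycles recompute every module with
    synchronous modulatory feedback (IV and III down to II, II down to I)
    from the previous cycle's activities.  Diagnostics retain the summed
    activity map of each module for the feedforward sweep and the final
    state, plus the per-cycle maximum state change.
    """
    config = config or ModelConfig()
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("run_model expects a 2D grayscale image")
    if mask is None:
        mask = np.ones(image.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ValueError("mask shape must match image shape")
    use_fb = config.feedback if feedback is None else feedback
    cycles = config.n_cycles if n_cycles is None else n_cycles

    banks = _build_banks(config, mask, field_scale=field_scale)
    freqs = config.gabor_spec().frequencies
    grad_freqs = config.grad_spec().frequencies

    diagnostics: Dict[str, dict] = {"cycle_change": []}

    def sweep(r1p=None, r2p=None, r3p=None, r4p=None):
        """One synchronous model sweep; previous-cycle states drive feedback."""
        if use_fb and r2p is not None:
            net1 = feedback_signal(r1p, r2p,
                                   config.params_I.replace(fb_gain=config.fb_gain_II_to_I))
            if config.fb_gain_IV_to_I > 0 and r4p is not None:
                net1 = net1 + feedback_signal(
                    r1p, _map_scales_to(r4p, grad_freqs, freqs),
                    config.params_I.replace(fb_gain=config.fb_gain_IV_to_I))
        else:
            net1 = 0.0
        from .v1 import band_normalize, frequency_weights, texture_energy
        wfreq = frequency_weights(freqs, config.freq_weight_exp)
        drive1 = config.gain_I * band_normalize(texture_energy(image, banks.gabor),
                                                floor=config.band_norm_floor) * wfreq
        r1 = _stage_with_net(drive1, config.params_I, net1)

        if use_fb and r4p is not None:
            net2 = feedback_signal(r2p, _map_scales_to(r4p, grad_freqs, freqs),
                                   config.params_II.replace(fb_gain=config.fb_gain_IV_to_II))
            if config.fb_gain_III_to_II > 0 and r3p is not None:
                net2 = net2 + feedback_signal(
                    r2p, r3p,
                    config.params_II.replace(fb_gain=config.fb_gain_III_to_II))
        else:
            net2 = 0.0
        from .v2 import bipole_combine
        drive2 = config.gain_II * bipole_combine(r1, banks.bipole,
                                                 transfer_scale=config.transfer_scale)
        r2 = _stage_with_net(drive2, config.params_II, net2)

        sk, r3 = sketch_from_v2(r2, banks.secderiv, banks.dog, config.params_III,
                                drive_gain=config.gain_III,
                                routing=config.sketch_routing,
                                pool_sigma=config.sketch_pool_sigma,
                                return_stack=True)
        total = summarize(r2).total
        r4, grad = _module_IV(total, banks, config, weights=it_weights)
        return r1, r2, r3, r4, sk, total

    r1, r2, r3, r4, sk, total = sweep()
    diagnostics["feedforward"] = {
        "I": r1.sum(axis=(2, 3)), "II": total, "III": sk,
        "IV": depth_combine(r4, how=config.depth_combine),
    }

    for _ in range(1, max(cycles, 1)):
        if not use_fb:
            break
        r1n, r2n, r3n, r4n, sk, total = sweep(r1, r2, r3, r4)
        change = max(np.abs(r1n - r1).max(), np.abs(r2n - r2).max(),
                     np.abs(r4n - r4).max())
        diagnostics["cycle_change"].append(float(change))
        r1, r2, r3, r4 = r1n, r2n, r3n, r4n
        if change < config.early_stop_tol:
            break

    raw = depth_combine(r4, how=config.depth_combine)
    diagnostics["final"] = {"I": r1.sum(axis=(2, 3)), "II": total,
                            "III": sk, "IV": raw}
    depth = depth_finalize(raw, mask, smooth_sigma=config.smooth_sigma)
    omap = orientation_map(summarize(r2).per_orientation,
                           config.gabor_spec().orientations,
                           patch_sigma=config.patch_sigma)
    return ModelOutput(depth=depth, sketch=sk, orientation=omap,
                       diagnostics=diagnostics)


def contour_mode(image: np.ndarray, mask: Optional[np.ndarray],
                 integration_direction: Optional[float],
                 config: Optional[ModelConfig] = None) -> ModelOutput:
    """Depth for contour/planar-cut textures with a caller-supplied
    integration direction (radians, image convention: +x right, +y down).

    Contour textures do not disambiguate the integration direction, so it
    must be supplied — never guessed.  The IT lobe integrating along the
    supplied direction keeps full weight; the opposite path and misaligned
    channels are down-weighted, and the gradient/IT fields are enlarged to
    span the whole object.
    """
    if integration_direction is None:
        raise ValueError("contour_mode requires an explicit integration direction")
    config = config or ModelConfig()
    spec = config.grad_spec()
    psi = float(integration_direction)
    weights = np.zeros((spec.n_orientations, spec.n_frequencies, 2))
    for i, theta in enumerate(spec.orientations):
        phi = theta + np.pi / 2  # integration direction of channel i's A-path
        c = np.cos(phi - psi)
        align = abs(c)
        wa = align * (1.0 if c >= 0 else config.contour_minor_weight)
        wb = align * (config.contour_minor_weight if c >= 0 else 1.0)
        for j in range(spec.n_frequencies):
            weights[i, j] = (wa, wb)
    return run_model(image, mask, config, it_weights=weights,
                     field_scale=config.contour_field_scale)
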
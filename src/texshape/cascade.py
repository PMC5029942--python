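"""Generic three-stage column dynamics shared by all four model areas.

Each model area applies the same steady-state computation to its own,
area-specific filter output ("drive"):

1. *filtering* — the drive ``f(F(r0))``, nonnegative;
2. *modulatory feedback* — re-entrant input from a higher area multiplies
   the drive as ``(1 + net)``; feedback can enhance existing activity but
   never create it;
3. *center-surround normalization* — subtractive and divisive inhibition by
   a pool ``q`` of activity across the feature domain and a spatial
   neighborhood.

The steady-state response is

    r = rect( (beta * d * (1 + net) - xi * q + eta)
              / (alpha + gamma * d * (1 + net) + q) )

which is bounded above by beta/gamma as drive and/or feedback grow large,
and below by -xi before rectification.  The inhibitory pool is

    q_{i,feat} = delta * ( sum_feat r_{i,feat}
                           + eps * sum_j max_feat(r_{j,feat}) * pool_{ij} )

(only the feature maximum enters the spatial term), and the feedback signal

    net_{i,feat} = rect(lambda_fb - r^{own}_{i,feat})
                   * gain * mean_{neighborhood}( r^{higher}_{feat} )

where the bracket gates feedback away from units that are already strongly
active — the mechanism by which re-entrant signals flatten ridges and
suppress noise rather than amplify winners.

Feature stacks are arrays shaped (rows, cols, n_orientations, n_frequencies);
``FeatureStack`` values are nonnegative (post-rectification), ``SignedStack``
values may carry sign (pre-rectification / gradient responses).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter, uniform_filter

__all__ = [
    "CascadeParams",
    "rect",
    "check_stack",
    "inhibitory_pool",
    "feedback_signal",
    "steady_state",
    "run_stage",
]


@dataclass
class CascadeParams:
    """Constants of the steady-state equations for one model area.

    beta/gamma set the saturation bound; alpha the degree of linearity
    (contrast-gain); xi the subtractive inhibition strength; delta scales
    the pool; epsilon weighs the spatial pool term against the feature-domain
    term; lambda_fb caps how much feedback a unit may receive; eta is a
    baseline (default 0 so zero input maps to zero output exactly);
    pool_sigma (pixels) is the scale of the isotropic Gaussian pool kernel,
    truncated at 3 sigma.
    """

    beta: float = 2.0
    xi: float = 1.0
    eta: float = 0.0
    alpha: float = 0.5
    gamma: float = 1.0
    delta: float = 0.2
    epsilon: float = 0.5
    lambda_fb: float = 1.0
    pool_sigma: float = 3.0
    fb_gain: float = 1.0
    fb_radius: int = 5  # half-size of the unweighted feedback neighborhood

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        for name in ("beta", "xi", "eta", "delta", "epsilon", "lambda_fb"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def replace(self, **kw) -> "CascadeParams":
        return replace(self, **kw)

    @property
    def bound(self) -> float:
        """Upper bound of the rectified steady-state response."""
        return self.beta / self.gamma + (self.eta / self.alpha if self.alpha > 0 else 0.0)


def rect(x: np.ndarray) -> np.ndarray:
    """Halfwave rectification max(x, 0)."""
    return np.maximum(x, 0.0)


def check_stack(x: np.ndarray, context: str = "stack") -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 4:
        raise ValueError(f"{context}: expected (rows, cols, n_theta, n_freq), got {x.shape}")
    if not np.all(np.isfinite(x)):
        raise FloatingPointError(f"{context}: non-finite values")
    return x


def inhibitory_pool(r: np.ndarray, p: CascadeParams) -> np.ndarray:
    """Pooled inhibition q: feature-domain sum plus spatial pooled feature max.

    The feature term sums all (theta, omega) channels at each location; the
    spatial term Gaussian-pools the per-location feature *maximum* (only the
    maximum of the neighborhood responses is summed, for speed and
    winner-dominated competition).  q is identical across channels at a
    location and broadcast back to the full stack shape.
    """
    r = check_stack(r, "inhibitory_pool input")
    feat_sum = r.sum(axis=(2, 3))
    feat_max = r.max(axis=(2, 3))
    spatial = gaussian_filter(feat_max, p.pool_sigma, mode="reflect", truncate=3.0)
    q2d = p.delta * (feat_sum + p.epsilon * spatial)
    return np.broadcast_to(q2d[:, :, None, None], r.shape).copy()


def feedback_signal(r_own: np.ndarray, r_higher: np.ndarray, p: CascadeParams) -> np.ndarray:
    """Modulatory feedback net = rect(lambda_fb - r_own) * pooled higher activity.

    ``r_higher`` must already be resampled to the receiving area's
    (theta, omega) grid; the pooled term is an unweighted average over a
    square spatial neighborhood of half-size ``fb_radius`` at the matching
    feature channel.
    """
    r_own = check_stack(r_own, "feedback_signal own activity")
    r_higher = check_stack(r_higher, "feedback_signal higher activity")
    if r_own.shape != r_higher.shape:
        raise ValueError(
            f"feature-grid mismatch between modules: {r_own.shape} vs {r_higher.shape}"
        )
    size = 2 * p.fb_radius + 1
    pooled = uniform_filter(r_higher, size=(size, size, 1, 1), mode="reflect")
    return rect(p.lambda_fb - r_own) * p.fb_gain * pooled


def steady_state(drive: np.ndarray, net: np.ndarray | float,
                 q: np.ndarray | float, p: CascadeParams) -> np.ndarray:
    """Rectified steady-state response of the shunting equation."""
    drive = np.asarray(drive, dtype=float)
    mod = drive * (1.0 + net)
    denom = p.alpha + p.gamma * mod + q
    if np.any(denom <= 0):
        raise FloatingPointError("steady_state: nonpositive denominator (need alpha > 0)")
    r = (p.beta * mod - p.xi * np.asarray(q) + p.eta) / denom
    return rect(r)


def run_stage(drive: np.ndarray, p: CascadeParams,
              feedback_source: np.ndarray | None = None,
              r_own_prev: np.ndarray | None = None,
              n_cycles: int = 1) -> np.ndarray:
    """One model-area stage: feedback modulation + pool normalization.

    ``drive`` is the area-specific filter output f(F(r0)), already
    rectified.  With ``feedback_source`` absent the pass is purely
    feedforward (net = 0).  The pool q depends on the stage's own output,
    so the q/r fixed point is iterated ``n_cycles`` times starting from
    q = 0; activity is bounded, so a couple of iterations settle it.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    drive = check_stack(drive, "run_stage drive")
    if feedback_source is None:
        net: np.ndarray | float = 0.0
    else:
        own = r_own_prev if r_own_prev is not None else np.zeros_like(drive)
        net = feedback_signal(own, feedback_source, p)
    q: np.ndarray | float = 0.0
    r = steady_state(drive, net, q, p)
    for _ in range(n_cycles - 1):
        q = inhibitory_pool(r, p)
        r = steady_state(drive, net, q, p)
    if not np.all(np.isfinite(r)):
        raise FloatingPointError("run_stage: non-finite stage output")
    return r
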
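"""Synthetic textured-surface stimuli with exact ground-truth depth.

Height-field surfaces (slanted plane, plane + semisphere, bell, doubly
curved object, multi-level depth steps, cylinder, sinusoidal inclined
plane) are covered with procedural textures (noisy polka dots, anisotropic
dots, contour lines, correlated noise) and imaged under orthographic or
perspective (pinhole) projection.  Textures are parameterized in *surface*
coordinates — per-axis arc length — so that slant and curvature compress
the projected texture exactly as foreshortening demands (an orthographic
plane at slant s renders circular dots with minor/major axis ratio cos s),
while under orthographic projection element size carries no distance cue.

Rendering is nearest-surface ray casting on the height field; there is no
shading — texture is the only depth cue, by design.  A (spec, seed) pair
fully determines the render.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

__all__ = [
    "SceneSpec",
    "RenderedScene",
    "normalize01",
    "make_height_field",
    "make_texture",
    "render",
    "measure_dots",
]


SHAPES = ("flat", "slanted_plane", "plane_plus_semisphere", "bell",
          "doubly_curved", "depth_steps", "cylinder", "sinusoidal_plane")
TEXTURES = ("polka", "anisotropic_dots", "contour_lines", "noise")


@dataclass
class SceneSpec:
    """Declarative description of one synthetic stimulus."""

    shape: str = "flat"
    shape_params: Dict = dc_field(default_factory=dict)
    texture: str = "polka"
    texture_params: Dict = dc_field(default_factory=dict)
    projection: str = "orthographic"
    fov_deg: float = 50.0
    image_size: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.texture not in TEXTURES:
            raise ValueError(f"unknown texture {self.texture!r}")
        if self.projection not in ("orthographic", "perspective"):
            raise ValueError(f"unknown projection {self.projection!r}")
        if self.projection == "perspective" and not (0 < self.fov_deg < 180):
            raise ValueError("perspective fov must be in (0, 180) degrees")

    def to_dict(self) -> dict:
        import dataclasses
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SceneSpec":
        return cls(**d)


@dataclass
class RenderedScene:
    """Image in [0,1], ground-truth relative depth (1 = nearest, NaN outside
    the mask), binary mask and full provenance."""

    image: np.ndarray
    depth_truth: np.ndarray
    mask: np.ndarray
    spec: SceneSpec


def normalize01(values: np.ndarray, mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Min-max normalize inside the mask (idempotent); constant maps to 0.

    Outside-mask entries are NaN in the result.
    """
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.ones(values.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    out = np.full(values.shape, np.nan)
    inside = values[mask]
    lo, hi = np.min(inside), np.max(inside)
    out[mask] = 0.0 if hi - lo < 1e-12 else (inside - lo) / (hi - lo)
    return out


# ---------------------------------------------------------------------------
# height fields

def make_height_field(spec: SceneSpec) -> Tuple[np.ndarray, np.ndarray]:
    """Analytic height (toward the viewer, world units = pixels at the image
    plane) and the binary object mask, on the image-sized grid."""
    n = spec.image_size
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    return _height_mask(spec, xx - c, yy - c)


def _height_mask(spec: SceneSpec, x: np.ndarray, y: np.ndarray
                 ) -> Tuple[np.ndarray, np.ndarray]:
    """Height and mask evaluated at centered world coordinates (x, y);
    the perspective renderer evaluates on a canvas larger than the image."""
    n = spec.image_size
    c = (n - 1) / 2.0
    p = spec.shape_params
    scale = n / 300.0
    mask = np.ones(x.shape, dtype=bool)

    if spec.shape == "flat":
        h = np.zeros(x.shape)
    elif spec.shape == "slanted_plane":
        s = np.deg2rad(p.get("slant_deg", 50.0))
        tilt = np.deg2rad(p.get("tilt_deg", 90.0))  # recession axis; 90 = vertical
        w = x * np.cos(tilt) + y * np.sin(tilt)
        h = -np.tan(s) * w
    elif spec.shape == "plane_plus_semisphere":
        R = p.get("radius", 70.0 * scale)
        rho2 = x**2 + y**2
        h = np.sqrt(np.maximum(R**2 - rho2, 0.0))
        mask = rho2 <= R**2  # the object is the sphere; the plane is ground
    elif spec.shape == "bell":
        # compact-support bell: raised-cosine profile, so the slant grows
        # from the apex and the object has a definite boundary (mask)
        R = p.get("radius", 90.0 * scale)
        amp = p.get("amplitude", 55.0 * scale)
        sign = 1.0 if p.get("sign", "convex") == "convex" else -1.0
        rho = np.hypot(x, y)
        prof = np.where(rho < R, np.cos(np.pi * np.minimum(rho / R, 1.0) / 2), 0.0)
        h = sign * amp * prof
        mask = rho < R
    elif spec.shape == "doubly_curved":
        # flattened spherical cap carrying a secondary bump and a dip:
        # convex and concave curvature on one object with a true boundary
        R = p.get("radius", 115.0 * scale)
        flat = p.get("flatten", 0.7)
        a2 = p.get("bump_amp", 14.0 * scale)
        w2 = p.get("bump_width", 36.0 * scale)
        a3 = p.get("dip_amp", 9.0 * scale)
        w3 = p.get("dip_width", 40.0 * scale)
        rho2 = x**2 + y**2
        cap = flat * np.sqrt(np.maximum(R**2 - rho2, 0.0))
        inside = rho2 < R**2
        ox, oy = 42.0 * scale, -28.0 * scale
        px, py = -48.0 * scale, 32.0 * scale
        h = cap + inside * (
            a2 * np.exp(-((x - ox)**2 + (y - oy)**2) / (2 * w2**2))
            - a3 * np.exp(-((x - px)**2 + (y - py)**2) / (2 * w3**2)))
        mask = inside
    elif spec.shape == "depth_steps":
        levels = int(p.get("levels", 4))
        step = p.get("step_height", 30.0 * scale)
        trans = p.get("transition_width", 9.0 * scale)
        axis = p.get("axis", "y")
        w = y if axis == "y" else x
        edges = np.linspace(-c, c, levels + 1)[1:-1]
        h = np.zeros(x.shape)
        for e in edges:
            h = h - step / (1.0 + np.exp(-np.clip((w - e) / trans, -60, 60)))
    elif spec.shape == "cylinder":
        R = p.get("radius", 80.0 * scale)
        a = np.deg2rad(p.get("axis_deg", 90.0))
        d = np.abs(-x * np.sin(a) + y * np.cos(a))
        h = np.sqrt(np.maximum(R**2 - d**2, 0.0))
        mask = d < R
    elif spec.shape == "sinusoidal_plane":
        s = np.deg2rad(p.get("slant_deg", 45.0))
        rot = np.deg2rad(p.get("wave_deg", 0.0))
        lam = p.get("wavelength", 80.0 * scale)
        amp = p.get("amplitude", 18.0 * scale)
        w = x * np.cos(rot) + y * np.sin(rot)
        h = -np.tan(s) * y * 0.4 + amp * np.sin(2 * np.pi * w / lam)
    else:  # pragma: no cover - guarded by SceneSpec
        raise ValueError(spec.shape)
    for key, val in p.items():
        if key in ("levels",):
            continue
        if isinstance(val, (int, float)) and val <= 0 and key.endswith(("radius", "width", "height", "amp")):
            raise ValueError(f"geometric parameter {key} must be positive")
    return h, mask


# ---------------------------------------------------------------------------
# procedural textures (analytic samplers in surface coordinates)

def _hash01(ix: np.ndarray, iy: np.ndarray, seed: int, salt: int) -> np.ndarray:
    """Deterministic per-cell pseudo-random value in [0, 1)."""
    h = (ix.astype(np.uint64) * np.uint64(0x9E3779B97F4A7C15)
         ^ iy.astype(np.uint64) * np.uint64(0xC2B2AE3D27D4EB4F)
         ^ np.uint64(seed * 0x165667B1 + salt * 0x85EBCA77))
    h ^= h >> np.uint64(33)
    h *= np.uint64(0xFF51AFD7ED558CCD)
    h ^= h >> np.uint64(33)
    return (h >> np.uint64(11)).astype(float) / float(1 << 53)


def _soft(x: np.ndarray, edge: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x / edge, -60, 60)))


def _dots_sampler(u, v, *, spacing, dot_radius, jitter, seed,
                  axis_ratio=1.0, axis_deg=0.0, edge=1.0, period_cells=64,
                  contrast=0.9):
    """Dark soft dots on a jittered lattice, evaluated at surface coords."""
    iu = np.floor(u / spacing).astype(np.int64)
    iv = np.floor(v / spacing).astype(np.int64)
    a = np.deg2rad(axis_deg)
    ca, sa = np.cos(a), np.sin(a)
    acc = np.zeros_like(np.asarray(u, dtype=float))
    for ou in (-1, 0, 1):
        for ov in (-1, 0, 1):
            cu_i, cv_i = iu + ou, iv + ov
            hu_i = np.mod(cu_i, period_cells)
            hv_i = np.mod(cv_i, period_cells)
            jx = (_hash01(hu_i, hv_i, seed, 1) - 0.5) * jitter * spacing
            jy = (_hash01(hu_i, hv_i, seed, 2) - 0.5) * jitter * spacing
            cx = (cu_i + 0.5) * spacing + jx
            cy = (cv_i + 0.5) * spacing + jy
            du, dv = u - cx, v - cy
            # elliptical dots: major axis along axis_deg, ratio major/minor
            pa = (du * ca + dv * sa) / axis_ratio
            pb = -du * sa + dv * ca
            d = np.hypot(pa, pb)
            acc = np.maximum(acc, _soft(dot_radius - d, edge))
    return 1.0 - contrast * acc


def _contour_sampler(u, v, *, spacing, orientation_deg, line_width, edge=0.8,
                     contrast=0.9):
    a = np.deg2rad(orientation_deg)
    # lines run along the orientation axis; phase varies perpendicular to it
    w = -u * np.sin(a) + v * np.cos(a)
    d = np.abs(w - np.round(w / spacing) * spacing)
    return 1.0 - contrast * _soft(line_width / 2.0 - d, edge)


def _noise_patch(seed: int, corr: float, size: int = 256) -> np.ndarray:
    rng = np.random.default_rng(seed)
    g = rng.standard_normal((size, size))
    g = gaussian_filter(g, corr, mode="wrap")
    g = (g - g.mean()) / (g.std() + 1e-12)
    return np.clip(0.55 + 0.28 * g, 0.0, 1.0)


def _texture_defaults(spec: SceneSpec) -> dict:
    p = dict(spec.texture_params)
    if spec.texture in ("polka", "anisotropic_dots"):
        p.setdefault("spacing", 16.0)
        p.setdefault("dot_radius", 5.0)
        p.setdefault("jitter", 0.5)
        if spec.texture == "anisotropic_dots":
            p.setdefault("axis_ratio", 2.5)
            p.setdefault("axis_deg", 0.0)
        else:
            p["axis_ratio"], p["axis_deg"] = 1.0, 0.0
    elif spec.texture == "contour_lines":
        p.setdefault("spacing", 12.0)
        p.setdefault("orientation_deg", 0.0)
        p.setdefault("line_width", 3.0)
    elif spec.texture == "noise":
        p.setdefault("correlation_length", 2.5)
    return p


def _sample_texture(spec: SceneSpec, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    p = _texture_defaults(spec)
    if spec.texture in ("polka", "anisotropic_dots"):
        return _dots_sampler(u, v, spacing=p["spacing"], dot_radius=p["dot_radius"],
                             jitter=p["jitter"], seed=spec.seed,
                             axis_ratio=p["axis_ratio"], axis_deg=p["axis_deg"])
    if spec.texture == "contour_lines":
        return _contour_sampler(u, v, spacing=p["spacing"],
                                orientation_deg=p["orientation_deg"],
                                line_width=p["line_width"])
    patch = _noise_patch(spec.seed, p["correlation_length"])
    coords = np.stack([np.mod(v, patch.shape[0]), np.mod(u, patch.shape[1])])
    return map_coordinates(patch, coords, order=1, mode="grid-wrap")


def make_texture(spec: SceneSpec, period: Optional[int] = None) -> np.ndarray:
    """Frontal texture patch on a regular grid (seeded, wrap-periodic)."""
    n = period or spec.image_size
    vv, uu = np.mgrid[0:n, 0:n].astype(float)
    return _sample_texture(spec, uu, vv)


# ---------------------------------------------------------------------------
# rendering

def _arc_length_coords(h: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Per-axis cumulative surface arc length, anchored at the image center.

    Texture coordinates measured along the surface reproduce foreshortening:
    a plane at slant s is compressed by cos s along the recession axis.
    """
    c = h.shape[0] // 2
    hx = np.gradient(h, axis=1)
    hy = np.gradient(h, axis=0)
    du = np.sqrt(1.0 + hx**2)
    dv = np.sqrt(1.0 + hy**2)
    u = np.cumsum(du, axis=1)
    v = np.cumsum(dv, axis=0)
    u -= u[:, c:c + 1]
    v -= v[c:c + 1, :]
    return u, v


def render(spec: SceneSpec) -> RenderedScene:
    """Texture-map the height field and project it; returns image + truth.

    Orthographic: parallel rays, element size carries no distance cue.
    Perspective: pinhole camera whose distance is set by the field of view
    (the h=0 plane maps 1:1), intersected with the height field by
    fixed-point ray iteration.  Ground-truth depth is the camera z-distance,
    min-max normalized with 1 = nearest.
    """
    n = spec.image_size
    c = (n - 1) / 2.0

    if spec.projection == "orthographic":
        h, mask = make_height_field(spec)
        u_map, v_map = _arc_length_coords(h)
        u, v, z, m = u_map, v_map, -h, mask
    else:
        D = (n / 2.0) / np.tan(np.deg2rad(spec.fov_deg) / 2.0)
        # the world footprint of rays hitting surface below the image plane
        # exceeds the image: evaluate the height field on an enlarged canvas
        h0, _ = make_height_field(spec)
        ext = int(np.ceil(c * max((D - h0.min()) / D - 1.0, 0.0))) + 4
        m_side = n + 2 * ext
        yy, xx = np.mgrid[0:m_side, 0:m_side]
        cc = c + ext
        h, mask_big = _height_mask(spec, xx - cc, yy - cc)
        u_map, v_map = _arc_length_coords(h)
        yy, xx = np.mgrid[0:n, 0:n]
        ax, ay = (xx - c).astype(float), (yy - c).astype(float)
        xw = ax + cc
        yw = ay + cc
        zs = np.zeros((n, n))
        for _ in range(25):
            coords = np.stack([yw, xw])
            zs = map_coordinates(h, coords, order=1, mode="nearest")
            xw = cc + ax * (D - zs) / D
            yw = cc + ay * (D - zs) / D
        coords = np.stack([yw, xw])
        u = map_coordinates(u_map, coords, order=1, mode="nearest")
        v = map_coordinates(v_map, coords, order=1, mode="nearest")
        m = map_coordinates(mask_big.astype(float), coords, order=0,
                            mode="nearest") > 0.5
        z = D - zs

    img = _sample_texture(spec, u, v)
    img = gaussian_filter(img, 0.6, mode="reflect")
    img = np.round(np.clip(img, 0.0, 1.0) * 255.0) / 255.0
    truth = normalize01(-z, m)  # larger -z = nearer; 1 = nearest
    return RenderedScene(image=img, depth_truth=truth, mask=m, spec=spec)


# ---------------------------------------------------------------------------
# measurement helper (used to validate foreshortening on renders)

def measure_dots(image: np.ndarray, min_area: int = 12):
    """Fit ellipses to the dark dots of a rendered dot texture.

    Returns (axis_ratios, orientations, areas): per-dot minor/major axis
    ratio, major-axis orientation in radians within [0, pi) measured from
    the image +x axis (y down), and pixel area.  Border-touching and
    merged blobs are excluded.
    """
    from skimage import measure as skmeasure

    img = np.asarray(image, dtype=float)
    thr = 0.5 * (img.min() + img.max())
    labels = skmeasure.label(img < thr)
    ratios, angles, areas = [], [], []
    h, w = img.shape
    for reg in skmeasure.regionprops(labels):
        if reg.area < min_area or reg.axis_major_length < 1e-6:
            continue
        r0, c0, r1, c1 = reg.bbox
        if r0 == 0 or c0 == 0 or r1 == h or c1 == w:
            continue
        ratio = reg.axis_minor_length / reg.axis_major_length
        # regionprops orientation: angle from the row axis, CCW; convert to
        # angle from +x with y down, axial in [0, pi)
        ang = np.mod(np.pi / 2.0 - reg.orientation, np.pi)
        ratios.append(ratio)
        angles.append(ang)
        areas.append(reg.area)
    return np.asarray(ratios), np.asarray(angles), np.asarray(areas)
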
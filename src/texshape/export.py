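"""File exports: depth as 16-bit PNG / text matrix / OBJ mesh, sketch and
kernel-gallery PNGs, profile CSVs."""

from __future__ import annotations

import csv
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .filterbanks import FilterBank

__all__ = [
    "save_image_png",
    "save_depth",
    "save_obj_heightfield",
    "save_profile_csv",
    "save_kernel_gallery",
    "save_stack_grid",
    "save_orientation_overlay",
]


def _finite01(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    a = np.where(np.isfinite(a), a, 0.0)
    hi = a.max()
    return a / hi if hi > 0 else a


def save_image_png(path, image: np.ndarray) -> None:
    """8-bit grayscale PNG; input scaled to its own maximum."""
    iio.imwrite(Path(path), (255 * _finite01(image)).astype(np.uint8))


def save_depth(path_stem, depth: np.ndarray) -> None:
    """16-bit PNG plus plain-text matrix (NaN preserved in the text form)."""
    stem = Path(path_stem)
    iio.imwrite(stem.with_suffix(".png"),
                (65535 * _finite01(depth)).astype(np.uint16))
    np.savetxt(stem.with_suffix(".txt"), np.asarray(depth, dtype=float), fmt="%.6f")


def save_obj_heightfield(path, depth: np.ndarray, z_scale: float = 60.0,
                         stride: int = 2) -> None:
    """Wavefront OBJ height field of the relative depth map (1 = nearest)."""
    d = np.asarray(depth, dtype=float)
    d = np.where(np.isfinite(d), d, 0.0)[::stride, ::stride]
    h, w = d.shape
    with open(path, "w") as fh:
        for r in range(h):
            for c in range(w):
                fh.write(f"v {c} {h - 1 - r} {z_scale * d[r, c]:.4f}\n")
        for r in range(h - 1):
            for c in range(w - 1):
                i = r * w + c + 1
                fh.write(f"f {i} {i + 1} {i + w + 1} {i + w}\n")


def save_profile_csv(path, index_axis: str, model: np.ndarray,
                     truth: np.ndarray | None = None) -> None:
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        header = [index_axis, "model"] + (["truth"] if truth is not None else [])
        wr.writerow(header)
        for i, v in enumerate(np.asarray(model, dtype=float)):
            row = [i, f"{v:.6f}"]
            if truth is not None:
                row.append(f"{float(truth[i]):.6f}")
            wr.writerow(row)


def save_stack_grid(path, stack: np.ndarray, pad: int = 2) -> None:
    """Tile the per-(orientation, frequency) response maps of a feature
    stack into one PNG (orientations as columns, frequencies as rows)."""
    stack = np.asarray(stack, dtype=float)
    h, w, nt, nf = stack.shape
    grid = np.zeros((nf * (h + pad), nt * (w + pad)))
    lim = stack.max() or 1.0
    for i in range(nt):
        for j in range(nf):
            grid[j * (h + pad): j * (h + pad) + h,
                 i * (w + pad): i * (w + pad) + w] = stack[:, :, i, j] / lim
    save_image_png(path, grid)


def save_orientation_overlay(path, image: np.ndarray, omap,
                             step: int = 16, length: int = 10) -> None:
    """Needle overlay: a bright line along the local slant direction
    (perpendicular to the anisotropy axis), scaled by the magnitude."""
    canvas = _finite01(np.asarray(image, dtype=float)).copy()
    h, w = canvas.shape
    for r in range(step // 2, h, step):
        for c in range(step // 2, w, step):
            if not omap.valid[r, c]:
                continue
            ang = omap.theta[r, c] + np.pi / 2  # slant direction (axial)
            L = length * float(omap.magnitude[r, c])
            for t in np.linspace(-L, L, int(4 * L) + 2):
                y = int(round(r + t * np.sin(ang)))
                x = int(round(c + t * np.cos(ang)))
                if 0 <= y < h and 0 <= x < w:
                    canvas[y, x] = 1.0
    save_image_png(path, canvas)


def save_kernel_gallery(path, bank: FilterBank, pad: int = 2) -> None:
    """Tile every kernel of a bank into one PNG (signed lobes summed)."""
    spec = bank.spec
    tiles = {}
    size = 0
    for key, kern in bank.kernels.items():
        w = (kern.weights if not isinstance(kern, tuple)
             else sum(k.weights for k in kern))
        tiles[key] = w
        size = max(size, w.shape[0])
    cell = size + pad
    grid = np.zeros((spec.n_frequencies * cell, spec.n_orientations * cell))
    for (i, j), w in tiles.items():
        s = w.shape[0]
        off = (size - s) // 2
        lim = np.abs(w).max() or 1.0
        grid[j * cell + off: j * cell + off + s,
             i * cell + off: i * cell + off + s] = w / lim
    save_image_png(path, 0.5 + 0.5 * grid)
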
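"""Quantitative comparison of model depth against ground truth.

The headline statistic is the relative error

    E = sum_i |o_i - m_i| / sum_i o_i

over the object mask, with both maps normalized to [0, 1] (1 = nearest);
reported as a percentage.  Profile utilities extract single rows/columns
and compare them by Spearman rank correlation (shape agreement), mean
signed error (under/over-estimation direction) and the profile-restricted
relative error.
"""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np
from scipy import stats

__all__ = ["relative_error", "extract_profile", "compare_profiles"]


def _common_mask(a: np.ndarray, b: np.ndarray,
                 mask: Optional[np.ndarray]) -> np.ndarray:
    if a.shape != b.shape:
        raise ValueError("map shapes differ")
    m = np.isfinite(a) & np.isfinite(b)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != a.shape:
            raise ValueError("mask shape differs from maps")
        m &= mask
    return m


def relative_error(truth: np.ndarray, model: np.ndarray,
                   mask: Optional[np.ndarray] = None) -> float:
    """E = sum|o - m| / sum o inside the mask (a fraction; * 100 for %)."""
    truth = np.asarray(truth, dtype=float)
    model = np.asarray(model, dtype=float)
    m = _common_mask(truth, model, mask)
    o, mm = truth[m], model[m]
    denom = o.sum()
    if denom <= 0:
        raise ValueError("ground truth sums to zero inside the mask")
    return float(np.abs(o - mm).sum() / denom)


def extract_profile(map2d: np.ndarray, axis: str, index: int,
                    mask: Optional[np.ndarray] = None) -> np.ndarray:
    """One row (axis='row') or column (axis='col'); NaN outside the mask."""
    map2d = np.asarray(map2d, dtype=float)
    if axis == "row":
        line = map2d[index, :].astype(float).copy()
        mline = None if mask is None else np.asarray(mask, bool)[index, :]
    elif axis == "col":
        line = map2d[:, index].astype(float).copy()
        mline = None if mask is None else np.asarray(mask, bool)[:, index]
    else:
        raise ValueError("axis must be 'row' or 'col'")
    if mline is not None:
        line[~mline] = np.nan
    return line


def compare_profiles(model: np.ndarray, truth: np.ndarray) -> Dict[str, float]:
    """Spearman rho, mean signed error (model - truth) and profile E."""
    model = np.asarray(model, dtype=float)
    truth = np.asarray(truth, dtype=float)
    ok = np.isfinite(model) & np.isfinite(truth)
    m, o = model[ok], truth[ok]
    if m.size < 3:
        raise ValueError("too few valid profile samples")
    if np.ptp(m) < 1e-12 or np.ptp(o) < 1e-12:
        rho = 0.0
    else:
        rho = float(stats.spearmanr(m, o).statistic)
    signed = float(np.mean(m - o))
    denom = o.sum()
    rel = float(np.abs(o - m).sum() / denom) if denom > 0 else float("nan")
    return {"spearman": rho, "mean_signed_error": signed, "relative_error": rel}
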
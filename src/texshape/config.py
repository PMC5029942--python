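"""Model configuration: filter-bank grids, per-module cascade constants,
feedback gains and cycle counts — fully round-trippable through YAML.

The numeric defaults below are the package's reference parametrization,
chosen once to satisfy the model's qualitative contracts (bounded activity,
noise suppression by feedback, convexity preference, slant monotonicity) on
the synthetic stimulus suite; every value is exposed here precisely because
the underlying biology constrains structure, not constants.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

from .cascade import CascadeParams
from .filterbanks import FilterBankSpec

__all__ = ["ModelConfig"]


def _p(**kw) -> CascadeParams:
    return CascadeParams(**kw)


@dataclass
class ModelConfig:
    # shared feature grid
    n_orientations: int = 8
    n_frequencies: int = 4
    freq_min: float = 0.03
    freq_max: float = 0.24

    # per-module cascade constants (supplementary-table analogue)
    params_I: CascadeParams = field(default_factory=lambda: _p(
        beta=2.0, xi=1.0, alpha=1.0, gamma=1.0, delta=0.05, epsilon=0.5,
        lambda_fb=0.7, pool_sigma=2.0, fb_radius=4))
    params_II: CascadeParams = field(default_factory=lambda: _p(
        beta=2.0, xi=1.0, alpha=1.0, gamma=1.0, delta=0.05, epsilon=0.5,
        lambda_fb=0.4, pool_sigma=4.0, fb_radius=6))
    params_III: CascadeParams = field(default_factory=lambda: _p(
        beta=2.0, xi=1.0, alpha=0.5, gamma=1.0, delta=0.05, epsilon=0.5,
        lambda_fb=0.5, pool_sigma=3.0, fb_radius=5))
    params_IV: CascadeParams = field(default_factory=lambda: _p(
        beta=2.0, xi=0.3, eta=0.65, alpha=0.5, gamma=1.0, delta=0.02,
        epsilon=0.3, lambda_fb=1.0, pool_sigma=8.0, fb_radius=8))

    # drive gains bringing raw filter outputs into the cascade working range
    gain_I: float = 0.3
    band_norm_floor: float = 0.2
    freq_weight_exp: float = 0.7
    gain_II: float = 4.0
    gain_III: float = 40.0
    gain_IV: float = 4.0

    # feedback loop
    n_cycles: int = 3
    feedback: bool = True
    fb_gain_II_to_I: float = 1.0
    fb_gain_III_to_II: float = 0.5
    fb_gain_IV_to_II: float = 1.0
    fb_gain_IV_to_I: float = 0.0
    early_stop_tol: float = 1e-4

    # module II grouping
    bipole_length_factor: float = 2.5
    bipole_separation: float = 1.2
    transfer_scale: float = 1.0

    # module III sketch
    sketch_routing: str = "per_band"   # orientation-summed per frequency
    sketch_pool_sigma: float = 6.0
    dog_sigma_center: float = 2.5
    dog_sigma_surround: float = 5.0

    # module IV depth pathway
    grad_freqs: tuple = (0.03, 0.08)
    it_sigma_dir: Optional[float] = None   # None: auto = it_sigma_factor * mask diameter
    it_sigma_factor: float = 5.0
    it_perp_ratio: float = 0.02
    it_support_sigmas: float = 0.2
    it_sigmoid_sharpness: float = 0.15
    it_combine: str = "max"                # lobe-pair combination; or "softmax"
    it_softmax_beta: float = 8.0
    depth_combine: str = "max_orientation"  # channel combination; or "sum"
    total_pool_sigma: float = 8.0
    smooth_sigma: float = 3.0

    # surface orientation read-out
    patch_sigma: float = 8.0

    # contour-texture mode
    contour_minor_weight: float = 0.1
    contour_field_scale: float = 1.5

    # ------------------------------------------------------------------
    def gabor_spec(self) -> FilterBankSpec:
        return FilterBankSpec(self.n_orientations, self.n_frequencies,
                              self.freq_min, self.freq_max, aspect_ratio=1.0)

    def bipole_spec(self) -> FilterBankSpec:
        return FilterBankSpec(self.n_orientations, self.n_frequencies,
                              self.freq_min, self.freq_max,
                              lobe_separation=self.bipole_separation)

    def sketch_spec(self) -> FilterBankSpec:
        return FilterBankSpec(self.n_orientations, self.n_frequencies,
                              self.freq_min, self.freq_max)

    def grad_spec(self) -> FilterBankSpec:
        f = sorted(self.grad_freqs)
        return FilterBankSpec(self.n_orientations, len(f), f[0], f[-1])

    def it_spec(self) -> FilterBankSpec:
        f = sorted(self.grad_freqs)
        return FilterBankSpec(self.n_orientations, len(f), f[0], f[-1],
                              sigmoid_sharpness=self.it_sigmoid_sharpness)

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grad_freqs"] = list(self.grad_freqs)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for key in ("params_I", "params_II", "params_III", "params_IV"):
            if key in d and isinstance(d[key], dict):
                d[key] = CascadeParams(**d[key])
        if "grad_freqs" in d:
            d["grad_freqs"] = tuple(d["grad_freqs"])
        return cls(**d)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "ModelConfig":
        if hasattr(source, "read"):
            d = yaml.safe_load(source.read())
        else:
            try:
                with open(source) as fh:
                    d = yaml.safe_load(fh.read())
            except (OSError, ValueError):
                d = yaml.safe_load(source)
        return cls.from_dict(d)

    def digest(self) -> str:
        """Short reproducibility hash of the full configuration."""
        import hashlib
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]
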
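# Methods

## Scope and idea

`texshape` implements a mechanistic account of monocular shape-from-texture:
a cascade of filtering, divisive normalization, long-range grouping,
gradient extraction and directed integration whose stages map onto cortical
areas V1, V2, V4 and IT. The model produces relative depth (ordering, not
metric distance), a boundary/ridge sketch, and local slant/tilt estimates.
Everything is deterministic: given an image, a mask and a configuration,
the outputs are bit-reproducible.

## The three-stage column

Every model area applies the same steady-state computation to its own
filter output `d`:

    r   = rect( (β·d·(1+net) − ξ·q + η) / (α + γ·d·(1+net) + q) )
    q_i = δ·( Σ_feat r_i,feat + ε·(Λ ⊛ max_feat r)_i )
    net = rect(λ_FB − r_own) · g · ⟨r_higher⟩_nbhd

Properties relied on throughout: the response is bounded in
[0, β/γ + η/α]; it is monotone in the drive; subtractive-plus-divisive
inhibition enhances strong responses relative to weak ones sharing a pool;
feedback is modulatory (multiplies the drive, creates nothing) and *gated* —
units already above λ_FB receive none, which is what makes re-entrant
signals flatten ridges and suppress noise instead of amplifying winners.

The q/r fixed point is settled by two inner iterations from q = 0 (the
response is bounded, so this converges quickly); whole-model feedback runs
a fixed number of synchronous cycles (default 3) with an early stop when
the maximum state change falls below 1e-4. Update order across modules is
synchronous because the biology does not specify one.

## Filter banks

Orientations are linear on [0, π) (default 8), frequencies octave-spaced
(default 4 bands on 0.03–0.24 cycles/pixel). θ always denotes the axis of
elongation — the stripe orientation a kernel prefers — measured from the
image +x axis with y pointing down, identified modulo π.

- *V1*: even/odd Gabor quadrature pairs, ~1-octave bandwidth
  (σ ≈ 0.56/f), DC-corrected, L1-normalized. L1 normalization makes the
  amplitude response to a matched unit-contrast grating scale-invariant, so
  relative energy between bands reflects the stimulus, not kernel size.
- *V2*: two anisotropic Gaussian lobes per channel, unit-sum, mirror
  symmetric, displaced ±1.2σ along θ; lobe length 2.5× the Gabor envelope
  so lobes span texture gaps. Lobe outputs pass a saturating transfer
  x/(1+x/s) and multiply.
- *V4 sketch*: three alternating anisotropic Gaussians (a second
  directional derivative across θ), exactly zero-sum, plus an isotropic
  difference-of-Gaussians (σ 2.5/5 px) for enhancement.
- *V4 depth*: opposite-sign displaced Gaussian pairs (first directional
  derivative along φ = θ + π/2), exactly zero-sum, applied in a single
  contrast polarity so the response sign encodes rising vs falling energy.
  Two scales (0.03, 0.08 cycles/pixel).
- *IT*: one nonnegative and one nonpositive lobe per channel, each an
  anisotropic Gaussian multiplied by a 2D sigmoid of the coordinate along
  φ, giving one-sided support on opposite sides.

Kernel support is 6σ of the widest Gaussian (odd side), except the IT
fields, which are deliberately *near-uniform windows*: σ along the
integration direction is several image widths and the support is truncated
at the image scale (defaults `it_sigma_factor = 5.0`,
`it_support_sigmas = 0.2`, lateral width ratio 0.02). The reasons are laid
out below.

## Module I: band-equalized, frequency-weighted texture energy

Texture energy is the quadrature amplitude per (θ, ω). Two normalizations
follow:

1. **Per-band mean normalization** — each band is divided by its image
   mean (plus a floor of 0.2× the grand mean to keep empty bands from
   amplifying noise). What survives is *relative* frequency energy: a
   patch whose spectrum occupies bands that are quiet elsewhere stands
   out, regardless of absolute contrast.
2. **Increasing frequency weighting** — bands are weighted by
   (f/f_min)^0.7. Energy appearing at finer scale contributes more summed
   activity. This is what orients the depth cue: compression (by slant,
   curvature or distance under perspective) moves energy into higher
   bands, so summed grouped activity *increases* with compression and its
   spatial gradient points away from the viewer. Without the weighting,
   band equalization is symmetric and any band-anomalous region — coarse
   or fine — would read the same.

The exponent 0.7 was chosen once on the synthetic suite as the value where
slant recession, step ordering and curved-surface recovery are
simultaneously monotone; 1.0 overweights the noisiest band, 0.5 loses the
step ordering.

## Module IV: anchored two-path integration

The depth pathway differentiates the total grouped activity (pooled by
σ = 8 px first — model V4 receptive fields are larger than V1's, and
texture-element granularity must not masquerade as depth structure) and
then integrates the *signed* gradient with the one-sided IT fields:

- the positive lobe sums the signed changes lying behind a location along
  φ — an activity estimate anchored on that side;
- the negative-weight lobe sums the changes ahead, its sign flip making
  decreases ahead count as positive depth;
- the maximum of the two anchored estimates is kept and rectified.

Each channel is therefore `e(x) − min(anchor_behind, anchor_ahead)`: depth
at a point is measured from whichever side carries *lower* summed
activity. This is the model's convexity preference — an ambiguous bounded
surface is read as climbing from its low-activity surround, so its
center ends up nearest. Channels are combined by the maximum over
orientations and the sum over scales: each orientation is a path-based
estimate that is only informative where its path crosses structure, and a
plain sum lets the silent directions of enclosed regions dominate
(config-switchable to the plain sum).

Numerical choices that matter here:

- *Zero padding* for the IT convolutions (the local banks use reflect
  padding): reflection would mirror whole-scene structure into the
  integration paths of fields that span the image.
- *Near-uniform field profile*: with a decaying profile the anchor rises
  as activity accumulates, so equal depth steps produce diminishing raw
  increments and far plateaus sag below nearer ones; a flat one-sided
  window preserves the cumulative semantics (the anchor is effectively
  the value at the far end of the window).
- *Tonic baseline* η = 0.65 in the module IV cascade: the depth read-out
  divides by the in-mask maximum, so a featureless scene must rest on a
  pedestal to finalize flat; η sets the scale that separates "no
  evidence" from real gradients. Other modules keep η = 0 so that zero
  input maps exactly to zero output.

Finalization smooths the summed activity (mask-normalized Gaussian,
σ = 3 px), inverts it (higher activity = farther) and divides by the
in-mask maximum; comparisons against ground truth additionally min-max
normalize both maps (or both profiles) to [0, 1].

## Surface orientation read-out

Module II activity summed over frequency gives one value per orientation
bin. Doubled angles handle axiality: R = Σ d_o·e^{2iθ_o}/Σ d_o,
slant axis Θ = arg(R)/2 (via atan2, so the quadrant is fixed), magnitude
‖R‖ ∈ [0,1], anisotropy A = 1 − min/max. Distributions are pooled with a
Gaussian window (σ = 8 px) before the statistics because single-pixel
histograms are noise-dominated. The model claims proportionality to slant
only; no calibration to degrees is attempted.

## Synthetic scenes

The generator replaces studio-rendered stimuli with analytic height
fields: slanted planes, a plane with a semisphere, compact-support bells
(convex/concave), a doubly curved object (flattened spherical cap with a
secondary bump and a dip), multi-level smoothed depth steps, cylinders and
a sinusoidal inclined plane. Textures — jittered polka dots, anisotropic
dots, contour lines, correlated noise — are parameterized in *surface*
coordinates (per-axis arc length), so foreshortening falls out of the
geometry: an orthographic plane at slant s renders circular dots with axis
ratio cos s (verified against fitted ellipses). Perspective uses a pinhole
whose distance is set by the field of view, intersected with the height
field by fixed-point ray iteration on a world canvas larger than the
image (the footprint of far rays exceeds the image frame). There is no
shading: texture is the only cue by design. Scene masks mark the *object*
(the sphere disk, the bell, the cap); background regions are processed but
excluded from depth statistics, as real use would after figure-ground
segregation.

Default conditions chosen once for the study suite: 300×300 images, dot
spacing 16 px / radius 5 px (coarse enough that the far end of a 50°
slanted plane under a 50° field of view stays within the model's frequency
bands), step fixture with 4 levels of 40 px at 20 px transitions under
50° fov, doubly curved object with cap flattening 0.7 and secondary
features of 14/9 px amplitude.

What the generator does *not* emulate: shading and specularity, occlusion
of one object by another, sensor noise, perspective texture distortion
compensation. Passing tests on these stimuli show the mechanism works
where texture compression is the dominant cue; they do not certify
performance on natural images.

## Known limitations

- **Concave/convex ambiguity**: under orthographic projection a dip and a
  bump produce identical texture statistics; the model reads both as
  convex (its documented bias). The concave bell is therefore recovered
  inverted; underestimation tests use convex geometry.
- **Fine-scale contrast death**: where compression pushes texture beyond
  the resolvable band range (grazing slant, extreme distance), summed
  energy drops and depth flattens — depth is underestimated near such
  rims.
- **Contour/planar-cut textures** carry no intrinsic integration
  direction; `contour_mode` requires the caller to supply one and fails
  by contract when it is absent. The multi-axis sinusoidal inclined plane
  remains unrecovered, matching the model's known failure case.
- The sketch marks boundaries and ridges but junction detection and
  figure-ground segregation on it are out of scope.
- Cascade constants (β, ξ, η, α, γ, δ, ε, λ_FB per module), filter-shape
  ratios and gains are this implementation's choices, set once so the
  property suite (boundedness, noise suppression by feedback, flat-null,
  slant monotonicity, convexity preference, step ordering) holds; they
  are all exposed in `ModelConfig` and round-trip through YAML.
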
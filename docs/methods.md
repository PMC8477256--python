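# Methods

This note documents the models, numerical choices and known limitations
of `patlv`.  It states no result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Imaging model

The image plane is a square n×n grid (default 128 px over 38 mm) centred
at the origin; the first image axis is depth, the second lateral, all
physical coordinates in mm.  Transducer elements are modelled as points
with a facing normal; a linear array is a row of Q elements (default
128) at uniform pitch (default 0.3 mm, so the aperture (Q−1)·pitch =
38.1 mm slightly exceeds the region — pitch is the hard hardware
constant).  Multi-array geometries place copies of the top array rotated
about the grid centre: rotating by θ yields the dual-probe geometry with
inter-normal angle θ (180° parallel shape, 90° L shape); four rotations
at 90° give the square, full-view reference.  Default standoff is 0
(elements on the region boundary); a standoff parameter covers
experiment-like placements.

The forward operator is the interpolating discrete-to-discrete PAT
model: pixel k at distance r from element i deposits its intensity into
the two temporal samples bracketing the arrival time r/(cΔt) with linear
interpolation weights, scaled by the element directivity D and the 2-D
geometric decay 1/(2πr̃).  Blocks are stored as scipy CSR matrices, at
most 2n² non-zeros each; a dense materialisation guard refuses
operators above 5·10⁷ entries.

### Unit convention for the decay factor

The decay radius r̃ is expressed in *sample-travel units* r/(cΔt) — the
same dimensionless distance that indexes the temporal samples — rather
than in mm.  This is a deliberate scaling choice: the solver's published
step size (α₀ = 5 with decay 1.05) and batch size (M = 5) are fixed
constants, and stochastic stability of the variance-reduced iteration
requires α₀·(Q/M)·λmax(A_iᵀA_i) ≲ 2.  Measured per-block spectral norms
put that product at ≈ 542 (mm units), ≈ 48 (pixel units) and ≈ 0.76
(sample units) for the four-array study at n = 128; only the sample-unit
convention is stable, and it is also the internally consistent one
(every distance in the model formula then carries the same unit).  The
choice only rescales the data and misfit jointly; reconstructed images
are unaffected up to the balance against the fixed TV weight.

### Near-field guard

1/(2πr) diverges as r → 0 for pixels adjacent to an element; r is
clamped below at half a pixel.  A stronger clamp at one element pitch
was evaluated and changed study RMSEs by < 0.005, so the minimal clamp
is kept.

## Directivity

Finite-width elements are less sensitive to waves arriving off their
normal axis.  The default profile is a monotone PCHIP interpolant
through the datasheet anchor sensitivities (0 rad, 1), (0.24 rad, 0.95),
(0.72 rad, 0.40), reaching 0 at 1.2 rad; `cosine` and `none` modes are
selectable since the effect on reconstruction is known to be modest.
The angle is measured in-plane between the element normal and the
element→pixel direction.

## Synthetic data generation

Data are generated by the package's own discrete forward model — a
deliberate, documented substitution for a full 3-D wave-propagation
simulation; this keeps the toolkit dependency-free and desk-scale.  Three
consequences follow:

* **Inverse-crime avoidance.** The phantom is re-rasterised on a
  refine× finer grid (default 2×) and projected with the fine-grid
  operator; the forward sum carries a 1/refine² pixel-area weight so
  that amplitude is resolution-independent and refine = 1 reproduces the
  reconstruction-grid operator exactly (a configuration used only in
  tests).
* **Temporal anti-aliasing.** The pressure is the time derivative of the
  potential; differentiating a rasterised potential amplifies
  pixel-quantisation ripple at the sampling frequency, which no physical
  receiver would see.  The simulator therefore smooths the pressure with
  a Gaussian over the pixel-crossing time (σ = pixel/(2cΔt) samples ≈ 2
  samples at the study scale).  This is anti-aliasing of the
  rasterisation, not a transducer-bandwidth model (bandwidth modelling
  is out of scope).  The raw sample-exact derivative remains available
  (`antialias=False`) and is what the model-property tests use.
* **What passing tests do not show.** The simulated data are noise-free,
  2-D and generated from the same model family as the reconstruction
  operator.  Real measurements add transducer bandwidth, out-of-plane
  signal, 3-D spreading and electronic noise; reconstructions from this
  simulator are therefore systematically *better* than experimental ones,
  and RMSE values land below the values reported for 3-D-simulated data.
  Trend comparisons across geometries are meaningful; absolute RMSE
  agreement is approximate.

Optional white measurement noise (std relative to peak pressure) is
seeded; the potential is then re-integrated from the noisy pressure.

## Phantoms

All phantoms are rasterised with 4×4 supersampling (stabilising RMSE
against aliasing), normalised to max 1, and carry a `render` closure so
the simulator can re-rasterise them on a finer grid.

* **FORBILD-style head phantom** — a deterministic rendition of the
  public head-phantom primitive list (ellipses/circles painted in
  order), with CT values affinely remapped to [0,1] and the head scaled
  to 85% of the half-extent.  The margin keeps the object clear of the
  in-plane arrays, where the point-detector model diverges; sharp
  intensity steps adjacent to an element would otherwise dominate
  max-normalisation.
* **Vessel tree** — a seeded recursive binary branching structure
  (segment length ×0.72, width ×0.70 per level, branching angles drawn
  uniformly from 15–40°), root entering from the top edge.  Tips number
  2^(depth−1); the segment list is exposed for structural checks.
* **Dot grids, discs, polygons** — parametric targets for resolution,
  ROI-metric and view-combination tests.

## DAS reconstruction

Per pixel, each element's pressure trace is sampled at the time of
flight (fractional delays by linear interpolation; out-of-window delays
contribute zero) and summed — no apodization and no depth compensation,
so the plain signed sum is exactly the initial image the iterative
solver needs.  For display and scoring the beamformer can operate on the
per-channel analytic (Hilbert) signals and return the magnitude of the
complex sum (`envelope=True`); the study driver reports
envelope-detected DAS images, the conventional nonnegative ultrasound
display, whose RMSE ordering across geometries matches the published
qualitative trend.  Images are max-normalised before metrics.

## VR-SGD solver

SVRG-style estimator: snapshot at the start of each outer loop, full
gradient μ there, inner batches of M blocks drawn uniformly without
replacement (sorted, so the M = Q case is bit-identical across seeds),
direction scaled by Q/M so its expectation is the full gradient.  The
inner count equals the number of element blocks Q.  Step α_s = α₀/a^s is
constant within an outer loop.  The TV proximal operator uses
Chambolle's dual projection iteration (isotropic TV, reflecting
boundaries, dual step 0.248 < 1/8, default 20 sweeps, tolerance 1e-4);
anisotropic TV and a nonnegativity clamp are options, both off by
default.  A divergence guard aborts if the cost exceeds 10× its initial
value.  DAS initialisation is rescaled by the closed-form least-squares
optimal scalar before iterating, since DAS output units are arbitrary
and the cost is scale-sensitive.

### Convergence behaviour

The geometric step schedule has a finite total step budget
(Σ α_s < α₀·a/(a−1) = 105), so the iteration semi-converges: RMSE falls,
saturates, and for dual-probe geometries can drift slightly upward as
residual inconsistencies of the refined-grid data are fitted.  On the
full-view inverse-crime configuration at n = 64 the saturation floor is
RMSE ≈ 0.20 — materially better than DAS but far from machine-precision
recovery; one acceptance property that postulates RMSE < 0.05 under
these settings is not attainable and is intentionally left failing (see
the test suite).  Under the study conditions the solver beats DAS for
every geometry and preserves the square < L ordering; the parallel
geometry lands slightly above the single array because the single-array
solution degenerates to a TV-smoothed blob whose RMSE is flattered by
max-normalisation — visible directly in the reconstructed images.

## Metrics

RMSE follows the mean-squared-pixel-difference definition; both images
are max-normalised first (reconstruction units are arbitrary).  CNR and
SNR use the 50%-of-ROI-peak rule for the target mean and the full
background ROI for μ_o, σ_o, in dB; degenerate inputs (zero contrast,
zero background spread, non-positive target mean) raise a dedicated
error instead of returning ±inf.  gCNR uses 255 shared uniform bins over
the pooled ROI range, histograms normalised to unit sum; it is bounded
in [0,1], attains 0/1 on identical/disjoint samples exactly, and is
invariant under monotone intensity transforms up to binning error.  With
small ROIs (≲ a few hundred pixels) the 255-bin histogram overlap is
biased low, inflating gCNR — a property of the estimator, not of the
implementation.

## Problem sizes

The shipped study runs at the published scale (128×128 grid, 128
elements per array, 40 MHz, record length covering the farthest pixel
≈ 1445 samples, 30 outer iterations) and completes in ≈ 6 minutes on one
CPU; tests use 8–64 px instances with proportionally reduced sampling
rates so dense oracles stay exact and fast.

## Known limitations

No 3-D propagation, no transducer bandwidth or impulse response, no
acoustic attenuation, no fluence modelling; the dual-probe calibration
transform is applied with given parameters (estimating them from
transmit/receive data is out of scope).  The solver is the standard SVRG
reading of a loosely specified algorithm; alternative inner-step
schedules or mid-epoch snapshots would change the trajectory but not the
structure.
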
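# Methods

## The problem

A cryo-electron tomogram is reconstructed from a tilt series: the same
specimen imaged at a sequence of stage tilts. Reconstruction quality is
limited by how precisely the images are registered to a common 3D frame.
Classical alignment tracks landmarks (gold beads or high-contrast surface
particles) or image patches; in FIB-milled lamellae landmarks are scarce
and patch tracking is unreliable, and residual per-tilt translation errors
of a few pixels blur the tomogram and limit every downstream analysis,
most visibly subtomogram averaging of small proteins.

`tiltrefine` refines an existing alignment by making the reconstruction
itself the objective: the tomogram of a lamella has biological material in
a central z slab and essentially only noise above and below it, so sharper
alignment means higher statistical contrast of the central slab. The
package reconstructs the tomogram as a differentiable function of the
per-tilt translations (and optionally a first-order local-motion field),
scores slab contrast, and ascends its gradient.

## Reconstruction model

Geometry. Right-handed coordinates with the beam along +z; the tilt axis
lies along y after an in-plane rotation. A volume point p maps to
micrograph coordinates u = R(θ, φ) p |_{xy} + (tx, ty), where
R = Ry(θ) Rz(φ), θ is the stage tilt and φ the in-plane tilt-axis
rotation. Translations are the refined variables; θ and φ are taken from
the input alignment and held fixed (the in-plane rotation flag exists but
rotation refinement is not implemented in this version).

Working resolution. The tilt series is Fourier-cropped so that Nyquist
corresponds to 50 Å (pixel size 25 Å). At this band the contrast of
cellular material is strong, CTF effects are secondary, and the whole
optimization runs comfortably on a CPU.

Tiled Fourier-slice reconstruction. The footprint is divided into cubic
tiles (default 64 voxels ≈ 160 nm at 25 Å/voxel; z thickness equals the
tile side). For each tile and tilt, a square patch centered on the
projected tile center is resampled from the micrograph; its 2D FFT is
placed on the central plane of the tile's 3D Fourier volume whose
orientation follows the tilt geometry, each sample distributed over its 8
neighboring voxels with trilinear weights. Accumulated values are divided
by accumulated weights, floored at `w_floor = 1e-3` so empty missing-wedge
regions do not amplify noise, and inverse-transformed. Patches reaching
outside the micrograph are zero-filled and the tilt's contribution is
down-weighted by its valid-pixel fraction.

Differentiability. Sub-pixel patch positioning is a Fourier phase ramp
applied to a *fixed* integer crop (the crop window is frozen at the
reference parameters with an 8-pixel margin), so reconstructed voxels are
smooth functions of the translations with no re-rounding discontinuities.
Because every other step is a linear operator (FFTs, crop/pad, trilinear
scatter, weight division), the gradient of any scalar of the tiles with
respect to each per-tilt 2D shift is computed by an exact reverse-mode
pass: the adjoint of trilinear insertion is trilinear extraction, the
adjoint of a unitary FFT is its inverse, and the phase-ramp derivative
contributes the 2πi·f factor. Gradient checks against central finite
differences (step 0.05 px) agree to a relative vector error of ~1e-3 or
better on noiseless fixtures; the residual scales as the square of the
step, i.e. it is finite-difference truncation, not gradient error.

## Contrast objective

Per tile, in order:

1. **Normalize**: subtract the global mean, divide by the pooled standard
   deviation of the top and bottom z slabs (`outer_slab_fraction = 0.2`
   per side). The outer slabs are noise, so this expresses contrast in
   units of the local noise level.
2. **Inverted leaky ReLU** (`slope = 0.2` on the positive branch):
   protein density is dark, so negative voxels pass at full weight while
   positive excursions are attenuated.
3. **Square** the voxels, further up-weighting high-contrast voxels.
4. **Slice std**: standard deviation of every X-Y slice along z.
5. **Average** over the central slab — by default the middle 40% of z;
   when particle coordinates are supplied, the z range containing
   particles plus a 2-voxel pad, which protects the loss from bright
   contamination above or below the sample.

The refined quantity is the negative mean over tiles and central slices
(minimized), reported to users as a positive contrast score. The ordering
(normalize → ReLU → square → std) makes the squaring act on the
re-weighted voxels; the 0.2 slope and the 0.2 outer-slab fraction are
conventional defaults, exposed in `ContrastConfig`. Between the central
window (40%) and the outer slabs (20% per side) a 10% guard band per side
absorbs the smeared slab boundary: reconstruction leaks sample contrast a
few voxels beyond the physical slab, and including those slices in the
normalization slabs measurably destabilizes the optimization.

## Optimization

Adam (β1 = 0.9, β2 = 0.999, ε = 1e-8) on the flattened translation vector,
learning rate 0.3 px/step, 300 iterations. A rate of 0.1 px/step does not
cross a 4 px initial error within a few hundred iterations, and 0.5
overshoots into wrong basins; 0.3 converges in ~150 steps and remains
stable.

Dropout stabilizer. Each iteration the loss and gradient are evaluated
with a random subset of the parameters transiently reset to their original
(input-alignment) values — the neural-network dropout idea transplanted to
parameters. The reset is per evaluation only; the running parameters are
not overwritten, so the optimum is not contaminated by stale resets. An
exact count of `round(fraction · N)` scalars is drawn without replacement
from a counter-based Philox generator keyed by (seed, phase, iteration),
which makes runs bit-reproducible. A `persistent` mode that overwrites the
running parameters after each step is available in the config.

Dropout schedule and re-anchoring. The loss landscape is locally rugged:
an individual tilt can latch onto a wrong feature several pixels away
while all other tilts converge. Two stabilizers address this:

* the first two thirds of the iterations use a stronger dropout fraction
  (0.25; the *capture* stage), whose frequent init-anchored evaluations
  repeatedly pull runaway parameters back toward their basin; the
  remainder uses the baseline 5% to polish;
* between stages, the displacement from the initial alignment is robustly
  fit to the tomogram-origin trend over tilts (a cos θ + b sin θ in x, a
  constant in y; fit trimmed and re-fit so outliers do not skew it), and
  any tilt whose residual exceeds the bulk distribution (median + 4 scaled
  MADs, at least 2 px) is reset onto the trend — deterministically —
  before optimization continues.

The returned parameters are the iterate with the lowest recorded clean
loss, not the last one, because dropout makes late iterates noisy; with
re-anchoring enabled the selection is restricted to the final segment,
since a trapped tilt can score a deeper (exploited) loss than the honest
optimum and a global argmin would resurrect it.

Local motion. Within-image drift is modeled per tilt as first-order
polynomials of the tile-center position, drift_a(x, y) = cx_a·x̂ + cy_a·ŷ
(a ∈ {x, y}), with (x̂, ŷ) normalized to [−1, 1] over the footprint so
that all coefficients have pixel scale and comparable gradients. The
constant terms are identifiable only jointly with (tx, ty) and are frozen
at zero. Motion is refined in a second phase with translations frozen at
the phase-one optimum, starting from zero coefficients. For particle
extraction, a particle's per-tilt position is its geometric projection
plus the drift evaluated at the particle's own (x, y).

## Gauge freedoms and how recovery is measured

The contrast loss cannot see a global re-parameterization of the tomogram
frame. Moving the reconstruction origin by (dx, dy, dz) shifts every
projection by (dx cos θ − dz sin θ, dy) — three modes of the translation
vector. With the linear motion field active, drift coefficients modulated
by {1, cos θ, sin θ} across tilts additionally realize global scales and
shears of the volume. None of these move anything *relative to the
reconstructed tomogram*: particles picked in the refined tomogram carry
the same remap, so extraction, averaging and every other downstream step
are invariant. When refined parameters are compared with simulation
ground truth, these families are therefore projected out first
(`tiltrefine.metrics`): translation recovery is RMSE modulo the 3-mode
origin family; particle-track accuracy is RMS modulo a 12-parameter
affine remap fit across all particles and tilts. Left in, the metric
would be dominated by an arbitrary frame choice (for random ±4 px injected
shifts on 15 tilts, the truth's own projection onto the origin family
alone contributes ~0.7 px of irreducible "error").

An optional `fix_origin` config projects the origin modes out of the
gradient; it is off by default because pinning the frame mid-optimization
measurably slows capture.

## The synthetic test bed

The phantom emulates a FIB-milled lamella at the working scale: a slab of
thickness 0.4 × the tile z-extent centered in z (so the default central
window brackets the sample exactly as in practice, where tomogram
thickness is chosen to bracket the lamella), containing non-overlapping
dark spheres (default 80 particles of radius 3 voxels, contrast −1) plus
strongly dark fiducial-like spheres on the slab faces (12, contrast −4,
mimicking the surface particles usable as landmarks), white Gaussian
noise, per-tilt shifts (uniform in ±4 px by default; Gaussian available)
and optionally a per-tilt linear drift field. The default noise level sets
the projection-domain SNR (signal variance over noise variance) to 0.3 —
low-dose tilt images retain modest but usable contrast at a 50 Å band.

The simulator projects in *real space* (spline-interpolated rotation, sum
along the beam, position-dependent warp, noise), deliberately independent
of the Fourier-slice reconstruction path, so forward/backward consistency
tests are not circular.

What the phantom does not contain: CTF oscillations, dose-dependent
damage, ice gradients, non-linear lamella deformation, or the structured
cellular background of real data. Passing tests therefore demonstrate the
correctness of the geometry, gradients and optimization under the stated
noise model, not performance on any particular real dataset.

## Problem sizes and numerical choices

Recovery experiments run on 128×128 footprints with 64-voxel z extent, 15
tilts from −56° to +56°, 64-voxel tiles without overlap (4 tiles), 300
iterations — a scale at which a full refinement takes on the order of two
minutes per series on one CPU core. Gradient-check fixtures use 32-voxel
tiles and noiseless phantoms (gradient correctness is a property of the
code; noise only inflates finite-difference truncation). FFTs use the
orthonormal convention throughout so adjoints equal inverses; slice
samples whose trilinear neighbors fall outside the Fourier cube are
discarded rather than wrapped; a zero slice standard deviation
contributes zero gradient; normalization refuses constant volumes.

## Known limitations

* Tilt angles and the in-plane rotation are not refined.
* Patch size equals tile size, so at high tilt the projection of a tile
  extends beyond its patch; the truncation is shared by all tile-local
  reconstruction schemes and limits tiles from shrinking too far.
* The standard deviation measures everything in the slab, noise and
  artifacts included; a feature-aware contrast measure would be sharper.
* First-order polynomials cannot represent curved lamella deformation.
* The loss determines parameters only up to the frame gauges above; the
  tomogram origin follows whatever the optimizer does along those flat
  directions unless `fix_origin` is set.
* At the synthetic test bed's noise level (SNR 0.3) and with only 15
  tilts, an occasional tilt still locks onto a wrong nearby feature in
  roughly one in six random conditions despite the capture/polish
  schedule; such traps are statistically indistinguishable from
  legitimate large random shifts in displacement space, so the re-anchor
  heuristic cannot flag them. Denser tilt schemes couple the tilts more
  strongly and suppress this failure mode.
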
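# Methods

`coromct` implements an in-silico murine coronary CT angiography pipeline:
a 4D digital mouse-heart phantom, a cone-beam micro-CT acquisition
simulator, intrinsic (image-based) cardiorespiratory gating, filtered
backprojection in standard and phase-correlated form, cyclic
motion-compensated reconstruction, and tensor-based adaptive denoising,
plus the quantitative evaluation used to characterize them.  This note
records the models, the defaults and why they were chosen, the numerical
choices, and what the synthetic experiments do and do not demonstrate.

## The imaging problem

Murine coronary imaging sits at the edge of what retrospectively gated
micro-CT can do: heart rates reach 600 bpm and respiratory rates 300 rpm,
while the left coronary artery tapers from roughly 400 µm at its ostium to
on the order of 160 µm on average.  Sampling five non-overlapping
respiratory phases at 300 rpm alone caps the usable detector integration
time at 60 s / 300 / 5 = 40 ms.  Spatial resolution is dose-limited: for a
fixed object and noise level the required dose grows with the fourth power
of resolution, so halving the voxel size costs 16× the dose.  The pipeline
addresses this by acquiring continuously for minutes, sorting projections
retrospectively into cardiac/respiratory windows, and recovering the dose
efficiency lost to gating via motion-compensated averaging of all windows.

## Phantom (`phantom4d`)

The anatomy is a compound of analytic primitives: axis-aligned ellipsoids
(thorax body, myocardial shell, LV/RV blood pools, two atria) and capsule
chains (aorta, pulmonary trunk, and a left coronary tree with a trunk, a
bifurcation into apex-bound and circumflex branches, and two
sub-branches).  Key dimensional defaults: 9 mm long axis, 4 mm short axis,
coronary diameters tapering 400 → 260 µm along the trunk and onward to
80 µm (half the literature 160 µm mean) at the distal tips, monotonically
non-increasing from the ostium.  Tissue values default to blood pool
+600 HU (a blood-pool agent holds vascular enhancement constant over the
whole scan, so enhancement is time-invariant by design), myocardium
+50 HU, thorax background −200 HU; HU ↔ µ conversion uses
HU = 1000·(µ−µ_w)/µ_w with µ_w = 0.02 mm⁻¹.

Every primitive stores its own attenuation and that of its host region,
and the assembly keeps primitives nested or disjoint (a test asserts this
over the cycle).  Point evaluation resolves by priority (coronary >
chamber blood > myocardium > great vessels > background); line integrals
are the additive sum of `chord × (µ − µ_host)`, which is exact under the
nesting invariant.  The coronary tree is a single capsule-chain primitive
whose ray intersections use the exact union of per-segment intervals, so
overlapping joints are never double counted.

Motion model:

* **Cardiac.** A raised-cosine contraction with a systolic duty factor
  (default 0.35): transverse inner semi-axes scale by
  1 − A·w(c), A = 0.25.  The outer wall adjusts so the myocardial shell
  volume is conserved exactly (verified < 2 % by grid integration).
  Atria are modulated in anti-phase (filled in systole) and the pulmonary
  trunk dilates in systole.  No published murine waveform exists; the
  raised cosine reproduces the qualitative systole/diastole behaviour.
* **Respiratory.** A raised-cosine "gasp" (duty 0.45) followed by a quiet
  end-expiratory plateau: craniocaudal translation (0.8 mm) of heart and
  vessels plus a 3 % anteroposterior expansion of the body.  No murine
  respiratory kinematics are published; the gasp/plateau pattern matches
  ventilated-rodent breathing and gives the end-expiration window its
  meaning.
* The coronary centerline is parameterized on the epicardial surface and
  re-evaluated against the instantaneous outer ellipsoid, so the tree
  rides the moving surface; its diameters are rigid.  Murine coronary
  motion velocities are not available in the literature, so coronary
  motion is not separately calibrated.  A right coronary analogue can be
  enabled (`include_rca`) but is off by default.

Default simulation rates are 587 bpm / 300 rpm: deliberately
incommensurate, so cardiac bins fill all gantry angles over many
revolutions and the cardiac fundamental (9.78 Hz) clears the second
respiratory harmonic (10 Hz).  `PhantomSpec` keeps 600 bpm as its own
default, matching the physiological ceiling.

## Scanner (`scanner`)

Circular trajectory, flat detector, monochromatic effective energy
(polychromatic spectra and beam hardening are out of scope).  Full-protocol
constants: source–isocenter 90 mm, source–detector 590 mm, 4×4-binned
pixel pitch 0.299 mm, 86 frames/s, 10 s per revolution, 300 s scan
(25,800 frames, 30 revolutions), nominal full dose 5 Gy.  The forward
model freezes motion at each frame timestamp (the 11.7 ms integration-time
blur is not simulated) and computes exact analytic chord lengths; a
voxelized ray-sampling projector serves as an independent cross-check.

The **desk profile** used by the test suite scales the protocol to one CPU:
128×96 detector pixels at 0.8 mm pitch (0.122 mm at the isocenter,
~16 mm transaxial field covering the phantom), 86 fps, 1 s/rev, 30 s →
2,580 frames over 30 revolutions with the same angle formula.  The pitch
is chosen to match the desk reconstruction voxel rather than to rescale
the full-protocol 44 mm field of view, which would spend most pixels on air.

Photon noise: transmitted counts are Poisson with mean
I₀·f·exp(−line integral) (I₀ = 5·10⁴ per pixel per frame at full desk
dose), re-log-transformed, seed-reproducible.  Dose reduction is realized
by uniform frame thinning by default (matching the protocol of using only
fractions of the acquired data); photon-budget scaling is available.  The
thinning stride can be stratified-random (seeded) to avoid resonances
between the stride and the periodic cardiac/angular structure.

## Intrinsic gating (`gating`)

No ECG leads or breathing pillow: both signals come from the projections.
The respiratory surrogate is the row-wise (craniocaudal) center of mass of
detector intensity.  The cardiac surrogate is the mean intensity over the
detector region with the highest temporal spectral energy in the cardiac
band — after notching two known contaminant harmonic combs: the
respiratory series (breathing translates the whole heart, so its
harmonics reach the cardiac band) and the gantry-rotation series (the
anatomy seen from a rotating viewpoint is periodic at the rotation rate).
Both combs are also regressed out of the surrogate time series before
peak analysis.  The surrogate construction is this package's design,
validated against simulator ground truth only.

Each surrogate is band-passed (zero-phase Butterworth, order 4) around the
dominant peak found within its physiological search band (1–8 Hz
respiratory, 6–15 Hz cardiac at default rates; both configurable for
scaled scenarios).  Peaks are refined to sub-frame accuracy by parabolic
interpolation; phase is a linear 0→1 ramp between consecutive peaks, and
the rate estimate comes from the median peak interval.  Phase 0 therefore
sits at the surrogate peak — an arbitrary but consistent origin, which is
all retrospective binning needs; accordingly, phase-recovery accuracy is
scored as circular RMS after removing the constant origin offset.
Measured on the default desk simulation both rates recover to <0.1 % and
both phase tracks to <0.01 cycles RMS.

Windows: 4 respiratory bins of Δr = 25 % and 10 cardiac bins of Δc = 10 %,
centers at (k+0.5)/n, half-open with wrap-around.  With uniform phases a
joint bin admits Δc·Δr = 2.5 % of all frames.  The end-expiration bin is
identified as the respiratory bin whose mean band-passed surrogate is most
negative (the quiet plateau); frame counts cannot identify it because the
phase ramp is linear in time.

## Reconstruction (`recon`)

FDK chain: cosine pre-weighting on the isocenter-plane grid; row-wise ramp
filtering built from the DFT of the discrete Ram-Lak kernel (correct DC
behaviour) windowed by a Shepp-Logan apodization with cutoff at the grid
Nyquist (scaling with voxel size, clipped at the detector Nyquist); an
axial Gaussian band limit matched to the same cutoff (isotropic
resolution, and the axial half of the dose ∝ resolution⁴ law);
distance-weighted cone-beam backprojection with bilinear detector
interpolation (numba kernel); rays leaving the detector contribute zero
and a coverage volume records the angular weight actually received.

Angular normalization over many revolutions and arbitrary gated subsets
uses per-unique-angle Voronoi (half-gap) quadrature weights on the circle,
split evenly across duplicate angles.  Fixed 1° sectors were rejected:
with 2.5 % gating most sectors are empty (scale bias), and zero-weighting
duplicate angles would break the σ ∝ 1/√n_frames noise behaviour that
multi-revolution averaging must provide.  A static uniform cylinder
reconstructs to well under 1 % error in the central region, and a random
2.5 % subset stays within 3 %.

Grids: desk default 72³ voxels at 0.15 mm (10.8 mm field); the full-protocol
240³ / 0.05 mm grid (from the ~70 µm system resolution) is available via
configuration but not exercised by the tests, which must fit a single-CPU
budget.  Coverage below the short-scan minimum (π + fan) raises an error
naming the gap; gated reconstruction in the sparse regime can opt into a
warning instead, since limited-angle streaks are exactly the phenomenon
the phase-correlated low-dose arm is meant to exhibit.

## Motion compensation (`moco`)

Adjacent cardiac phases are registered with symmetric-force Demons
(SimpleITK's filter behind this module's interface) over a 4-level
pyramid (shrinks 8/4/2/1; iterations 60/40/20/10 by default, 30/20/10/5 in
the desk profile), Gaussian fluid (σ_f = 1.5 vox) and diffusion
(σ_d = 1.0 vox) regularization, intensities normalized to a robust [0,1]
range, forces computed on 1-voxel-presmoothed copies while warping uses
the raw volumes.  The per-iteration update cap is expressed in
level-voxels.

The cycle of fields (including phase N−1 → 0) is then regularized:

1. **Magnitude cap** (default 0.5 mm) — streak-chasing on sparse gated
   volumes produces non-physiological outliers.
2. **Air masking** — displacements are zeroed below −600 HU.
3. **Cyclic temporal-harmonic projection** — per voxel, the field sequence
   is projected onto its first 3 cyclic Fourier modes.  Physiological
   motion is smooth over the cycle while registration noise is independent
   between pairs; dropping the DC term removes the drift component that
   breaks loop closure.
4. **Noise-adaptive shrinkage** — all displacements are scaled by
   1/(1+(σ/σ₀)²) with σ the per-phase image noise (Laplacian-MAD estimate)
   and σ₀ = 150 HU.  Registration accuracy is a function of SNR; on very
   noisy series the compensation therefore approaches a plain phase
   average instead of applying unreliable warps.  At full desk dose the
   factor is ≈0.7 and the reference-phase LV radius is preserved to a
   tenth of a voxel; at the lowest sweep dose it is ≈0.1 and the coronary
   survives averaging instead of being scattered by garbage fields.
5. **Loop-closure enforcement** — the composed cycle residual is
   distributed equally over the N fields and iterated.  On consistent
   smooth fields this converges below 0.1 voxel (and is required to); on
   measured noisy fields it converges to the level set by registration
   inconsistency, which is reported via a warning rather than an error.

Warping composes adjacent-phase fields along the shorter arc of the cycle
(≤ N/2 trilinear compositions; backward arcs use fixed-point field
inversion) and the warped volumes are averaged with no Jacobian density
compensation (intensity-only superposition).  On a static scan the MoCo
volume's noise matches the ungated standard reconstruction within a few
percent — the dose-efficiency claim at the heart of the method — while
the 10 % phase window alone pays a √10 noise penalty.

## Tensor-based adaptive filter (`tbaf`)

Structure tensor: Gaussian-derivative gradients (σ_g = 1 vox), outer
products smoothed at σ_t = 2 vox, per-voxel eigen-decomposition.  The
volume is smoothed with an oriented 1-D Gaussian (half-length 3 voxels)
along the eigenvector of the **smallest** eigenvalue — the direction of
least intensity variation, i.e. along edges and tubes.  (The source
description reads "the direction corresponding to the largest Eigenvalue",
which for a gradient-based tensor points across edges and would destroy
structure; the established convention is adopted and the discrepancy
flagged.)  Kernel width is modulated by a local noise estimate (MAD of the
volume Laplacian over 5³, scaled 1.4826/√42) and suppressed where the
smallest eigenvalue rises above its own noise floor (true variation along
the filtering direction).  The filter needs no interaction, preserves the
mean to <0.1 %, removes ≥30 % of flat-region noise at <15 % edge-width
growth, weakens on its own output (noise adaptivity), and deviates less
from a noisy linear ramp's best-fit plane than an iterated bilateral
baseline at matched blind noise reduction.

## Metrics and the dose sweep (`metrics`)

* Detectability uses the Rose criterion CNR ≥ 4 as the operational proxy
  for visual identifiability; every serialized report states this.
* Coronary CNR uses the phantom's ground-truth lumen mask of proximal
  segments (simulation privilege) as the signal ROI and eroded adjacent
  myocardium as background.
* STS-MIP is a sliding-window maximum; vessel tracking is threshold
  segmentation → 3-D skeletonization → longest geodesic path from a seed,
  with diameters from the distance transform and end-retraction corrected
  by one local radius.  For display, a constant 1 mm radius tube can be
  rendered around the tracked centerline (the real lumen is far below
  rendering scale).
* The dose sweep thins frames to 2000/1500/1000/500 mGy of the 5 Gy
  protocol (fractions 0.4–0.1), reconstructs PC and MoCo at the reference
  (late-diastolic) cardiac bin inside the end-expiration window, and
  reports noise, CNR, detectability and tracked-length fraction.  On the
  desk profile CNR(MoCo) > CNR(PC) at every level; note the desk scan has
  10× fewer frames than the full protocol, so its 500 mGy arm is far
  harsher (≈6 frames per joint bin) than the equivalent full-protocol arm.
* The dose-resolution experiment reconstructs one set of noisy cylinder
  projections at voxel sizes 0.15 and 0.30 mm (cutoffs at each grid's
  Nyquist, detector sampled at 0.0375 mm iso-pitch so neither band is
  detector-limited), fits σ² = a/dose per grid over three photon budgets
  × two realizations, and reports a_fine/a_coarse ≈ 16.

## What the synthetic experiments do not show

The phantom is a smooth compound of quadrics: no trabeculae, valves,
perfusion or contrast washout, no spectral physics (scatter, beam
hardening, focal-spot blur, detector lag), no arrhythmia or outlier
breaths, and exactly periodic motion (optional Gaussian phase jitter
exists but is off by default).  Passing tests therefore demonstrate the
internal consistency and the scaling laws of the reconstruction chain
under its own forward model — not in-vivo visibility rates, which depend
on animals and hardware.  The in-vivo endpoints (left-coronary visibility
in all animals, apex tracking in a fraction of them, right-coronary
invisibility due to its motion speed) are outside simulation scope.

## Reproducibility

Every stochastic step takes an explicit seed; the CLI derives per-stage
seeds from one global seed by stable hashing and writes JSON manifests
with SHA-256 checksums of all inputs and outputs, so any reported number
traces to the artifacts and parameters that produced it.  Problem sizes in
the test suite (desk profile, 72³ grids, 2,580-frame scans, reduced Demons
iterations) are the package's desk-scale defaults chosen so the full suite
runs on a single CPU.
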
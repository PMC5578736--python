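# Methods

This note documents the models implemented in `ecstransport`, the
defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical choices that matter when
interpreting results.

## Transport models

**Halfspace (surface-source) model.** Tracer applied to the brain
surface is modelled as a constant-concentration reservoir over a
semi-infinite homogeneous medium:

    C(x, t) / C0 = erfc( x / (2 √(D t)) )

This matches a tracer-filled subpial space that stays replenished over
the ~1 h experiment. An instantaneous plane-source alternative
(`source="bolus"`, Gaussian in depth) is provided for cases where the
surface pool depletes; the constant source is the default. Fractional
decay depths follow by root finding: d_f = 2√(Dt)·erfc⁻¹(f), so depth
scales as √(Dt) and relative depths across tracers as √D — the core
diffusive signature. First-order clearance (rate k) multiplies the
absolute amplitude by e^(−kt) and cancels from surface-normalized
profiles; no clearance or barrier parameters are fitted.

**Point-source (injection) model.** A ~nanolitre intraparenchymal
bolus is approximated as a point release in free space,
C(r,t) = dose·(4πDt)^(−3/2)·exp(−r²/4Dt); the 10%-decay radius is
r₁₀ = √(4Dt·ln 10). The finite injection volume is ignored because
early-time distributions are dominated by the injection itself and the
model is only applied at later times, where the Gaussian width swamps
the initial extent.

**Hindrance and ECS volume.** Tissue hinders diffusion by the
tortuosity λ: D_eff = D_free/λ². The ECS volume fraction α scales how
much tracer a block of tissue holds (tissue-averaged concentration
α·C_ecs) but not the shape of a surface-normalized profile; a genotype
that only enlarges α therefore shows the same relative penetration
unless D_eff changes too. This linear-scaling treatment is a
deliberate simplification; more elaborate α-dependent models exist but
add parameters the data here cannot constrain.

**Default tracer panel.** D_ecs = 51, 7.5 and 1.0 µm²/s for the 10, 70
and 2000 kDa dextrans (the 2000 kDa value derives from its aqueous
coefficient and an assumed λ = 2.64). Diffusion coefficients are
accepted in cm²/s in configs and converted exactly (1 cm²/s = 10⁸
µm²/s); all internal computation is in µm and seconds, velocities are
accepted in µm/min and converted to µm/s.

## Convection–diffusion simulator

Explicit forward-time central-space diffusion plus first-order upwind
advection on a uniform grid; the automatic step is 0.4× the linear
stability bound 1/(2D·Σ1/Δx² + Σ|v|/Δx), and an explicit dt above the
bound raises an error naming the admissible maximum. The scheme
conserves mass to machine precision with closed or periodic boundaries
and preserves nonnegativity. Upwinding introduces numerical diffusion
of order v·Δx/2, visible only in the Galilean-invariance check at the
few-percent level.

Defaults: 100 × 100 µm field at 0.5 µm spacing (the two-photon field
of view), **fixed-concentration boundaries** — the rim is clamped to
the pre-bleach value, representing tissue extending far beyond the
imaged region. Closed and periodic boundaries are available for
conservation and invariance tests. Velocity is uniform across the
field; simulated "convection" is directional flow, not a solved
pressure field (no poroelasticity, by design).

Photobleaching multiplies the field inside a disk by
(1 − depth_fraction), with 4×4 sub-sampled anti-aliasing at the rim.
In thin-disk 3-D mode the grid gains a 20 µm axial extent and the
bleach is confined to the central ~3 µm slab (4 cells at 1 µm axial
spacing, so the realised slab is 4 µm); the imaged plane is the mean
over that slab. 2-D mode is the default for speed; the 3-D mode
recovers faster at equal D because of axial replenishment.

A consequence worth stating plainly: with a 3 µm slab and unbleached
tissue 1.5–8 µm above and below, axial replenishment caps the
half-recovery time at roughly (h/2)²/D regardless of spot diameter, so
simulated t₁/₂ versus diameter *saturates* beyond ~15 µm rather than
growing linearly (a linear fit over 5–40 µm reaches R² ≈ 0.88–0.93,
not better). Experimentally, recovery time is reported to grow roughly
linearly with spot radius; reproducing that would require the bleached
volume to extend axially with spot size, as the out-of-focus dose of
raster-scan two-photon bleaching does. The fixed-thickness slab is a
known limitation of this geometry, not a tuning target.

## FRAP analysis

Recovery is normalized as F(t) = (I(t) − I₀)/(I_pre − I₀), with I_pre
the mean over pre-bleach frames and I₀ the first post-bleach ROI mean;
t₁/₂ is the earliest time F crosses 0.5, linearly interpolated between
frames and reported as absent (never extrapolated) if the curve never
gets there. The plateau is taken to be the pre-bleach level — dextrans
in ECS have no immobile fraction worth modelling, so no immobile-
fraction correction is applied. An unbleached stack (I_pre = I₀) is a
degenerate input and raises rather than returning a flat curve.

**Quadrants.** The bleached disk is split into four 90° sectors,
axis-aligned by default and rotatable. The asymmetry index is
(max t₁/₂ − min t₁/₂)/mean t₁/₂ across sectors: exactly 0 for
noiseless zero-flow recovery (by symmetry), a noise floor with photons,
and increasing with flow speed.

**Centroid tracking.** Per frame, the difference image (pre-bleach
reference − frame) is convolved with a normalized disk (default 10 µm,
the scanning circle); the spot centre is the grid argmax refined by a
1-D quadratic fit along each axis of its 3×3 neighbourhood (offsets
clipped to ±½ pixel). From the second frame on, the search is
restricted to a window of 2× the scan diameter around the previous
position (preventing lock-on to distant noise) and ties break toward
the smallest displacement. Apparent speed can be read either as
end-to-end displacement over time (used for the detection bound, see
below) or as the norm of a linear least-squares fit of position against
time, which uses every frame and is the estimator used for velocity
recovery (it averages down the late-time tracking noise that inflates
an end-to-end reading of slow flows).

**Velocity upper bound.** The detection floor is calibrated
empirically: track ≥10 zero-velocity simulations at matched noise and
take the 95th percentile of end-to-end displacement divided by the
observation time (µm/min). An observed trace is called directional
only above that bound. With the default synthetic conditions (D = 0.4
µm²/s, 50% bleach, 60 s, ~100 photons/pixel at 0.5 µm pixels, 20
nulls) the bound computes to ≈ 2.8 µm/min. This number is set almost
entirely by the photon budget: the late-time deficit (~10 counts above
a 0.56-count disk-filtered noise floor) permits ~1.2 µm of per-axis
argmax jitter at 60 s, which is the theoretical noise floor of the
scanning-circle statistic itself, not an implementation loss. At the
~6× higher photon flux per 0.5 µm cell that a 512×512 acquisition of
the same field would collect, the identical tracker calibrates to
≈ 1 µm/min. The detector gain of the emulated instruments is unknown,
so the noise default is a stated assumption; the bound should be read
as conservative for bright acquisitions. The bound scales down with
photon count (verified as a monotone trend in the tests).

**Registration.** Optional rigid pre-registration to the pre-bleach
frame (phase cross-correlation with mean subtraction, plain
cross-correlation normalization, sub-pixel upsampling) removes
heartbeat-like jitter. It requires image structure: on a featureless
synthetic field there is nothing to register, so the generator offers
a static tissue-texture option (below). With 1 µm jitter and 20%
texture, registration reduces apparent centroid noise ≳2× (pooled over
seeds).

**Statistics.** Group comparisons of t₁/₂ are plain two-sample t-tests
with group means ± SEM (scipy); section-position × genotype
comparisons use two-way ANOVA (statsmodels); both are thin wrappers by
design. The power-analysis effect size is d = Δ%/σ%. A blinding helper
hashes group labels until reporting.

## Synthetic-data generator

Ground truth (D, v, geometry, noise, seed) rides along in metadata on
every output, making closed-loop tests the package's backbone:
generate with known parameters → analyze → compare. What it emulates:
Poisson photon noise (default 100 expected counts per unit
concentration per pixel), Gaussian read noise (2 counts), optional
per-frame rigid jitter, optional static multiplicative tissue texture
(Gaussian random field, 3 µm correlation length); section images with
a bright sub-pial band (5× parenchymal surface, exercising the 1/4/16
µs exposure-bridging path), erfc depth decay per channel and straight
paravascular streaks with exponential longitudinal decay and
size-independent amplitude; injection images with radial Gaussian
spread. What it does not emulate: realistic tissue morphology, PSF
blur, vessel branching, detector nonlinearity, slow drift or
photobleaching during imaging. Passing closed-loop tests therefore
demonstrates correctness of the analysis chain under the stated noise
model, not robustness to every artifact of real microscopy.

The default FRAP tracer mobility is D = 0.4 µm²/s, chosen so the
simulated 10 µm disk recovers with t₁/₂ ≈ 14 s — the observed
timescale for a 500 kDa dextran in cortex (partial recovery ~20 s
after bleaching, followed for 60 s), and consistent with a free-
solution coefficient of ~15–20 µm²/s hindered ~3-fold-squared in ECS.
The repeat-bleach (arrest) recipe uses a 150 kDa-like tracer at
D = 1 µm²/s bleached by 30%, recovering in ~5 s so the same spot can
be bleached repeatedly; the anoxic-swelling surrogate divides D by 3.

## Problem sizes and numerical choices

* Fractional decay distances: bracketing + Brent root find to 10⁻³ µm.
* Depth profiles: pixel distance to a densified surface polyline via
  Euclidean distance transform; sidedness from the local tangent keeps
  the bright band out of the parenchymal bins; 1-pixel bins; d₁/₂ by
  linear interpolation. Radial profiles: 1-pixel annuli.
* Simulations in tests and recipes run at 1 µm spacing where a
  grid-convergence check shows < 1% RMS difference from the 0.5 µm
  default (recovery curves), and at 0.5 µm where the tracking noise
  floor is itself under study. The thin-disk sweep uses 1 µm spacing,
  domains scaled to 3× the bleach diameter, and 6 diameters between 5
  and 40 µm. The null-bound calibration uses 20 seeds; velocity
  recovery 5 seeds per speed; the arrest null-specificity check 50
  replicates of 3-vs-3.
* Ties in the centroid argmax break toward the previous position;
  sub-pixel offsets are clipped to ±½ pixel; degenerate inputs
  (no bleach, zero-length segments, empty masks, λ < 1, α ∉ (0,1])
  raise typed errors rather than returning silent defaults.

## Known limitations

* Homogeneous, isotropic media only: no white-matter anisotropy, no
  3-D brain geometry, no paravascular flow coupling.
* Velocity fields are imposed, not derived from pressure.
* The α model is a pure uptake scaling; profile-shape effects of ECS
  remodelling enter only through D_eff.
* The thin-disk geometry cannot reproduce linear t₁/₂-vs-radius
  scaling (see above).
* The velocity detection floor depends directly on the assumed photon
  budget; treat the default as conservative.
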
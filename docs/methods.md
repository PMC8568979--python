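# Methods

This note documents the models implemented in `qlfm`, the defaults and
their rationale, the numerical choices that affect results, and what the
synthetic experiments do and do not demonstrate.

## Optical model

All lengths are micrometres; depth z is signed, z = 0 at the native
objective plane, +z toward the objective.

**Geometry.** A microlens array (pitch p, focal length f) sits at the
image plane; a relay (magnification m_r) images its back focal plane onto
the camera (pixel pitch p_c). The pixels behind one lens,
`pixels_per_lens = round(p·m_r/p_c)`, must be odd so a central chief-ray
angular component exists. The simulation uses the exactly commensurate
pixel `p/pixels_per_lens` at the MLA plane, absorbing the sub-percent
relay rounding. `effective_magnification` is an explicit field: real
systems (tube-lens mismatches) deviate from the objective's nominal
magnification, and the lens footprint at the sample plane
(`mla_pitch/effective_magnification`) is the native sampling of every
reconstruction. The ×40/1.0 NA preset stores the measured 46.5×
(2.15 μm per lens); the ×20/0.5 NA preset — the default for synthetic
work, because its out-of-focus blur footprints stay desk-sized — uses the
nominal 20× (5 μm per lens) and is NA-matched to the MLA within 5 %.

**PSF.** For a point source at depth z the pupil field is
`exp(i·k₀·n·z·cos θ(ρ) + i·φ_ab(ρ, θ))` over the NA-limited pupil
(scalar, unit amplitude — no aplanatic apodisation), transformed to the
MLA plane by a zoomed DFT (Bluestein), multiplied by the 100 %-fill
square thin-lens phase of each lenslet, Fresnel-propagated one focal
length (transfer-function form), squared, and box-integrated over camera
pixels (2× subsampling by default). Realigning the patch per lens yields
the *phase-space PSF*: one lateral convolution kernel per angular
component per depth, on the lens-pitch grid. This per-angle
shift-invariant approximation is the package's central reduction; it
discards sub-lens-pitch spatial variation, which is exactly the
information realignment cannot represent anyway.

Numerical safeguards: the pupil grid (default 256²) is automatically
enlarged so the defocus + window + aberration phase never exceeds π per
sample (deep depths need ~1000²); kernels converge to <1 % when the
pupil sampling is doubled (tested). The lateral support follows the
marginal-ray blur diameter with a 1.35 margin plus 4 lenses; a
configuration error reports when the z = 0 window would hold <99 % of
the energy an enlarged window detects.

**Energy bookkeeping.** Kernels are normalised so the total detected
energy at z = 0 is 1. Per-depth totals stay within [0.9, 1.01] of that:
deep kernels may carry up to ~1 % *more* because the in-focus Airy tails
lose a little energy outside any finite window while defocus disks are
compact.

**Symmetry caveat.** The unaberrated PSF is exactly even under joint
angle+space inversion at fixed z. It is *not* exactly mirror-symmetric
under z → −z: the microlens refocusing term places sub-images before vs
behind the sensor for ±z. The geometric content mirrors (per-view
parallax centroids flip sign); kernel correlation between ±z mirrors is
0.94–0.99. Tests assert the symmetry at that level rather than exactly.

## Multiscale complete space

Lateral and axial resolution degrade away from focus; following an
exponential fit `R(z) = α·e^{β|z|} + γ` the volume is tiled into axial
slabs whose lateral step is the largest power-of-two multiple of the
lens pitch still at Nyquist (`step ≤ R_xy/2`), doubling at most once per
transition, with axial step `R_z/2` rounded to an integer plane count
per slab. The high-resolution half-range — inside which resolution is
treated as constant — defaults to the |z| where `R_xy = 1.2·R_xy(0)`.
Slab boundaries closer than one fine axial step are merged at their
mean, so symmetric ranges produce symmetric grids. For ±300 μm at the
desk preset this yields ~1.5 k voxels instead of ~12 k; for ±500 μm at
the ×40 preset the reduction is more than tenfold.

Two resolution-model sources exist: `analytic_resolution_model`
(marginal-ray blur combined in quadrature with the 2×-lens-pitch
sampling floor; axial = 3× lateral by default, reflecting the axial
elongation of low-NA LFM PSFs) and `resolution_model_from_psf`, which
fits the simulated PSF's own width-vs-depth curve. Both feed the same
fitting routine; the analytic route is the default because deep ranges
would otherwise require very large wave simulations for no extra
fidelity.

Volumes store photons per voxel. Resampling between grids interpolates
*density* (value/voxel volume) trilinearly with nearest-edge clamping and
rescales by the destination voxel volume — mass-preserving within ~1 %
for smooth fields, exactly value-preserving for constants, bitwise for
identical grids.

## Scattering model

Scattered light is modelled as single (first-Born), isotropic,
incoherent redistribution: `I⁽ˢ⁾ = ½·(F∘I) ⊛ K` with
`K(Δr) = ΔV/‖Δr‖²` and the self-voxel value regularised to the kernel at
half the voxel diagonal (finite, grid-convergent). Scattered photons are
added to the emission field *before* projection — scattered light is
imaged like fluorescence. On multi-slab grids the product is routed
through a uniform auxiliary grid (2× lens pitch laterally) via sparse
mass-preserving interpolation matrices whose transposes provide the
adjoint; on a single uniform slab the convolution is direct, and it
matches an O(N²) direct summation to 1e−6 relative error.

The potential update is projected gradient on
`‖P(I + S(F, I)) − y‖² + λ_F‖F‖²` (λ_F = 1e−3 relative to the squared
mean data level) holding I fixed. The misfit is quadratic in F, so each
step uses the exact line search along the gradient with a backtracking
safeguard; non-negativity by projection. **Identifiability**: F is only
observable where light traverses it (the data constrain F·I), so
recovery experiments include a weak diffuse emission component in the
medium; with emission held fixed a smooth potential blob is recovered to
Pearson ≈ 0.9, while the fully joint decomposition — which is inherently
degenerate (emission can mimic scatter) — recovers the blob's shape to
~0.7.

## Reconstruction

Emission updates are Richardson–Lucy multiplicative steps
`I ← I · Aᵀ(y/(A I + ε)) / Aᵀ1` with ε = 1e−8 × max(y), cycled
centre-out (spiral) over angular components; each angular focal stack
(one angle, all scan positions) is the error-map unit. Because
ordered-subset cycling is not guaranteed monotone, the Poisson data loss
is monitored per full cycle and a cycle that would increase it is
replaced by the joint all-angle EM update (which is monotone); the
monitored misfit therefore never increases over accepted steps. The
outer loop alternates RL cycles (default 10) with potential updates
(default 3 steps) for 3 outer iterations, under an ADMM consensus
splitting with non-negativity indicators (ρ = 1): since the
multiplicative and projected updates never leave the feasible set, the
splitting's subproblems are trivially satisfied and the scaled duals
remain zero — the structure is kept for generality (e.g. penalties that
do bind). Background is handled purely by the coarse complete-space
slabs; there is deliberately no constant-background term.

Axial scans reconstruct on one global grid spanning all scan positions
(distance-to-nearest-position replaces |z| in the resolution model); the
forward model for scan position s uses kernels at z − s. A single scan
position reduces exactly to the snapshot reconstruction (same code
path). The scan step should be comparable to the high-resolution axial
range; a larger step is warned about and produces genuinely uneven
coverage (beads outside every position's high-resolution band
reconstruct dimmer).

## Calibration

Sub-aperture (u, v) maps to the pupil point (u, v)/u_max. The view
displacement of a bead image obeys d = −(1/NA)·∂W/∂ρ (transverse ray
aberration; sign fixed by the simulator's phase convention). Shifts are
measured by FFT normalised cross-correlation with parabolic sub-pixel
peak interpolation; angles scoring <0.2 are excluded (≥60 % must
survive). Slopes are zonally integrated by sparse least squares over
neighbour differences (piston removed) and the surface fitted with Noll
modes (default 15); piston/tip/tilt are excluded from the PSF model
(they encode bead position, not aberration). The loop simulate →
correlate → integrate → fit → accumulate runs until the RMS coefficient
change drops below λ/50 (≤10 iterations).

**Protocol note:** the bead must be moderately *defocused* (default
30 μm in the synthetic experiment). At the native plane the entire PSF
sits under one microlens and lens-pitch-sampled views carry almost no
sub-aperture shift information; defocus spreads the light over many
lenses, giving the correlations their Shack–Hartmann sensitivity. With
0.5 waves spherical + 0.3 waves astigmatism the loop converges in ≤4
iterations and recovers both within 15 % (within 25 % under Poisson
noise at 1000 peak counts).

## Synthetic data

The generator emulates bench characterisation samples: fluorescent beads
(spheres rasterised with 4³ antialiasing, or trilinear point deposits
below half a voxel; per-bead mass matches the analytic sphere volume to
2 %), a smooth non-negative scattering potential (low-pass Gaussian
random field rescaled to an exact mean), and nonuniform out-of-focus
background confined to the coarse slabs. Captures run the full forward
model, map views to the sensor by inverse realignment, and apply Poisson
shot noise then Gaussian read noise (σ = 1.6 counts, a typical sCMOS
figure). Default desk geometry: 15×15 lenses, 13×13 pixels per lens,
5×5 angular components retained for reconstruction (symmetric pixel
groups summed after realignment, so Poisson statistics survive binning),
±60 μm fine range with coarse slabs to ±300 μm.

The benchmark experiment (`qlfm.experiments.sbr_fold_change_experiment`)
uses ten 2-μm beads at 60 photons/μm³, scattering level 0.05, background
25 photons per coarse voxel, Poisson at 1000 peak counts: the full
scattering model improves bead SBR 3.2–3.8× over the incomplete-space
reconstruction across seeds.

**What passing these tests does not show:** the phantoms are generated
by the same forward model used for reconstruction (no model mismatch
beyond noise), scattering is single and isotropic (no anisotropic phase
function, no multiple scattering), aberrations are field-independent,
and lens-grid rectification is assumed known. Real-data performance
additionally depends on all of these.

## Known limitations

- Coarse slabs cover only the lateral field of view; fluorophores just
  outside it are not modelled.
- The joint emission/scattering decomposition is degenerate without
  structural priors; only the data fit and non-negativity disambiguate.
- The phase-space approximation discards sub-lens-pitch spatial detail;
  there is no vectorial/polarisation PSF and no spatially varying
  aberration.
- `inverse_realign` requires full angular sampling; angularly binned
  views cannot be mapped back to a sensor frame.
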
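# Methods

`lungdce` implements a complete desk-scale replica of a preclinical
dynamic contrast-enhanced (DCE) lung MRI pipeline: continuous tiny-golden-
angle radial UTE acquisition of a rat thorax, sliding-window image
reconstruction, model-free enhancement analysis, and the accompanying
morphometry (lesion histogram volume, histology tissue fraction, SNR QC).
Because no raw animal data are redistributable, a digital dynamic phantom
stands in for the scanner, and every stage is validated against the
phantom's known ground truth.

## Acquisition model

The acquisition is 2D multi-slice radial UTE with center-out half-spokes.
Spoke *i* is at angle ψ·i (mod 360°) with ψ = 180°/(φ + N − 1), the
generalized (tiny) golden angle; the default order N = 7 gives ψ = 23.63°,
small enough to limit gradient jumps between shots while keeping any
consecutive 90-spoke subset quasi-uniform (maximum angular gap < 5°, a
property the tests assert numerically).  The sequence loops over all
slices at each angle, so the effective per-slice repetition time is
TR_eff = n_slices · TR_profile (114 ms = 38 × 3 ms at full scale).
Protocol constants: TE = 0.368 ms, flip 40°, FOV 58 × 58 mm², matrix 96,
slice thickness 1.208 mm, 7 min baseline before contrast injection,
28 min total.

## Reconstruction

**Density compensation.** Radial sampling over-covers the k-space center;
each sample is weighted by its normalized radius |k|/k_max (ramp
weighting).  The k = 0 sample, shared by all spokes, would get weight 0;
it is floored instead.  The default floor is 1/(8(S−1)) for S samples per
spoke — exactly the weight for which the floored value equals the area of
the disk-shaped cell (radius half a radial step) that the DC sample owns.
A larger floor (e.g. a fixed 0.01) measurably over-weights the center and
adds a uniform intensity offset of a few times the parenchymal signal
level to the reconstructions, which biases the relative-enhancement maps
of dim compartments; the floor remains user-configurable.

**Gridding.** The adjoint NUFFT: weighted samples are spread onto a 1.5×
oversampled Cartesian grid with a width-4 Kaiser-Bessel kernel (β from the
Beatty formula), inverse FFT, deapodization by the kernel's analytic
transform, and central crop.  The forward operator is the exact conjugate
transpose (the adjoint identity holds to ~1e-15; tests require 1e-6), and
both match naive nonuniform-DFT summation oracles to ~0.2–1% NRMSE.  An
overall scalar — k_max · Δk_r · 2π/P, the annular-sector area element —
makes the adjoint quantitative so reconstructed intensities approximate
the phantom's signal units.  Zero-filling (default ×2 in the CLI, giving
0.302 mm apparent pixels from 0.604 mm acquired ones) is k-space
zero-padding before the final inverse FFT.

**Sliding window.** Frame k covers profiles [k·step, k·step + window),
0-based half-open, window 90 and step 60 by default: 10.26 s per frame
(reported as 10.2 s) every 6.84 s (reported 6.8 s) at TR_eff = 114 ms.
Trailing profiles that cannot fill a window are dropped; the frame count
is floor((n_profiles − window)/step) + 1, derived from the input length
rather than hard-coded, because the total acquired profile count is what
determines it.  A high-quality baseline volume uses the first 3000
(pre-injection) spokes through the same path.

**Regularized reconstruction.** Optionally each frame solves

argmin_x ‖W^{1/2}(Ax − y)‖² + λ₁‖Ψx‖₁ + λ₂‖x‖²

with monotone FISTA (power-iteration step size, momentum restart when the
objective would increase, diagnostic error if it increases persistently).
Ψ is an orthogonal Daubechies-4 wavelet (3 levels, periodized; prox =
exact complex soft-thresholding) or, as a configuration alternative, an
(anisotropic) total-variation penalty via Chambolle denoising of the real
and imaginary parts.  The default weights λ₁ = 0.00536 and λ₂ = 0.0016
(ratio 3.35) are the protocol's empirically determined values; they were
tuned in a toolbox that normalizes the data, so each slice is scaled to a
peak-magnitude-one reconstruction before solving and scaled back after —
without this the weights are meaningless on arbitrary data scales.
Whether density compensation sits inside the data term is a switch
(`dcf_in_solve`, default on); both variants solve to visually identical
images on the phantoms, differing in their noise weighting.

## Synthetic phantom

The phantom is a stack of nested elliptical compartments: body wall,
left/right lung parenchyma with a perfusion-rich central (hilar) zone,
large vessels, an inflammatory/remodeling lesion, and — for the
late-fibrotic preset — a peripheral low-density expansion zone.  Each
compartment has a baseline T1₀ and proton density and an enhancement
course ΔR1(t) = A(1 − e^{−(t−t₀)/τ_in})e^{−(t−t₀)/τ_out} (uptake ×
washout product; peak at τ_in·ln(1 + τ_out/τ_in)).  Signal follows the
steady-state SPGR equation S = PD·sinα(1 − E1)/(1 − cosα·E1),
E1 = exp(−TR_eff(1/T1₀ + ΔR1)).  The forward model renders the
compartment signals at every profile's time stamp and evaluates the
nonuniform DFT along each spoke by direct summation over nonzero pixels —
exact with respect to the rasterized phantom and sharing no code with the
FFT reconstruction it is used to test.  Complex Gaussian noise is seeded
and added per sample; optionally every sample is then multiplied by a
slow global modulation m(t) = 1 + a·sin(2πt/T) emulating the time-varying
streak/artefact level of continuous scanning (default amplitude 3%).

**Parameter choices.** Parenchyma (T1₀ 1.8 s, PD 0.25) and body (1.9 s,
0.9) are literature-typical placeholders for 9.4 T — the study organism's
actual lung relaxation times are not published — and T2* decay during the
0.368 ms TE is folded into PD.  Vessels and lesions use deliberately long
*effective* T1₀ (9 s and 6 s): with flip 40° at TR_eff 114 ms a physical
tissue T1 saturates the SPGR ratio near relative enhancement ≈ 3, whereas
the in-vivo data reach RE > 12 through inflow of unsaturated spins; the
long effective T1₀ reproduces that dynamic range within the SPGR form.
The default k-space noise (sd 0.015 per component) yields parenchymal
SNR ≈ 25 in a single 90-spoke frame.

**Disease presets.** `control`, `bleo_d7` and `bleo_d28` are calibrated
to the study's group means: total lung volume 4.4 / 5.5 / 6.5 ml,
baseline high-intensity (vessel + lesion) volume 0.64 / 1.03 / 1.70 ml,
and per-compartment peak enhancements chosen so the low-enhancement
(peak RE < 3) lung fraction is ≈ 61 / 50 / 74%.  Compartment areas are
fitted per slice by bisection on the rasterized pixel count, so the
ground-truth volumes land within ~0.05 ml of their targets at any matrix
size or slice count.  Reduced-slice desk phantoms (default matrix 64,
4 slices) keep volumes intact by thickening the slabs (1.208·38/(4·n_z)
mm) and scale all time constants by n_z/38 together with TR_eff, so
profile counts per acquisition phase mirror the full protocol (baseline
frames 1–50 pre-injection, ~3700 baseline profiles).  The day-7 preset
additionally slows the diffuse tissue washout (τ_out 700–800 s vs 300–350
s), modeling the inflammatory permeability increase that sustains its
group-mean curve above controls during washout.

**Binning phantom.** A separate four-class phantom validates the 7-class
binning end to end, with peak enhancements 0.5 / 2.5 / 9 / 15 (classes
0, 2, 5, 6).  Its geometry follows explicit resolvability rules rather
than anatomy: compartments tens of pixels across, several pixels of
separation between blobs of very different enhancement, baseline signal
matched across neighbours so partial-volume mixing interpolates (rather
than amplifies) enhancement, and a moderately enhancing body wall (peak
RE 1.3, muscle-like) chosen so boundary mixes can cross neither the RE=2
edge from below nor the RE=1 edge from above.  With the regularized
reconstruction, ≥ 95% of each compartment's pixels classify correctly at
default noise.

## Model-free DCE analysis

Baseline S0 is the per-pixel mean of frames 1–50 (validated to lie before
the recorded injection time).  Relative enhancement is RE = (S − S0)/S0
(`re_mode="delta"`; a ratio convention S/S0 is available, under which
"below 3× baseline" thresholds the ratio at 3).  The background trace
b(t) = (B(t) − B0)/B0 is measured in four 8×8 corner ROIs outside the
animal and subtracted from all curves per animal; a `divide` mode
((1+RE)/(1+b) − 1) is provided because it is exact for a purely
multiplicative global drift, while subtraction leaves a residual of order
b·RE (the subtractive default follows the study's method).  Pixels are
binned by their maximum corrected RE in the 60 s directly after injection
(thresholds 1, 2, 3, 4, 8, 12 → classes 0–6); bin volumes partition the
lung volume exactly by construction.  The "low-enhancement volume"
aggregates all classes whose upper edge is ≤ 3 — i.e. classes 0–2; the
phrasing "the three lowest signal bins, bins 0–3" is internally
inconsistent (three bins vs four labels) and is resolved as the classes
below the RE = 3 threshold, with the threshold exposed.  Lung volume is
voxel count × pixel area × slice thickness, on the grid the mask was
drawn on.

Two caveats the phantom work surfaced, documented here because they
affect how the correction should be read: (i) corner ROIs measure not
only global drift but also the enhancement-coupled streak level — when
the object's total signal roughly doubles after injection, b(t) rises
with it, and subtracting it from tissue curves over-corrects whenever the
in-lung artefact level does not track the corner level one-to-one;
(ii) after wavelet-regularized reconstruction the corners are largely
shrunk to zero, making B0 small and b(t) noisy — the correction is only
meaningful on artifact-preserving (gridding) reconstructions or with
real-data noise floors.  The drift-correction validation therefore
compares corrected curves of a drifting acquisition against the
identically corrected drift-free acquisition, and the binning validation
on the drift-free phantom uses uncorrected maxima (`background_mode` is
configurable, including `none`).

## Morphometry

Lesion burden on the 3000-spoke baseline volume is the lung-ROI volume
above mean + k·SD of the lung intensity distribution.  The rule is an
explicit, configurable surrogate for a previously published histogram
method that the protocol cites without restating.  The default is k = 1:
in these phantoms (and the study's lungs) the bright vessel/lesion
plateau holds 15–20% of the lung volume, and for a bimodal distribution
with that bright fraction mean + 2·SD lands *above* the plateau,
excluding the lesions entirely; k = 2 remains appropriate for sparse
bright tails and is available.

Histology sections are single-channel images thresholded at 900 (scanner
export scale): strictly greater is tissue, at-or-below is air.  Color
images are summed across channels first, since 900 exceeds the 8-bit
single-channel range.  The synthetic section generator thresholds a
smoothed Gaussian random field at the (1 − f) quantile and draws
intensities from well-separated truncated distributions on either side of
900, so the generating fraction is recovered to the quantile granularity.
Fractions 0.43 and 0.33 mirror the control and fibrotic group means.

SNR is mean(signal ROI)/sd(noise ROI), with the background-magnitude
(Rayleigh) bias correction dividing the measured sd by √(2 − π/2) ≈ 0.655
(on by default).  The noise-propagation prediction σ_img =
σ_k·√Σ(w_j·A_j)² holds for the direct-DFT adjoint; in gridded images the
deapodization roll-off amplifies the rim (including the corners) by up to
several-fold, so quantitative noise checks use the direct recon.

## Problem sizes and numerical choices

Unit tests run a matrix-32, 2-slice, ~2700-profile phantom (seconds).
End-to-end validation uses matrix 64, 4 slices, ~5000 profiles (about one
minute to simulate, a similar time to reconstruct 82 sliding-window
frames with the regularized solver at 30 iterations).  All randomness
flows through a single seeded generator per simulation; identical seeds
give bit-identical k-space, and the pipeline runner reproduces its JSON
report byte-for-byte for a fixed configuration.  Ties and edge cases:
bin thresholds are right-open intervals (a maximum exactly at a threshold
joins the upper class); histology pixels exactly at 900 count as air;
S0 ≤ 0 pixels are excluded from RE and counted in the report.

## Known limitations

The phantom has no respiratory or cardiac motion, no coil-sensitivity
structure, no B0/trajectory miscalibration (a per-sample phase-correction
hook exists but measured calibration files are out of scope), and its
arterial input is a fixed analytic course per compartment, not a
circulating bolus — pharmacokinetic model fitting is deliberately
unsupported.  Passing the phantom tests shows the pipeline's operations
are numerically faithful; it does not show that the biological
group-level findings would reproduce on new animals, nor does the
enhancement-coupled background behaviour of the phantom exactly replicate
the motion-driven artefacts of real continuous radial scans.
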
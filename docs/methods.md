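# Methods

## The physical model

Residual inhomogeneity of the static field of an NMR magnet — imperfect
shimming — broadens and skews every line of a 1D spectrum in the same way.
To a very good approximation the observed spectrum is the ideal spectrum
convolved with a single *response function*: an N-point real kernel whose
shape encodes the field distribution over the sample volume.  `postshim`
implements post-acquisition correction in three stages:

1. **Calibration.** A scan of the two lowest axial shim coils (Z1, Z2)
   around their optimum records a narrow-singlet spectrum at each setting.
   Each mis-shimmed spectrum is deconvolved against the best-shimmed one by
   linear least squares, yielding a library of measured response functions
   for that spectrometer.
2. **Hybrid online training.** Clean synthetic spectra of random
   Lorentzian–Gaussian multiplets are convolved with randomly drawn library
   responses plus white Gaussian noise, and an attention-equipped
   convolutional autoencoder is trained to invert the distortion.  Every
   batch is freshly generated and never reused.
3. **Correction.** A measured spectrum is resampled to the training
   frequency step, its tallest point scaled to 16, passed through the
   network, unscaled and resampled back onto its original grid.

## Response functions and deconvolution

A response function is a vector of N real values at frequency step Δf, with
center index (N−1)/2 corresponding to zero shift; a well-chosen N makes the
values decay to zero at both ends.  Extraction solves

    argmin_r ‖A r − d‖² + λ‖r‖²

where A is convolution-by-the-best-shimmed-spectrum restricted to a window
around the calibration peak and d is the distorted spectrum there.  The
window defaults to the span of the reference peak above 0.1 % of its
maximum, shifted toward the distorted peak's maximum and widened by N points
on each side.  λ defaults to 0 (plain least squares via SVD); if the system
is ill-conditioned (condition number > 1e12) one automatic retry uses
λ = 1e-8 × the largest diagonal of AᵀA.  No sign or unit-area constraint is
imposed: measured responses are asymmetric and irregular, which is exactly
why they are measured rather than modelled.  The relative RMS fit residual
is stored with each response.

Resolution constraints tie Δf to the expected peak widths: the narrowest
undistorted singlet must stay above one point (FWHM_min > Δf) and the
broadest distorted peak below 100 points (W + FWHM_max < 100 Δf), with
W ≤ N Δf fixing the kernel length.  `response_length` returns the smallest
odd N satisfying the latter; an explicit odd override is accepted for
compatibility with existing libraries (e.g. the reference 61/81-point
choices at W ≈ 21/23 Hz, which round the quoted W).

## The calibration simulator

Real calibration needs a spectrometer; the simulator stands in for it so the
entire pipeline is testable.  The sample column is a normalized coordinate
z ∈ [−1, 1]; the Z1 and Z2 coils contribute field offsets shaped like the
first two Legendre polynomials,

    δ(z) = κ1 z1 z + κ2 z2 (3z² − 1)/2   [Hz],

the simplest physically motivated stand-in for the axial shim harmonics.
The inhomogeneity response is the density of δ(z) under uniform z —
evaluated by 200,000-point midpoint quadrature histogrammed onto a Δf/8
grid — convolved with the natural Lorentzian line and integrated to the
Δf grid (fine cells centered on integer multiples of Δf/8; each coarse cell
integrates 9 fine cells with half-weight ends, which keeps the
discretization exactly mirror-symmetric).  Responses are renormalized to
unit sum, and a setting whose response leaves more than 0.1 % of its mass
outside the N-point window is rejected — mirroring the user's duty to pick
W large enough.

Defaults: κ1 = 0.045 and κ2 = 0.060 Hz per shim unit put the widest
response of a ±100-unit scan near 18 Hz, inside a 21 Hz window at
Δf ≈ 0.34 Hz; the natural half-width w_nat = 0.008 Hz corresponds to a
long-T2 chloroform-like singlet (T2 ≈ 20 s), far below Δf, so calibration
peaks are dominated by the inhomogeneity.  The shim-unit→Hz couplings are
simulator knobs, not measured values.

Two symmetries follow from the field model and are enforced exactly by the
discretization: flipping z1 alone relabels the column (z → −z) and leaves
the response unchanged, while flipping *both* currents negates δ(z)
pointwise and mirrors the response in frequency.

The simulated calibration spectrum is the *ideal* narrow singlet convolved
with the setting's ground-truth response (the response already carries the
natural linewidth).  The ideal singlet is exposed separately
(`simulate_ideal_singlet`) as the deconvolution reference, which makes the
forward–inverse oracle exact: extracting a response from a simulated
spectrum recovers the stored ground truth to the solver's accuracy.

## Synthetic training spectra

Each line is the Lorentzian–Gaussian mixture

    f(ω) = (1−γ) H w² / (w² + (ω−ω₀)²) + γ H exp(−(ω−ω₀)²/2σ²)

with both components tied to the same FWHM via w = σ√(2 ln 2).  A
multiplet of multiplicity m is m equidistant, equally wide lines spaced by
the coupling j1 with unit-sum binomial weights (weak coupling); with
probability 1/2 a second coupling j2 splits each line into a half-weight
doublet.  Parameter ranges (uniform draws; scopes: per spectrum / per
multiplet): number of multiplets 2–5, centers ±279.02 Hz (clipped to 90 %
of the grid half-span on narrow grids), multiplicities 1–7 weighted
(0.30, 0.30, 0.20, 0.10, 0.05, 0.03, 0.02) toward low values as found when
harvesting multiplets from drug-like small molecules, couplings 0–15 Hz,
multiplet width 1–2 Hz × spectrum width factor 0.2–1 (so component
half-widths span 0.2–2 Hz), relative intensity 1–3, multiplet height factor
0.5–4, spectrum height factor 0.5–2, Gaussian fraction 0–1, noise standard
deviation 0–0.02.  Training spectra are not per-spectrum normalized; the
inference-time peak height of 16 lies inside the training height range by
construction.  Multiplets are *sampled parametrically* rather than harvested
from a molecular database: the ranges above already delimit what a database
would produce, and a parametric sampler keeps the generator dependency-free
and exactly reproducible.

## Network and training

Encoder: four stride-1 1D convolutions (kernel 7, 64 channels) with ReLU
between them — receptive field 4·6+1 = 25 points.  Attention pooling:
scalar product of each latent column with one learned 64-component query
(no bias, no temperature — exactly 64 parameters), softmax over positions,
weighted average.  Decoder: mirror of the encoder built from stride-1
transposed convolutions (which coincide with flipped-kernel convolutions at
stride 1), fed with each latent column concatenated with the broadcast
global vector (128 input channels); encoder+decoder receptive field
2·4·6+1 = 49 points.  Auxiliary decoder: 64 → 64 → N fully connected with
one ReLU, used only by the training loss.  All (transposed) convolutions
zero-pad by (kernel−1)/2 so every length is preserved; there is no output
activation (baselines may be slightly negative).  Initialization is
fan-in-scaled uniform, seeded.  The correction path holds 202,113
parameters (encoder 86,720 + decoder 115,329 + attention 64); the reference
total of 202,176 cannot be decomposed exactly under any natural reading
that includes a two-layer auxiliary decoder, so the count is checked as a
soft ±0.1 % bound on the correction path rather than asserted exactly.

The network is implemented directly on NumPy with hand-written backward
passes; convolutions run as one BLAS matrix product per kernel tap, which
keeps CPU training practical and the package free of deep-learning
framework dependencies.

The loss over a batch of K spectra is

    L = (1/K) (|S_trg − S_out|² + |R_trg − R_out|² + |S_inp − S_out∗R_out|²)

with ∗ the centered same-length convolution.  Each |·|² is the per-element
mean of its vector, making the loss — and therefore the working learning
rates — independent of the training spectrum length; the notation leaves
this open and the per-element choice is ours.  The optimizer is Adam with
moments (0.9, 0.999) and ε = 1e-8, no dropout or weight decay.  The
reference schedule raises the batch size and lowers the learning rate in
three phases — (1.6 M, 64, 0.001), (25.6 M, 512, 0.001),
(12.8 M, 512, 0.0005), 40 M spectra in total — and trains on 2048-point
spectra; the trained network processes any length ≥ its receptive field.

## Desk-scale (smoke) configuration

Full training is a GPU-day-scale computation.  For CPU-only verification the
package ships a desk-scale setup whose problem sizes were chosen so that a
complete 3-seed run finishes in minutes while still demonstrating genuine
learning:

* spectra of 512 points at Δf = 0.3406 Hz;
* an 8×8 library of simulated responses spanning ±100 shim units
  (widths up to ≈ 18 Hz);
* a 24-channel model (same kernel, depth, attention and auxiliary decoder
  as the reference architecture);
* a two-phase schedule scaled from the reference one: 800 batches of 32 at
  learning rate 3e-3 followed by a 300-batch tail at 1e-3 (35,200 spectra
  per seed).  The smaller model tolerates — and needs — a higher initial
  rate than the reference 1e-3 to reach useful reconstruction quality
  within the shortened run.

Under this configuration the corrected-vs-clean MSE falls below half of the
distorted-vs-clean MSE on held-out synthetic examples for the majority of
seeds — the same qualitative claim the full-scale training supports, at a
fraction of the cost.  The `smoke_schedule()` preset (50,048 spectra, batch
64, lr 1e-3) is the single-phase CPU preset for the reference 64-channel
model.

## What the simulator does and does not emulate

The synthetic pipeline reproduces: narrow-singlet calibration, smooth
variation of responses with shim currents, asymmetric response shapes (from
the interplay of the linear and quadratic profiles), convolutional
distortion, and the documented parameter ranges of the training spectra.  It
does not emulate: X/Y shim profiles, susceptibility or sample-volume
effects, phase and baseline errors, strong scalar coupling, temperature
drifts, or solvent peaks with extreme dynamic range.  Tests passing on
synthetic data therefore validate the *machinery* (deconvolution, training,
correction plumbing) and the architecture's stated properties; they do not
by themselves establish performance on real spectrometer data.

## Numerical choices and degenerate inputs

* Spectrum files: '#'-prefixed `key: value` headers, two whitespace-separated
  columns (frequency Hz, intensity); ascending or descending axes accepted;
  axis uniformity enforced to a relative step tolerance of 1e-6; ppm axes
  converted only when a `spectrometer_frequency_MHz` header is present.
* Resampling: cubic spline with flat extrapolation at the clipped edges;
  exact on constant and linear signals; resampling to the native step is the
  identity.
* Convolution convention: odd kernels only, center index (N−1)/2 ≡ zero
  shift, zero-padded edges — one convention used everywhere (extraction,
  generation, loss, network) to avoid one-bin drifts.
* Response endpoints: |r[0]|, |r[N−1]| < 5 % of max|r| is a quality check
  (logged, not enforced) that N was chosen large enough.
* Extraction failures in a calibration directory are isolated per file; the
  run fails only if more than 1 % of files fail.
* Spectra with no positive point cannot be normalized and are rejected; a
  peak-height dynamic range beyond 1:220 triggers a warning (training
  coverage), not an automatic solvent suppression.
* Correction refuses inputs whose resampled length falls below 64 points
  rather than padding silently.

## Known limitations

* The NumPy training loop is single-process and CPU-bound; full-scale
  (40 M-spectra) training is impractical without a GPU framework, and the
  package makes no attempt at it.
* The shim-field stand-in is two axial harmonics on a uniform column; real
  shim sets span many more harmonics and non-uniform sample geometries.
* Correction quality on real spectra depends on preprocessing (phasing,
  baseline) that is deliberately out of scope here.
* The attention summary is reported over user-supplied frequency intervals;
  no automatic multiplet segmentation is attempted.
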
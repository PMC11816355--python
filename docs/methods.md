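# Methods

## Problem and model

Echo-planar spectroscopic MRI (EPSI) acquires a proton spectrum in every
voxel of a 3D brain volume.  In glioma imaging the quantities of interest
are the choline (Cho, 3.20 ppm), creatine (Cr, 3.03 ppm) and
N-acetyl aspartate (NAA, 2.01 ppm) resonances: infiltrating tumor raises
Cho and depletes NAA, so voxels whose Cho/NAA ratio is at least twice the
level in contralateral normal-appearing white matter (NAWM) serve as a
surrogate for the high-dose radiotherapy target.

Every fitter in this package shares one forward model.  A voxel's
time-domain signal (FID) is

    s(t) = e^{i phi} e^{i 2 pi Df t} g(t; L) * sum_m a_m b_m(t),
    g(t; L) = exp(-(pi L t)^2 / (4 ln 2)),

with non-negative amplitudes `a_m` (one per metabolite), a zero-order phase
`phi` in [-180, 180] degrees, a frequency shift `Df` (Hz) and a Gaussian
broadening envelope whose parameter `L` is the full width at half maximum
(in Hz) *added* to each line.  The observed spectrum is the FFT of `s` plus
a baseline.  The baseline lives directly in the frequency domain: its real
and imaginary channels are each the inverse discrete wavelet transform of
approximation coefficients with all detail bands zeroed (Daubechies-4,
periodized, level 4: 32 coefficients per channel for 512 spectral points).
Because the periodized DWT is orthonormal, coefficient extraction is the
exact adjoint of reconstruction and the approximation subspace is closed
under the round trip.  The decomposition level controls how much of a
metabolite line the baseline subspace could absorb: at level 3 a Gaussian-
broadened line shares up to ~75% of its windowed energy with the baseline
subspace, which makes the metabolite/baseline split badly conditioned; at
level 4 (features at least ~16 bins / 0.3 ppm wide, comparable to the
stiff-spline baselines of established LCM fitters) the overlap roughly
halves while smooth in-vivo-like baselines remain representable.

The metabolite basis is synthesized analytically from a line table
(chemical shift, relative amplitude, Lorentzian width per resonance):
Cho as a 3.20 ppm singlet; Cr as 3.03 ppm plus the 3.91 ppm CH2 at 0.7
relative amplitude; NAA as the 2.01 ppm singlet plus a weak 2.49/2.57/2.67
ppm aspartate multiplet.  Each basis spectrum is normalized to unit peak
magnitude, so a fitted amplitude is approximately the contributed peak
height and ratio maps are scale-free.  An analytic line-table basis (rather
than a quantum-mechanical simulation) preserves every algorithmic property
of the pipeline while keeping the package self-contained.

### Spectral axis

The default grid uses 512 complex points over a 1250 Hz bandwidth at a
123.25 MHz transmitter (proton at 3 T), referenced to water at 4.70 ppm —
typical values for a long-TE 3 T EPSI protocol; all four numbers are
configurable.  Spectra are stored in ascending-frequency order; one bin is
2.44 Hz = 0.0198 ppm.  The analysis window is ppm in [1.7, 4.2] (NAA
through Cho plus margin, excluding residual water and lipid); both fitters
evaluate their objective only inside it.

## The neural fitter

Two 1D residual encoders (ResNet-18 layout: a stride-2 stem convolution of
kernel 7, max-pooling, then four stages of two basic blocks with 16, 32,
64 and 128 filters, a position-preserving flatten of the final feature
map, and a dense layer to a 128-dimensional latent) read the same
2-channel (real/imaginary) input: the
spectrum cropped to the analysis window plus a 0.35 ppm margin and scaled
by its maximum magnitude (the scale is stored and folded back into the
estimated amplitudes and baseline coefficients).  One encoder feeds a dense
head producing the metabolite-model parameters, the other a dense head
producing the 2 x 64 baseline coefficients.  Amplitudes and linewidth pass
through softplus maps (non-negative by construction; the linewidth softplus
is scaled by 4 Hz), phase through 180 * tanh, and frequency shift through
30 Hz * tanh, so every estimate respects its physical range for any
weights.

Training is self-supervised: no parameter labels are used.  Each batch is
augmented with a random zero-order phase drawn uniformly from [-180, 180]
degrees and a frequency shift from [-20, 20] Hz (redrawn every epoch), and
the loss is the mean squared real+imaginary error between the decoder's
reconstruction and the augmented spectrum over the analysis window.
Because the decoder is the analytic forward model, the loss gradients with
respect to the decoder parameters are closed-form (the FFT adjoint maps
the spectral residual back to the time domain; the wavelet synthesis
operator's adjoint is its transpose), and the encoders are trained by
ordinary backpropagation.  The network engine is a compact numpy
implementation (im2col convolutions on BLAS, batch normalization, Adam)
with explicit backward passes, verified against finite differences; all
computation is float32, single-threaded and deterministic for a given
seed.

Because broadened metabolite lines and the wavelet approximation subspace
overlap, the metabolite/baseline decomposition needs a convention; the
training loss therefore carries a small L2 penalty on the baseline
coefficients (weight 0.01 on their mean square), which prefers the
smallest baseline able to explain the data — the same convention as the
least-squares fitter's minimum-norm baseline recovery.  The readout
flattens the final feature map instead of global-average pooling because
peak-height estimation is position-specific; averaging over the spectral
axis was measurably worse at equal budget.

At inference the fitter averages its estimates over eight views of each
spectrum: the spectrum itself plus seven copies transformed by fixed
phase/frequency offsets drawn from the augmentation ranges.  Amplitudes
and linewidth are transform-invariant and averaged directly; phase and
shift are averaged after subtracting the applied offset (phase via the
circular mean); the baseline coefficients and reconstruction loss are
those of the untransformed view.  Because training enforces equivariance
under exactly these transforms, the views are exchangeable estimates and
averaging reduces estimation variance measurably; the view offsets are
fixed constants shared by every spectrum, so inference remains
deterministic and independent of batch composition.  A single-pass mode
(``n_views=1``) is available where throughput matters.

The reference training configuration is a learning rate of 1e-4, batch
size 512 and 200 epochs, intended for corpora of hundreds of thousands of
spectra.  The desk-scale configuration used throughout the test suite
trains on 20,000 synthetic spectra for 20 epochs; with only ~1,500
optimizer steps the peak learning rate is raised to 4e-3 (batch 256) with
a 5% linear warmup and cosine decay to zero.  Both configurations share
the augmentation ranges and window.

## The least-squares reference fitter

The classical counterpart fits the same model per voxel by nonlinear least
squares, in the spirit of the iterative Levenberg–Marquardt fitters that
are standard in spectroscopic-MRI processing.  It uses variable
projection: only (phi, Df, L) are nonlinear; for fixed values of those the
amplitudes and baseline coefficients are linear and solved in closed form.
The baseline subspace restricted to the window is orthogonalized once
(SVD, singular values above 1e-10 of the largest retained), so each
residual evaluation projects the three metabolite columns against it and
solves a 3-column system.  Initialization is a coarse grid search over
frequency shift (±24 Hz in 17 steps, at 2 and 8 Hz linewidth) with complex
amplitudes absorbing the phase; the phase starts from the argument of the
dominant complex amplitude.  The trust-region refinement allows the phase
180 degrees of slack beyond its box so optima near the ±180 branch cut are
not pinned; afterwards the amplitude-sign ambiguity (e^{i phi} a =
e^{i(phi-180)} (-a)) is canonicalized to non-negative total amplitude, the
phase re-wrapped, and residual negative amplitudes (noise-level) clipped
to zero.  Baseline coefficients are recovered as the minimum-norm solution
reproducing the windowed residual; coefficients with no support in the
window are therefore near zero.

On noiseless forward-model spectra this fitter recovers amplitudes to
better than 1%, phase to 1 degree and shift to 0.2 Hz (verified over 100
random draws), which is why it serves as the oracle when validating the
neural fitter.

## Synthetic phantom

Clinical EPSI data are not redistributable, so all tests run on a
generator that emulates the statistical structure the method assumes.  The
default phantom uses the acquisition geometry of a whole-brain protocol —
a 64 x 64 x 32 matrix over a 280 x 280 x 180 mm field of view, i.e. 4.375
x 4.375 x 5.625 mm voxels of ~108 uL.  Anatomy is expressed in fractions
of the matrix so scaled-down phantoms keep the same layout: a brain
ellipsoid (~14,000 voxels at default size), a CSF shell at the outer 7% of
the brain radius, cerebellum and brainstem blocks in the inferior slices,
a tumor ellipsoid (~300 voxels) in one hemisphere and a contralateral NAWM
reference box (~500 voxels).

Metabolite amplitudes are drawn per voxel from truncated-at-zero normals.
Tissue levels (basis-normalized peak-height units) are NAA 1.0 ± 0.1,
Cr 0.8 ± 0.08, Cho 0.35 ± 0.05 — plausibility choices for long-TE brain
spectra, not measured values.  The tumor multiplies the Cho mean by 3 and
the NAA mean by 0.4 (true tumor Cho/NAA ~7.5x tissue); the cerebellum uses
1.3x Cho / 0.9x NAA; CSF amplitudes are near zero (sd 0.02).  Phase and
shift are uniform over the augmentation ranges (±180 degrees, ±20 Hz),
Gaussian linewidth uniform on [2, 8] Hz.  Baseline coefficients follow a
scaled random walk over the coefficient index (scale 0.3), giving smooth
baselines of roughly 10–30% of the NAA peak.  Noise is i.i.d. complex
Gaussian in the frequency domain with sd 0.05 per channel per bin (NAA
peak SNR ~20).  A quality mask fails a random 8% of voxels in the
peripheral 20% of the brain radius, mimicking the rim artifacts typical of
in-vivo EPSI.  Every voxel's generating parameters are recorded as ground
truth, and generation is reproducible from the configuration seed.

What the phantom does *not* emulate: residual water/lipid signals, B0
field maps and spatially correlated frequency drift, partial-volume
mixing, and coil-sensitivity or reconstruction artifacts.  Passing tests
therefore demonstrate correctness of the algorithms under the model's own
assumptions, not clinical performance.

## Ratio maps and target delineation

The Cho/NAA map floors the denominator at the 5% quantile (linear
interpolation between order statistics) of its distribution within the
supplied mask, clamping — not excluding — sub-floor voxels, so the ratio
cannot diverge as NAA approaches zero.  The target pipeline then takes the
arithmetic mean ratio over the NAWM mask, thresholds at 2x that mean
(inclusive: a voxel exactly at threshold is abnormal), removes
quality-failed, CSF, cerebellum and brainstem voxels, and keeps the
largest 26-connected component (connectivity configurable to 6/18/26;
size ties are broken by smallest flat voxel index, making the selection
deterministic).  Volumes are voxel count x voxel volume.  Exclusions are
applied before component selection so an artifact outside the brain
parenchyma can never become the primary component.

## Agreement metrics

SSIM is computed in 3D with a 7-voxel uniform-weight cubic window whose
local statistics are restricted to mask voxels (renormalized by the
in-mask voxel count, with the usual sample-covariance correction); the
dynamic range is the joint min–max within the mask, and the reported value
is the mean local SSIM over mask voxels.  On interior voxels with a full
window this reduces exactly to the standard implementation, which is how
it is cross-checked.  Dice is 2|A∩B|/(|A|+|B|) with the both-empty case
defined as 1.  Bland–Altman limits are bias ± 1.96 sample standard
deviations of voxelwise differences, subsampled to at most 20,000 voxels
within the brain mask.  Pearson correlation is the plain product-moment
coefficient and raises on constant input rather than returning NaN.

## Problem sizes used by the test suite

The suite trains once per session on 20,000 spectra for 20 epochs
(~8 minutes single-threaded) and fits the ~14,000 brain voxels of the
default phantom with both fitters (~4 minutes for the least-squares
fitter at ~15 ms per voxel; ~1 minute for the neural fitter with 8-view
averaging).  The held-out evaluation uses 3,000 noiseless spectra.
Unit tests use a 16 x 16 x 8 phantom with identical anatomy fractions.

## Design choices that were genuinely open

- **Baseline channels.**  The baseline is fit in both the real and
  imaginary channel with independent coefficients; equivalently one
  complex coefficient vector.  Fitting only the real channel would couple
  baseline error into the phase estimate.
- **Input representation.**  Both encoders see the same normalized
  real/imaginary crop.  Feeding the baseline encoder a residual after a
  provisional metabolite fit was considered and rejected as it would make
  the two encoders order-dependent.
- **Amplitude floor vs exclusion.**  Sub-floor denominators are clamped,
  not dropped, so the ratio map stays defined on the full mask and
  downstream masks remain well-posed.
- **Quantile convention.**  Linear interpolation between order statistics
  (the numpy default); with 20 in-mask voxels and a 5% floor this gives a
  floor of 1.95 between the first and second order statistic.
- **Split replication.**  The subject-level splitter optionally repeats
  the seeded draw until the test subjects' scan total matches a requested
  count, which reproduces a published split whose aggregate counts are
  known; all of a subject's scans always travel together.

## Known limitations

- The numpy network engine is single-threaded and CPU-bound; it is meant
  for desk-scale corpora, not the hundreds of thousands of spectra of a
  full clinical training set (the reference configuration is retained for
  completeness).
- The least-squares fitter's coarse shift grid covers ±24 Hz; shifts far
  outside the augmentation range would need a wider grid.
- Basis line tables are fixed analytic approximations; J-coupling
  evolution with echo time is not modeled.
- The phantom's quality mask is parameterized (fraction, shell depth), not
  calibrated to any scanner's SNR/linewidth cutoffs.
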
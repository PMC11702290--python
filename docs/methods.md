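# Methods

## Signal model

The tracer is modeled as an ensemble of superparamagnetic moments in
thermodynamic equilibrium: magnetization `M = s · L(β B)` with the Langevin
function `L(ξ) = coth ξ − 1/ξ`, a gain `s` (signal units per g_Fe,
arbitrary and calibratable) and a steepness `β` (1/T). Magnetic relaxation
is deliberately omitted: the FFL traverses the field of view at 2.7 Hz,
orders of magnitude below the rate at which microsecond-scale relaxation
times would affect spatial response, so the relaxation-free model is
adequate for resolution and sensitivity studies.

Rather than deriving `β` from core-diameter physics, it is calibrated so
that the **third-harmonic offset-field kernel** — |3rd harmonic| versus
static offset at the operating drive amplitude — has a chosen full width at
half maximum, because that is how the particle is characterized in practice
(a magnetic particle spectrometer sweep). The default is 6 mT FWHM at
5.8 mT_peak drive, giving `β ≈ 331 /T`. The FWHM is measured on the
kernel's central lobe: for steep magnetization curves the |3rd harmonic|
profile develops sidelobes inside the drive window, and the half-max search
walks outward from the peak so sidelobes cannot widen the estimate. The
map β → FWHM is strictly decreasing, so a bracketed root find on log β
converges unconditionally; the bracket spans 1e2–1e6 /T.

One deliberate assumption: the kernel measured on the real instrument is the
through-plane one, and the in-plane kernel is unmeasured; the simulator
applies the 6 mT kernel isotropically in-plane.

Harmonic amplitudes are computed by sampling one drive period of `M(t)` at
the digitizer density (38 samples per period: 1 MS/s at the 1e6/38 Hz
drive), taking the FFT, and applying Faraday's law *exactly in the Fourier
domain* — harmonic n is multiplied by `i·n·2π` (the drive frequency itself
is a fixed global factor absorbed in the gain). The brute-force read-out
oracle synthesizes all 1330 samples of a 35-period read-out and reads FFT
bin 35·n with the same factor; because the two paths share only the
Langevin sampling and the FFT, their agreement (to 1e-6 relative, tested)
validates the offset-field factorization, not a differencing scheme.

Note the drive period: the drive hardware uses a period of exactly 38
digitizer samples (38 µs, f_d = 1e6/38 ≈ 26 315.79 Hz) so that every period
is digitized identically.

## Geometry and units

Fields are mT, gradients T/m, distances mm (so G[T/m]·d[mm] is directly
mT), angles degrees counter-clockwise from +x. The FFL passes through the
isocenter along the rotated y′ axis; the gradient acts along
x′ = (cos θ, sin θ), and the offset field at a point p is
`G·(p·x̂′) + H_s`. The FFL zero crossing therefore sits at perpendicular
offset `s = −H_s/G`.

Image grids put the isocenter on the pixel `(n//2, n//2)` — i.e. pixel
centers at integer offsets from a center pixel — so that the tomographic
rotation axis coincides exactly with the back-projector's center-pixel
convention; sinogram projections are resampled onto an odd, pixel-centered
detector grid before back-projection for the same reason.

## Acquisition

A 5 s image = 180° gantry sweep at 6 RPM = 27 projections of 132 read-outs
(RO). Each RO spans 35 drive periods (1.33 ms, 1330 samples); the ~5%
slack between 132 ROs and the 185 ms projection slot is taken as dead time
at the projection boundary. The shift field is a rounded triangular wave:
corners are replaced over a configurable fraction of the period (default
5%) by a cosine blend that matches the triangle's value and slope (C¹) and
slightly clips the peak, reproducing the corner dwell of a real rounded
drive. Each RO records its mean gantry angle and mean shift field.

The default (kernel) signal path tabulates the complex harmonic response on
a 0.05 mT offset grid and evaluates each RO as a mass-weighted gather over
the phantom's nonzero pixels; the time-domain path is retained as the
oracle (they agree within 1% on small phantoms, tested). Receiver noise is
additive complex white Gaussian per harmonic per RO (`noise_sigma` is the
std of the complex value; each quadrature gets σ/√2). Spurious
shift-system spikes are modeled as a ×20 multiplicative outlier on a
read-out's 3rd harmonic with a per-RO probability; spiked ROs carry a truth
flag so despiking efficacy can be scored. The spike amplitude model exists
to exercise the despiker, not to model the (unknown) physical arc process.

Binning: per projection, ROs fall into 132 uniform shift bins spanning
[−peak, +peak]; multiple ROs per bin are complex-averaged (phase is
preserved), empty bins (the rounded-triangle corner region) are linearly
interpolated along the shift axis and flagged. The projection angle is the
mean measured RO angle. Each bin also records the mean measured angle of
its own ROs: the gantry rotates ~6.7° during one projection, and the
forward-model reconstruction uses these per-bin angles (the inverse Radon
reconstruction, which needs a single angle per projection, uses the mean).

## Preprocessing

Baseline: each projection column has the complex line through (mean of its
first two points, mean of its last two points) subtracted — the assumption
being no tracer signal at the FOV perimeter. The operation is idempotent
and exactly annihilates constant and linear columns.

Despiking: a point is an outlier when its deviation from the local median
within a **3-element moving window along the shift axis** exceeds
3 scaled MADs (scaled MAD = 1.4826·MAD), the standard moving-median rule.
Choices the rule's description leaves open, and how they are resolved here:
the test statistic is the complex magnitude (phase-robust; the mask is
invariant under global complex rescaling); windows truncate to two elements
at column ends; MAD = 0 windows never flag (zero deviation is never greater
than zero, so constant regions are untouched); outliers are replaced by the
elementwise real/imaginary median of the non-outlier window points (the
two-neighbor mean in the interior). The window orientation (along shift)
matches the sinogram-domain description of the artifact.

A structural limitation, measured and accepted: two *adjacent* spiked
read-outs defeat any 3-element median (the window median is then itself a
spike), so with independent 2% spiking the expected recall is ~93–96%
depending on the collision draw; the seeded test measures 97.5% recall at
0.8% false-mask rate. Real arcs that cluster in time would face the same
ceiling.

## Reconstruction

Both reconstructions consume the cleaned 3rd-harmonic sinogram after a
single global phase rotation that zeros the signal-energy-weighted mean
phase (weight |v| on each unit phasor, i.e. arg Σ|v|·v); the real part is
then used. Taking magnitudes instead would rectify noise and was rejected.

**Inverse Radon**: the shift axis maps to FFL offset `s = −H_s/G`; filtered
back-projection over the measured angles uses a Ram-Lak filter with
linear-interpolation back-projection (the filter is a flag), and the result
is cropped to the FOV disc. Grid: 132 × 132 pixels over the configured FOV.

**Forward model**: each measurement row is the ideal FFL line at its
(per-bin) measured angle and shift, rasterized on the image grid and
convolved perpendicular-to-line with a Gaussian of standard deviation
7 mm — an estimate of the instrument's native point spread — truncated at
4σ and stored sparsely (~40 M nonzeros at the 132² default, ~0.5 GB).
Entries are nonnegative and interior rows at a common angle share the same
line-integral normalization (on a square grid the chord length, and hence
the row sum, legitimately varies with angle).

The normal equations AᵀAx = Aᵀb are solved by conjugate gradients with a
Jacobi (diagonal of AᵀA) preconditioner, zero initial guess, and **exactly
15 iterations, no early stopping** — iteration truncation is the only
regularization, trading sharpness against ringing. The solver matches a
dense least-squares oracle on a small grid after convergence-many
iterations (tested, residual gap ≤ 1e-3). Fixed-iteration CG is exactly
homogeneous but only approximately additive (its Krylov space depends on
the data); superposition holds to a few percent at 15 iterations and is
tested as such. Pixels outside every row's support get a unit
preconditioner entry and remain exactly zero.

Post-reconstruction smoothing is an isotropic Gaussian of stated FWHM
(σ = FWHM/2.3548): 1.5 mm for resolution images, 6 mm for dilution images.

## Metrology

Contrast `C = 1 − S_min / (0.5(S_max,L + S_max,R))` uses the two most
topographically *prominent* peaks (not the two tallest — deconvolution
ringing produces tall shoulder artifacts), and the minimum between them;
fewer than two local maxima is reported as a distinct "unresolved" error
rather than a low C. When scoring reconstructed images the central profile
is floored at zero first: iron concentration is nonnegative, and the
negative ringing excursions of the phase-aligned real reconstruction would
otherwise push C above 1 and make the statistic meaningless precisely where
the tubes are well separated. C > 0.5 is the resolution criterion.

The detection limit fits peak signal versus iron mass by ordinary least
squares, keeping the intercept, and solves the fitted line against k·σ of
an empty-bore reconstruction (k = 1, 5). With a baseline b the k-sigma
limits are (kσ − b)/slope, so a positive baseline makes the 5σ/1σ ratio
slightly exceed 5. The printed hardware detection limits depend on the real
receiver's noise floor and are not simulation targets; the simulator
reproduces the procedure and its scaling laws (LOD ∝ noise, R² ≈ 1 for a
noiseless series).

FOV calibration scales the known 136 mm ring diameter of the 'G' phantom by
grid size over measured extent in pixels, the extent being the distance
between the ring's two sub-pixel-refined peaks on the central column (the
ring is uninterrupted there; the glyph's gap and crossbar are free
parameters of the generator, chosen as a 12°–60° gap with a 25 mm bar).

## What the synthetic data does and does not capture

The generator reproduces the study conditions: tube pairs of 2.5 mm
diameter and 0.5 mg_Fe/mL at 5–9 mm separations in the zoomed 74 mm FOV;
20 µL point sources in a geometric 8-step dilution from 6 mg/mL to
15.6 µg/mL (the stated endpoints are not a factor-2 series; a geometric
series between them is used); the 0.0625 mg/mL 'G' ring in a 190 mm FOV.
Phantoms are 2D slabs with an explicit depth (tube diameter for
capillaries, 3 mm fill height for point sources) so masses are physical;
rasterization is area-weighted (exact for rectangles, 16× supersampled for
curved shapes), conserving analytic mass to ≲0.5%.

Not captured: receiver-chain spectra and filters, feedthrough leakage,
gradient-field inhomogeneity (the simulated gradient is ideal), relaxation,
3D effects, and the empty-bore noise structure of the real instrument —
which is why passing the simulated detection-limit and FOV tests
demonstrates correctness of the *procedures*, not the hardware's measured
sensitivity or its extrapolated 181 mm FOV. One consequence of the ideal
kernel deserves note: the simulated point spread (6 mT/1.13 T/m ≈ 5.3 mm
FWHM ≈ 2.25 mm std) is much narrower than the 7 mm-std kernel the forward
model assumes, so the 15-iteration inversion over-sharpens and rings more
than on the real instrument; at one separation (8 mm) the ringing fills the
inter-tube valley enough that the floored contrast dips below the
back-projection's saturated C = 1, inverting the usual ordering of the two
algorithms at that single point while leaving the resolved separations
(5 mm iterative, 6 mm inverse Radon) intact.

## Problem sizes and runtime

Defaults are chosen for a single CPU: one image is 27 × 132 = 3564
read-outs; phantom grids are 0.5 mm pitch (resolution, dilution) or 1 mm
(FOV); the system matrix is built once per configuration and cached within
an experiment. The full resolution protocol runs in ~1 minute, the
dilution and FOV protocols in a few seconds each.
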
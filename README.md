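# mpisim

A desk-scale simulator and reconstruction toolkit for a mechanically-rotated
**field-free-line (FFL) magnetic particle imaging (MPI)** scanner of the kind
built for human brain imaging: a permanent-magnet selection gradient
(1.13 T/m in-plane), a 26.3 kHz drive coil (up to 7 mT_peak), a slow 2.7 Hz
shift field that sweeps the FFL across the head, and a gantry that rotates
180° in 5 s to collect 27 projections of 132 read-outs each.

MPI maps the distribution of superparamagnetic iron-oxide nanoparticles
(SPIONs, e.g. Synomag-D). In the relaxation-free regime the tracer
magnetization follows the Langevin function

```
M(H) = M_s · L(βH),    L(ξ) = coth ξ − 1/ξ,
```

so the EMF induced by a sinusoidal drive H_d cos ωt contains harmonics of ω
whose complex amplitudes fall off with the static offset field
G·d + H_s seen by each particle (G the gradient, d the distance to the FFL,
H_s the shift field). Only particles near the field-free line respond:
each read-out is a kernel-blurred line integral of the iron map, and the
binned harmonics form a sinogram amenable to tomography.

The package implements, end to end:

* **`scanner_model`** — scanner configuration, Langevin particle calibrated
  to the measured 6 mT third-harmonic kernel FWHM, harmonic response,
  FFL offset-field geometry;
* **`phantoms`** — capillary line pairs, point-source dilution series,
  and the 136 mm 'G' ring used for FOV calibration;
* **`acquisition`** — the 5 s acquisition (35-drive-period read-outs,
  rounded-triangle shift, harmonic extraction 2–9, sinogram binning), with
  a fast kernel-factorized signal path validated against a brute-force
  time-domain oracle;
* **`preprocess`** — per-projection complex linear baseline subtraction and
  moving-median scaled-MAD despiking;
* **`recon`** — the two reconstructions: filtered back-projection of the
  phase-aligned 3rd-harmonic sinogram, and a forward-model inversion
  (Gaussian-widened FFL rows, 7 mm std, solved by 15 fixed
  Jacobi-preconditioned conjugate-gradient iterations);
* **`metrics`** — two-peak contrast C = 1 − S_min / (0.5(S_max,L + S_max,R)),
  resolution-from-series (C > 0.5 resolved), dilution-regression detection
  limit, FOV calibration, image SNR, gradiometer feedthrough attenuation;
* **`engcalc`** — closed-form engineering/dosimetry numbers (shift-coil heat
  load, cooling, gearing, per-voxel iron dose);
* **`experiments` / CLI** — drivers chaining
  simulate → preprocess → reconstruct → score for the three validation
  protocols (resolution, dilution, FOV).

## Worked example

Simulate the spatial-resolution protocol — noiseless images of two 2.5 mm
capillary tubes (0.5 mg_Fe/mL) at 5–9 mm inner-surface separation in a
zoomed 74 mm FOV — and score both reconstructions:

```python
>>> import mpisim
>>> res = mpisim.run_resolution_experiment()
>>> print(res.table.to_string(index=False))
 separation_mm  C_inverse_radon  C_iterative
             5         0.338843     1.000000
             6         0.779400     1.000000
             7         1.000000     1.000000
             8         1.000000     0.692349
             9         1.000000     1.000000
>>> res.resolved_mm
{'inverse_radon': 6.0, 'iterative': 5.0}
```

The contrast C compares the valley between the two reconstructed tubes with
the peak heights; C > 0.5 counts as resolved. The forward-model iterative
reconstruction resolves the 5 mm pair; plain inverse Radon needs 6 mm.

The dosimetry calculator reproduces the expected gray-matter signal for a
5 mg_Fe/kg intravascular dose:

```
$ mpisim engcalc voxel-dose
blood concentration: 76.92 ug/mL
tissue concentration: 3.846 ug/mL
voxel volume: 216 uL
iron mass per voxel: 830.8 ng
```

The same pipeline is scriptable from the shell:

```
$ mpisim simulate --phantom point --fov 74 --seed 5 --out run.h5
$ mpisim preprocess run.h5 --out clean.h5
$ mpisim recon clean.h5 --algo radon --out img.tif
$ mpisim experiment dilution --noise-sigma 2e-7
```

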
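"""Image reconstruction: inverse Radon (FBP) and forward-model PCG.

Both reconstructions consume the preprocessed 3rd-harmonic sinogram.  The
complex sinogram is first rotated by a single global phase so that its
signal-energy-weighted mean phase is zero, and the real part is kept
(taking the magnitude instead would rectify noise).

Inverse Radon: the shift-field axis maps to the FFL's perpendicular spatial
offset (s = -H_s / G), and filtered back-projection runs over the measured
projection angles (Ram-Lak filter, linear-interpolation back-projection, by
default).

Forward-model iterative: each measurement row is an ideal FFL line through
the image grid convolved perpendicular-to-line with a Gaussian of standard
deviation ``kernel_std`` (7 mm by default, an estimate of the native point
spread), truncated at 4 sigma and stored sparsely.  The normal equations
A^T A x = A^T b are solved by Jacobi-preconditioned conjugate gradients with
a zero initial guess and a fixed iteration count (15, as implicit
regularization) — no early stopping.

Grid convention: square n x n grid over the FOV, isocenter at pixel
(n//2, n//2), x = (col - n//2) * pitch, y = (row - n//2) * pitch (mm),
angles in degrees counter-clockwise from +x.  This puts the rotation axis
on a pixel center, matching the back-projector's convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.ndimage import gaussian_filter
from skimage.transform import iradon

from .acquisition import Sinogram
from .scanner_model import ScannerConfig

logger = logging.getLogger("mpisim")

__all__ = [
    "ReconImage",
    "SystemMatrix",
    "align_phase",
    "inverse_radon_recon",
    "build_forward_model",
    "iterative_recon",
    "smooth_image",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # 1/2.3548


@dataclass
class ReconImage:
    """Reconstructed 2D iron-distribution image (arbitrary units ~ g_Fe/pixel)."""

    values: np.ndarray
    fov: float                      # mm, = pixel_pitch * grid size
    pixel_pitch: float              # mm
    method: str                     # "inverse_radon" or "iterative"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("reconstruction grid must be square")
        if self.method not in ("inverse_radon", "iterative"):
            raise ValueError(f"unknown method {self.method!r}")

    @property
    def grid_n(self) -> int:
        return self.values.shape[0]

    def coords(self):
        """Pixel-center x (cols) and y (rows) in mm."""
        n = self.grid_n
        ax = (np.arange(n) - n // 2) * self.pixel_pitch
        return ax, ax

    def center_profile(self, axis: str = "x"):
        """Line profile through the isocenter; (positions mm, values)."""
        n = self.grid_n
        ax, _ = self.coords()
        if axis == "x":
            return ax, self.values[n // 2, :]
        return ax, self.values[:, n // 2]

    def peak_position(self):
        """(x, y) mm of the image maximum."""
        r, c = np.unravel_index(np.argmax(self.values), self.values.shape)
        ax, ay = self.coords()
        return float(ax[c]), float(ay[r])


def align_phase(plane: np.ndarray):
    """Rotate a complex table so its energy-weighted mean phase is zero.

    Returns ``(real_part, phi)`` where ``phi`` is the removed phase.  The
    weight |v| on each unit phasor makes the estimate
    arg(sum |v| v) = arg(sum |v|^2 e^{i arg v}), i.e. signal-energy
    weighting, so noise-dominated bins barely contribute.
    """
    v = np.asarray(plane)
    z = np.sum(np.abs(v) * v)
    phi = float(np.angle(z)) if z != 0 else 0.0
    return (v * np.exp(-1j * phi)).real, phi


def smooth_image(image: ReconImage, fwhm: float) -> ReconImage:
    """Isotropic Gaussian blur of the stated FWHM (mm); fwhm 0 is identity."""
    if fwhm < 0:
        raise ValueError("fwhm must be nonnegative")
    if fwhm == 0:
        return ReconImage(image.values.copy(), image.fov, image.pixel_pitch,
                          image.method, dict(image.provenance))
    sigma_px = fwhm * FWHM_TO_SIGMA / image.pixel_pitch
    vals = gaussian_filter(image.values, sigma_px, mode="constant")
    prov = dict(image.provenance)
    prov["smoothing_fwhm_mm"] = fwhm
    return ReconImage(vals, image.fov, image.pixel_pitch, image.method, prov)


def inverse_radon_recon(sinogram: Sinogram, harmonic: int = 3,
                        smoothing_fwhm: float = 1.5,
                        filter_name: str = "ramp") -> ReconImage:
    """Filtered back-projection of the phase-aligned harmonic sinogram.

    The shift axis is converted to the FFL's spatial offset
    ``s = -H_s / gradient`` and resampled onto an odd, pixel-centered
    detector grid so the rotation axis lands exactly on the back-projector's
    center pixel; projections are back-projected at the measured angles and
    the result is cropped to the FOV disc, then Gaussian-smoothed.
    """
    plane = sinogram.plane(harmonic)  # KeyError if absent
    real_plane, phi = align_phase(plane)
    cfg_yaml = sinogram.provenance.get("config")
    gradient = _gradient_from_provenance(cfg_yaml)
    n = sinogram.n_shift
    pitch = (sinogram.shift_axis[-1] - sinogram.shift_axis[0]) \
        / (n - 1) / gradient
    fov = n * pitch

    s = -sinogram.shift_axis / gradient
    order = np.argsort(s)
    s_sorted = s[order]
    prof = real_plane[order, :]
    m = n + 1 if n % 2 == 0 else n
    s_grid = (np.arange(m) - m // 2) * pitch
    resampled = np.empty((m, prof.shape[1]))
    for p in range(prof.shape[1]):
        resampled[:, p] = np.interp(s_grid, s_sorted, prof[:, p],
                                    left=0.0, right=0.0)

    # skimage's detector coordinate is x cos(t) - y sin(t); negating the
    # angles yields our s = x cos(t) + y sin(t) convention.
    vals = iradon(resampled, theta=-sinogram.angle_axis, output_size=n,
                  filter_name=filter_name, interpolation="linear",
                  circle=True)
    img = ReconImage(vals, fov=fov, pixel_pitch=pitch, method="inverse_radon",
                     provenance={"harmonic": harmonic, "phase": phi,
                                 "filter": filter_name})
    return smooth_image(img, smoothing_fwhm)


def _gradient_from_provenance(cfg_yaml):
    if cfg_yaml is None:
        raise ValueError("sinogram provenance lacks the scanner config")
    return ScannerConfig.from_yaml(cfg_yaml).gradient_inplane


@dataclass
class SystemMatrix:
    """Sparse linear forward operator: image pixels -> measurements.

    Row i is the Gaussian-widened FFL at (``angles[i]``, ``shift_fields[i]``)
    rasterized over the grid; entries are nonnegative and every fully
    interior row sums to the same line-integral normalization.
    """

    matrix: sp.csr_matrix
    angles: np.ndarray              # degrees, per row
    shift_fields: np.ndarray        # mT, per row
    kernel_std: float               # mm
    grid_n: int
    pixel_pitch: float              # mm

    @property
    def fov(self) -> float:
        return self.grid_n * self.pixel_pitch


def build_forward_model(angles, shift_fields, config: ScannerConfig,
                        kernel_std: float = 7.0, grid_n: int = 132,
                        fov_mm: float = None, truncate: float = 4.0
                        ) -> SystemMatrix:
    """System matrix of Gaussian-convolved FFL lines over the image grid.

    Parameters
    ----------
    angles, shift_fields : per-measurement gantry angle (deg) and shift
        field (mT); equal length, one row each.
    kernel_std : Gaussian standard deviation perpendicular to the line, mm.
    grid_n, fov_mm : reconstruction grid; FOV defaults to the config's.
    truncate : support cutoff in sigmas (rows stored sparsely).
    """
    if kernel_std <= 0:
        raise ValueError("kernel_std must be positive")
    angles = np.asarray(angles, float)
    shift_fields = np.asarray(shift_fields, float)
    if angles.shape != shift_fields.shape:
        raise ValueError("angles and shift_fields must have equal length")
    fov = config.fov_mm if fov_mm is None else fov_mm
    pitch = fov / grid_n
    ax = (np.arange(grid_n) - grid_n // 2) * pitch
    X, Y = np.meshgrid(ax, ax)        # X[row, col] = x, Y[row, col] = y
    xf, yf = X.ravel(), Y.ravel()

    blocks = []
    cut = truncate * kernel_std
    s0 = -shift_fields / config.gradient_inplane
    chunk = max(1, int(4e6 // len(xf)))   # bound the dense scratch block
    for lo in range(0, len(angles), chunk):
        th = np.deg2rad(angles[lo:lo + chunk])[:, None]
        d_pix = xf[None, :] * np.cos(th) + yf[None, :] * np.sin(th)
        dd = d_pix - s0[lo:lo + chunk, None]
        w = np.where(np.abs(dd) <= cut,
                     np.exp(-0.5 * (dd / kernel_std) ** 2), 0.0) * pitch
        blocks.append(sp.csr_matrix(w))
    matrix = sp.vstack(blocks, format="csr").astype(np.float64)
    logger.debug("forward model: %d rows x %d pixels, %d nonzeros",
                 len(angles), grid_n * grid_n, matrix.nnz)
    return SystemMatrix(matrix=matrix, angles=angles,
                        shift_fields=shift_fields, kernel_std=kernel_std,
                        grid_n=grid_n, pixel_pitch=pitch)


def sinogram_measurements(sinogram: Sinogram, harmonic: int = 3):
    """Phase-aligned real measurement vector plus per-row angles and shifts.

    Rows are ordered projection-major: for each projection, all shift bins.
    Uses the per-bin measured angles when the sinogram carries them — the
    gantry keeps rotating while the shift field ramps, so each shift bin of
    a projection was actually measured at a slightly different angle, and
    the forward model can honor that (the inverse Radon path cannot).
    """
    real_plane, phi = align_phase(sinogram.plane(harmonic))
    n_shift, n_proj = real_plane.shape
    b = real_plane.T.ravel()
    if sinogram.bin_angles is not None:
        row_angles = sinogram.bin_angles.T.ravel()
    else:
        row_angles = np.repeat(sinogram.angle_axis, n_shift)
    row_shifts = np.tile(sinogram.shift_axis, n_proj)
    return b, row_angles, row_shifts


def iterative_recon(measurements, system_matrix: SystemMatrix,
                    n_iter: int = 15, smoothing_fwhm: float = 0.0
                    ) -> ReconImage:
    """Fixed-iteration PCG solution of the forward model's normal equations.

    Runs exactly ``n_iter`` conjugate-gradient iterations on
    A^T A x = A^T b with a Jacobi (diagonal) preconditioner and zero initial
    guess; truncating the iteration is the regularization.  ``n_iter = 0``
    returns the zero image.
    """
    A = system_matrix.matrix
    b = np.asarray(measurements, float).ravel()
    if len(b) != A.shape[0]:
        raise ValueError(
            f"got {len(b)} measurements for {A.shape[0]} matrix rows")
    At = A.T.tocsr()
    atb = At @ b
    diag = np.asarray(A.multiply(A).sum(axis=0)).ravel()
    diag[diag <= 0] = 1.0  # pixels unseen by any line: harmless identity

    x = np.zeros(A.shape[1])
    r = atb.copy()
    z = r / diag
    p = z.copy()
    rz = r @ z
    for _ in range(int(n_iter)):
        Ap = At @ (A @ p)
        denom = p @ Ap
        if denom == 0:
            break
        alpha = rz / denom
        x += alpha * p
        r -= alpha * Ap
        z = r / diag
        rz_new = r @ z
        p = z + (rz_new / rz) * p
        rz = rz_new

    img = ReconImage(x.reshape(system_matrix.grid_n, system_matrix.grid_n),
                     fov=system_matrix.fov,
                     pixel_pitch=system_matrix.pixel_pitch,
                     method="iterative",
                     provenance={"n_iter": int(n_iter),
                                 "kernel_std": system_matrix.kernel_std})
    return smooth_image(img, smoothing_fwhm) if smoothing_fwhm > 0 else img
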
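"""Scanner configuration, SPION magnetization model, and field/harmonic physics.

A mechanically-rotated field-free-line (FFL) magnetic particle imager encodes
a 2D tracer distribution as line integrals: a strong selection gradient
(``gradient_inplane``, T/m) nulls the field along a line through the bore, a
slow "shift" field translates that line across the head, and the gantry
rotates the whole magnet to collect projections at many angles.  A 26.3 kHz
sinusoidal drive field pushes superparamagnetic iron-oxide nanoparticles
(SPIONs) around their nonlinear magnetization curve; the induced EMF contains
harmonics of the drive whose amplitudes fall off with distance from the FFL,
giving the projection kernel.

Units follow one convention throughout the package: magnetic fields in mT,
gradients in T/m, distances in mm (so ``gradient[T/m] * distance[mm]``
is directly a field in mT), times in s, frequencies in Hz.
"""

from __future__ import annotations

import dataclasses
import io
import logging
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.optimize import brentq

logger = logging.getLogger("mpisim")

__all__ = [
    "ScannerConfig",
    "SPIONModel",
    "langevin",
    "harmonic_response",
    "third_harmonic_fwhm",
    "calibrate_beta",
    "ffl_offset_field",
]

# Harmonics retained by the console: 2nd through 9th.
HARMONICS = np.arange(2, 10)

#: YAML keys carry explicit unit suffixes; this maps them to field names.
_YAML_KEYS = {
    "gradient_inplane_T_per_m": "gradient_inplane",
    "gradient_axial_T_per_m": "gradient_axial",
    "drive_frequency_Hz": "drive_frequency",
    "drive_amplitude_mT": "drive_amplitude",
    "sample_rate_Sps": "sample_rate",
    "periods_per_readout": "periods_per_readout",
    "readouts_per_projection": "readouts_per_projection",
    "projections_per_image": "projections_per_image",
    "shift_frequency_Hz": "shift_frequency",
    "shift_field_peak_mT": "shift_field_peak",
    "gantry_rpm": "gantry_rpm",
    "image_sweep_degrees": "image_sweep_degrees",
}


@dataclass(frozen=True)
class ScannerConfig:
    """Operating point of the scanner.

    Defaults reproduce the human-scale prototype's nominal 181 mm
    field-of-view acquisition: 1.13 T/m in-plane gradient, 5.8 mT_peak drive
    at 1e6/38 Hz (38 samples per period at 1 MS/s), a 2.7 Hz rounded-triangle
    shift waveform, and a 180 degree gantry sweep in 5 s yielding 27
    projections of 132 read-outs each.
    """

    gradient_inplane: float = 1.13      # T/m, in the imaging plane (x')
    gradient_axial: float = 0.85        # T/m, through-plane; informational in 2D
    drive_frequency: float = 1e6 / 38.0  # Hz
    drive_amplitude: float = 5.8        # mT peak (coil limit ~7)
    sample_rate: float = 1e6            # samples/s
    periods_per_readout: int = 35
    readouts_per_projection: int = 132
    projections_per_image: int = 27
    shift_frequency: float = 2.7        # Hz
    shift_field_peak: float = 0.5 * 181.0 * 1.13  # mT; FOV = 2*peak/gradient
    gantry_rpm: float = 6.0
    image_sweep_degrees: float = 180.0

    def __post_init__(self) -> None:
        for name in (
            "gradient_inplane", "gradient_axial", "drive_frequency",
            "drive_amplitude", "sample_rate", "shift_frequency",
            "shift_field_peak", "gantry_rpm", "image_sweep_degrees",
        ):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("periods_per_readout", "readouts_per_projection",
                     "projections_per_image"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be a positive count")
        spp = self.sample_rate / self.drive_frequency
        if abs(spp - round(spp)) > 1e-9:
            raise ValueError(
                "sample_rate/drive_frequency must be an integer number of "
                f"samples per drive period (got {spp!r})"
            )

    @property
    def samples_per_period(self) -> int:
        return round(self.sample_rate / self.drive_frequency)

    @property
    def fov_mm(self) -> float:
        """Field-of-view diameter swept by the shift field, mm."""
        return 2.0 * self.shift_field_peak / self.gradient_inplane

    # -- serialization ------------------------------------------------------

    def to_yaml(self, path=None) -> str:
        doc = {k: getattr(self, v) for k, v in _YAML_KEYS.items()}
        text = yaml.safe_dump(doc, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "ScannerConfig":
        """Load from a YAML path, file object, or string."""
        if hasattr(source, "read"):
            doc = yaml.safe_load(source)
        elif isinstance(source, str) and "\n" not in source:
            with open(source) as fh:
                doc = yaml.safe_load(fh)
        else:
            doc = yaml.safe_load(io.StringIO(source))
        kwargs = {}
        for key, val in doc.items():
            if key not in _YAML_KEYS:
                raise KeyError(f"unknown config key {key!r}")
            kwargs[_YAML_KEYS[key]] = val
        return cls(**kwargs)

    def replace(self, **kwargs) -> "ScannerConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def with_fov(cls, fov_mm: float, **kwargs) -> "ScannerConfig":
        """Config whose shift-field peak gives the requested FOV diameter."""
        gradient = kwargs.get("gradient_inplane", cls.gradient_inplane)
        return cls(shift_field_peak=0.5 * fov_mm * gradient, **kwargs)


@dataclass(frozen=True)
class SPIONModel:
    """Relaxation-free Langevin particle model.

    The tracer is characterized operationally by the steepness ``beta`` of
    its Langevin argument per unit applied field (1/T): magnetization is
    ``signal_scale * L(beta * B)``.  ``beta`` is normally obtained with
    :func:`calibrate_beta` so that the third-harmonic offset-field kernel has
    the measured full-width-half-maximum (about 6 mT for Synomag-D at
    5.8 mT_peak drive).  ``signal_scale`` (signal units per g_Fe) is an
    arbitrary, calibratable gain.
    """

    beta: float                         # 1/T
    signal_scale: float = 1.0           # signal units per g_Fe
    name: str = "Synomag-D-like"

    def __post_init__(self) -> None:
        if not np.isfinite(self.beta) or self.beta <= 0:
            raise ValueError("beta must be strictly positive")

    @classmethod
    def from_kernel_fwhm(cls, target_fwhm_mT: float = 6.0,
                         drive_amplitude_mT: float = 5.8,
                         signal_scale: float = 1.0,
                         name: str = "Synomag-D-like") -> "SPIONModel":
        beta = calibrate_beta(target_fwhm_mT, drive_amplitude_mT)
        return cls(beta=beta, signal_scale=signal_scale, name=name)


def langevin(xi):
    """Langevin function L(xi) = coth(xi) - 1/xi.

    Equilibrium magnetization fraction of an ensemble of superparamagnetic
    moments at dimensionless field argument ``xi``.  Odd, strictly
    increasing, bounded in (-1, 1); the removable singularity at 0 is
    handled by the Taylor series xi/3 - xi^3/45 + 2 xi^5/945.
    """
    xi = np.asarray(xi, dtype=float)
    if not np.all(np.isfinite(xi)):
        raise ValueError("langevin requires finite arguments")
    out = np.empty_like(xi)
    small = np.abs(xi) < 1e-4
    xs = xi[small]
    out[small] = xs / 3.0 - xs**3 / 45.0 + 2.0 * xs**5 / 945.0
    xl = xi[~small]
    out[~small] = 1.0 / np.tanh(xl) - 1.0 / xl
    return out if out.ndim else float(out)


def harmonic_response(offset_field, drive_amplitude, spion, n_harmonics=9,
                      samples_per_period=38):
    """Complex received-signal amplitude at harmonics 2..n of the drive.

    Samples one drive period of magnetization
    ``M(t) = signal_scale * L(beta * (offset + drive * cos(w t)))``,
    Fourier-transforms it, and applies Faraday's law exactly in the Fourier
    domain (harmonic n multiplied by ``1j * n * w``), since the received EMF
    is proportional to dM/dt.  Fields in mT; ``beta`` converts T to the
    Langevin argument, hence the 1e-3 factor.

    Parameters
    ----------
    offset_field : float or array, mT
        Static field offset(s) seen by the particle (gradient x distance
        plus shift field).
    drive_amplitude : float, mT peak.
    spion : SPIONModel
    n_harmonics : highest harmonic returned (>= 2).
    samples_per_period : samples of the drive period; 38 matches the
        1 MS/s digitizer at the 1e6/38 Hz drive.

    Returns
    -------
    ndarray, complex, shape (..., n_harmonics - 1)
        Amplitudes at harmonics 2, 3, ..., n_harmonics.  For scalar input
        the leading axis is dropped.
    """
    if not np.isfinite(drive_amplitude) or drive_amplitude <= 0:
        raise ValueError("drive_amplitude must be strictly positive")
    if n_harmonics < 2:
        raise ValueError("n_harmonics must be >= 2")
    if n_harmonics >= samples_per_period // 2:
        raise ValueError("n_harmonics beyond the Nyquist bin of one period")
    offset = np.asarray(offset_field, dtype=float)
    scalar = offset.ndim == 0
    offset = np.atleast_1d(offset)
    if not np.all(np.isfinite(offset)):
        raise ValueError("offset_field must be finite")

    phase = 2.0 * np.pi * np.arange(samples_per_period) / samples_per_period
    field_mT = offset[:, None] + drive_amplitude * np.cos(phase)[None, :]
    m = spion.signal_scale * langevin(spion.beta * field_mT * 1e-3)
    spectrum = np.fft.fft(m, axis=-1) / samples_per_period
    n = np.arange(2, n_harmonics + 1)
    # Faraday differentiation: d/dt -> i * 2*pi*f_n in the Fourier domain.
    # The drive frequency itself is a fixed global factor absorbed here.
    omega = 2.0 * np.pi  # per drive period; callers see amplitudes ~ n * c_n
    amps = spectrum[:, n] * (1j * n * omega)
    return amps[0] if scalar else amps


def third_harmonic_fwhm(spion, drive_amplitude, offset_max=None, n_points=2001):
    """Full width at half maximum of the |3rd harmonic| central lobe, mT.

    Scans the offset-field axis symmetrically and walks outward from the
    peak (at zero offset) to the first half-maximum crossings, interpolating
    linearly.  The central lobe is the resolution-relevant kernel; for steep
    magnetization curves the |3rd harmonic| profile develops sidelobes
    inside the drive window that must not widen the measurement.  This is
    the simulated analogue of a magnetic particle spectrometer "system
    matrix mode" kernel measurement.
    """
    if offset_max is None:
        # Central lobe narrows like 1/beta but never below the drive window.
        offset_max = max(10.0 * drive_amplitude, 20.0e3 / spion.beta)
    offsets = np.linspace(-offset_max, offset_max, n_points)
    mag = np.abs(harmonic_response(offsets, drive_amplitude, spion,
                                   n_harmonics=3)[:, 1])
    ipk = int(np.argmax(mag))
    peak = mag[ipk]
    if peak <= 0:
        raise ValueError("third harmonic vanishes; cannot measure a width")
    half = 0.5 * peak

    def crossing(step):
        i = ipk
        while 0 < i < n_points - 1 and mag[i + step] >= half:
            i += step
        if i in (0, n_points - 1):
            raise ValueError("offset range does not bracket the half-max points")
        y0, y1 = mag[i], mag[i + step]
        x0, x1 = offsets[i], offsets[i + step]
        return x0 + (half - y0) * (x1 - x0) / (y1 - y0)

    return crossing(1) - crossing(-1)


def calibrate_beta(target_fwhm, drive_amplitude=5.8,
                   beta_range=(1e2, 1e6), rtol=1e-4):
    """Langevin steepness (1/T) whose 3rd-harmonic kernel has the target FWHM.

    The kernel FWHM is a strictly decreasing function of ``beta`` (a steeper
    magnetization curve saturates over a narrower offset range), so a
    bracketed root find on log(beta) converges unconditionally.

    Raises
    ------
    ValueError
        If ``target_fwhm`` is not positive or the search range does not
        bracket the solution.
    """
    if not np.isfinite(target_fwhm) or target_fwhm <= 0:
        raise ValueError("target_fwhm must be strictly positive")

    def f(log_beta):
        spion = SPIONModel(beta=float(np.exp(log_beta)))
        return third_harmonic_fwhm(spion, drive_amplitude) - target_fwhm

    lo, hi = np.log(beta_range[0]), np.log(beta_range[1])
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise ValueError("beta search range does not bracket the target FWHM")
    log_beta = brentq(f, lo, hi, xtol=rtol)
    beta = float(np.exp(log_beta))
    logger.debug("calibrate_beta: target %.3f mT at %.2f mT drive -> beta "
                 "%.1f 1/T", target_fwhm, drive_amplitude, beta)
    return beta


def ffl_offset_field(point_xy, gantry_angle, shift_field, config):
    """Selection-plus-shift field (mT) at a lab-frame point, given the gantry.

    The FFL passes through the isocenter along the rotated y' axis; the
    gradient acts along rotated x' = (cos theta, sin theta).  The offset is
    ``G * d + H_s`` with ``d`` the signed perpendicular distance (mm) from
    the point to the line, positive along +x'.  T/m times mm is directly mT.

    ``point_xy`` may be a single (x, y) pair in mm or an (N, 2) array.
    """
    pts = np.asarray(point_xy, dtype=float)
    theta = np.deg2rad(gantry_angle)
    d = pts[..., 0] * np.cos(theta) + pts[..., 1] * np.sin(theta)
    return config.gradient_inplane * d + shift_field
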
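"""One 5 s image acquisition: gantry sweep, shift waveform, read-outs, sinogram.

The console chops each projection into 132 read-outs (ROs) of exactly 35
drive periods (1.33 ms at the 26.3 kHz drive).  Each RO is Fourier
transformed and only the complex amplitudes at harmonics 2-9 are kept,
together with the mean gantry angle and mean shift field during the RO.
ROs are then binned by shift field and projection to form the per-harmonic
sinogram that reconstruction consumes.

Two signal paths are provided.  The fast *kernel* path factorizes the
response: every pixel's harmonic amplitude depends only on its scalar offset
field, so a precomputed offset->harmonics lookup table turns an RO into one
gather plus a mass-weighted sum.  The *time-domain* path synthesizes the
full 1330-sample magnetization waveform and FFTs it; it is the brute-force
oracle the kernel path is validated against.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .scanner_model import HARMONICS, ScannerConfig, SPIONModel, langevin

logger = logging.getLogger("mpisim")

__all__ = [
    "AcquisitionTiming",
    "Readout",
    "Sinogram",
    "HarmonicKernelTable",
    "make_timing",
    "shift_waveform",
    "simulate_image",
    "simulate_readout_timedomain",
    "bin_to_sinogram",
]

# Readout.flags bits
FLAG_INJECTED_SPIKE = 0x1   # simulator truth marker: this RO carries a spike
FLAG_INTERPOLATED = 0x2     # sinogram bin filled by neighbor interpolation


@dataclass(frozen=True)
class AcquisitionTiming:
    """Derived timing of one image acquisition (all durations in seconds)."""

    readout_duration: float
    samples_per_readout: int
    readouts_per_image: int
    projection_duration: float
    image_duration: float
    dead_time_per_projection: float


def make_timing(config: ScannerConfig) -> AcquisitionTiming:
    """Derive acquisition timing from the scanner configuration.

    Read-outs are contiguous blocks of ``periods_per_readout`` drive periods
    at the start of each projection slot; the slack between 132 read-outs
    and the projection slot (about 5% at the default operating point) is
    dead time at the projection boundary.
    """
    spp = config.sample_rate / config.drive_frequency
    if abs(spp - round(spp)) > 1e-9:
        raise ValueError("non-integer samples per drive period")
    readout_duration = config.periods_per_readout / config.drive_frequency
    samples_per_readout = config.periods_per_readout * round(spp)
    image_duration = (config.image_sweep_degrees / 360.0) * 60.0 / config.gantry_rpm
    projection_duration = image_duration / config.projections_per_image
    dead = projection_duration - config.readouts_per_projection * readout_duration
    if dead < -1e-12:
        raise ValueError("read-outs do not fit in the projection slot")
    return AcquisitionTiming(
        readout_duration=readout_duration,
        samples_per_readout=samples_per_readout,
        readouts_per_image=config.readouts_per_projection * config.projections_per_image,
        projection_duration=projection_duration,
        image_duration=image_duration,
        dead_time_per_projection=max(dead, 0.0),
    )


def shift_waveform(t, config: ScannerConfig, rounding_fraction: float = 0.05):
    """Rounded-triangle shift field (mT) at time(s) ``t``.

    A periodic triangle at ``shift_frequency`` of amplitude
    ``shift_field_peak``, starting at the negative corner at t = 0, with each
    corner replaced by a cosine blend spanning ``rounding_fraction`` of the
    period.  The blend matches the triangle's value and slope at its
    boundary (C1); ``rounding_fraction = 0`` gives the exact triangle.
    """
    if not 0.0 <= rounding_fraction < 0.5:
        raise ValueError("rounding_fraction must be in [0, 0.5)")
    u = np.mod(np.asarray(t, dtype=float) * config.shift_frequency, 1.0)
    peak = config.shift_field_peak
    s = np.where(u < 0.5, 4.0 * u - 1.0, 3.0 - 4.0 * u)  # unit triangle
    if rounding_fraction > 0.0:
        w = rounding_fraction / 2.0
        # distance (in u) to the nearest corner; sign of that corner's peak
        d_top = np.abs(u - 0.5)
        d_bot = np.minimum(u, 1.0 - u)
        for dist, sign in ((d_top, +1.0), (d_bot, -1.0)):
            m = dist <= w
            x = dist[m] / w
            blend = 1.0 - 4.0 * w * (1.0 - (2.0 / np.pi) * np.cos(np.pi * x / 2.0))
            s = np.array(s)
            s[m] = sign * blend
    out = peak * s
    return out if np.ndim(t) else float(out)


@dataclass(frozen=True)
class Readout:
    """One 35-drive-period acquisition window."""

    harmonic_amplitudes: np.ndarray   # complex, harmonics 2..9
    mean_gantry_angle: float          # degrees
    mean_shift_field: float           # mT
    timestamp: float                  # s, RO start
    flags: int = 0

    def __post_init__(self):
        if len(self.harmonic_amplitudes) != len(HARMONICS):
            raise ValueError("expected amplitudes for harmonics 2..9")


class HarmonicKernelTable:
    """Precomputed offset-field -> complex-harmonics lookup.

    Tabulates :func:`mpisim.scanner_model.harmonic_response` on a dense,
    uniform offset grid and evaluates by linear interpolation, vectorized
    over pixels and harmonics at once.  Offsets beyond the grid are fully
    saturated particles and return zero.
    """

    def __init__(self, spion: SPIONModel, drive_amplitude: float,
                 offset_max: float, step: float = 0.05,
                 samples_per_period: int = 38):
        from .scanner_model import harmonic_response

        n = int(np.ceil(offset_max / step)) + 1
        self.offsets = np.linspace(-n * step, n * step, 2 * n + 1)
        self.step = step
        # (n_harmonics, n_offsets) complex table
        self.table = harmonic_response(
            self.offsets, drive_amplitude, spion,
            n_harmonics=int(HARMONICS[-1]),
            samples_per_period=samples_per_period).T.copy()

    def __call__(self, offsets: np.ndarray) -> np.ndarray:
        """Complex harmonic amplitudes, shape (n_harmonics, len(offsets))."""
        o0 = self.offsets[0]
        idx = (np.asarray(offsets, float) - o0) / self.step
        inside = (idx >= 0) & (idx <= len(self.offsets) - 1)
        idx = np.clip(idx, 0, len(self.offsets) - 1.0000001)
        i0 = idx.astype(np.intp)
        frac = idx - i0
        vals = self.table[:, i0] * (1.0 - frac) + self.table[:, i0 + 1] * frac
        vals[:, ~inside] = 0.0
        return vals


def _pixel_point_masses(phantom):
    """Nonzero pixels of a phantom as (positions mm (N,2), masses g_Fe (N,))."""
    rows, cols = np.nonzero(phantom.concentration_grid)
    x, y = phantom.pixel_coordinates(rows, cols)
    # mg/mL * uL = ug; 1e-6 -> g
    vol_ul = phantom.pixel_pitch ** 2 * phantom.depth
    mass_g = phantom.concentration_grid[rows, cols] * vol_ul * 1e-6
    return np.column_stack([x, y]), mass_g


def _readout_schedule(config, timing, rounding_fraction):
    """Per-RO (timestamps, mean angles deg, mean shift fields mT)."""
    n_ro = config.readouts_per_projection
    n_proj = config.projections_per_image
    proj = np.repeat(np.arange(n_proj), n_ro)
    within = np.tile(np.arange(n_ro), n_proj)
    t0 = proj * timing.projection_duration + within * timing.readout_duration
    # gantry sweeps uniformly through image_sweep_degrees in image_duration
    rate = config.image_sweep_degrees / timing.image_duration
    angles = rate * (t0 + 0.5 * timing.readout_duration)
    # mean shift over the RO window, averaged over its digitizer samples
    ts = (np.arange(timing.samples_per_readout) + 0.5) / config.sample_rate
    shift = shift_waveform(t0[:, None] + ts[None, :], config,
                           rounding_fraction).mean(axis=1)
    return t0, angles, shift


def simulate_image(phantom, config: ScannerConfig, spion: SPIONModel,
                   noise_sigma: float = 0.0, spike_rate: float = 0.0,
                   seed: int = 0, spike_factor: float = 20.0,
                   rounding_fraction: float = 0.05):
    """Simulate all read-outs of one image (fast kernel mode).

    For each RO the mean gantry angle and mean shift field come from the
    timing model; each harmonic amplitude is the mass-weighted sum of the
    per-pixel kernel response at that pixel's offset field.  Complex white
    Gaussian noise of scale ``noise_sigma`` (std of the complex magnitude;
    each quadrature gets ``noise_sigma/sqrt(2)``) is added per harmonic per
    RO.  With probability ``spike_rate`` an RO's 3rd harmonic is multiplied
    by ``spike_factor``, mimicking the spurious shift-system spikes; such
    ROs carry the ``FLAG_INJECTED_SPIKE`` truth marker.

    Returns a list of :class:`Readout`, reproducible bit-for-bit from
    ``seed``.
    """
    timing = make_timing(config)
    t0, angles, shifts = _readout_schedule(config, timing, rounding_fraction)
    n_ro = len(t0)

    if phantom is not None and np.any(phantom.concentration_grid):
        pts, masses = _pixel_point_masses(phantom)
        r_max = np.hypot(pts[:, 0], pts[:, 1]).max()
        if 2.0 * r_max > config.fov_mm * (1 + 1e-9):
            warnings.warn("phantom extends beyond the configured FOV",
                          stacklevel=2)
        offset_max = (config.gradient_inplane * r_max
                      + config.shift_field_peak + 40.0 * 1e3 / spion.beta
                      + 2.0 * config.drive_amplitude)
        kernel = HarmonicKernelTable(spion, config.drive_amplitude, offset_max)
        theta = np.deg2rad(angles)
        proj_d = pts[:, 0][None, :] * np.cos(theta)[:, None] \
            + pts[:, 1][None, :] * np.sin(theta)[:, None]
        signal = np.empty((n_ro, len(HARMONICS)), dtype=complex)
        for i in range(n_ro):
            offs = config.gradient_inplane * proj_d[i] + shifts[i]
            signal[i] = kernel(offs) @ masses
    else:
        signal = np.zeros((n_ro, len(HARMONICS)), dtype=complex)

    rng = np.random.default_rng(seed)
    if noise_sigma > 0.0:
        noise = rng.normal(size=(n_ro, len(HARMONICS), 2))
        signal = signal + (noise[..., 0] + 1j * noise[..., 1]) \
            * noise_sigma / np.sqrt(2.0)
    flags = np.zeros(n_ro, dtype=int)
    if spike_rate > 0.0:
        spiked = rng.random(n_ro) < spike_rate
        h3 = int(np.where(HARMONICS == 3)[0][0])
        signal[spiked, h3] *= spike_factor
        flags[spiked] |= FLAG_INJECTED_SPIKE

    return [
        Readout(harmonic_amplitudes=signal[i].copy(),
                mean_gantry_angle=float(angles[i]),
                mean_shift_field=float(shifts[i]),
                timestamp=float(t0[i]), flags=int(flags[i]))
        for i in range(n_ro)
    ]


def simulate_readout_timedomain(point_masses, gantry_angle, shift_field,
                                config: ScannerConfig, spion: SPIONModel):
    """Brute-force time-domain oracle for one read-out.

    Synthesizes the summed magnetization waveform of a few point masses over
    ``samples_per_readout`` samples at the digitizer rate, Fourier
    transforms it, and reads harmonic n at FFT bin
    ``periods_per_readout * n`` with the same Fourier-domain Faraday factor
    as :func:`mpisim.scanner_model.harmonic_response`.

    Parameters
    ----------
    point_masses : list of ((x_mm, y_mm), mass_g) pairs.
    """
    from .scanner_model import ffl_offset_field

    timing = make_timing(config)
    n_samp = timing.samples_per_readout
    phase = 2.0 * np.pi * config.drive_frequency \
        * np.arange(n_samp) / config.sample_rate
    m = np.zeros(n_samp)
    for (xy, mass) in point_masses:
        offset = ffl_offset_field(np.asarray(xy, float), gantry_angle,
                                  shift_field, config)
        field_mT = offset + config.drive_amplitude * np.cos(phase)
        m = m + mass * spion.signal_scale * langevin(spion.beta * field_mT * 1e-3)
    spectrum = np.fft.fft(m) / n_samp
    n = HARMONICS
    bins = config.periods_per_readout * n
    # one FFT bin per period-harmonic; same Faraday convention as the
    # kernel path (drive frequency absorbed into the global gain)
    return spectrum[bins] * (1j * n * 2.0 * np.pi)


@dataclass
class Sinogram:
    """Per-harmonic complex sinogram: shape (n_harmonics, shift bins, projections)."""

    data: np.ndarray                  # complex, (8, n_shift, n_proj)
    shift_axis: np.ndarray            # mT, bin centers, strictly increasing
    angle_axis: np.ndarray            # degrees, mean measured angle per projection
    interpolated: np.ndarray          # bool, (n_shift, n_proj)
    provenance: dict = field(default_factory=dict)
    harmonic_numbers: np.ndarray = field(default_factory=lambda: HARMONICS.copy())
    #: degrees, mean measured angle of the ROs in each (shift, projection)
    #: bin; the gantry keeps rotating during a projection, so bins within a
    #: projection differ by up to the per-projection sweep (~6.7 degrees).
    bin_angles: np.ndarray = None

    def plane(self, harmonic: int) -> np.ndarray:
        """The (shift, angle) table of one harmonic."""
        idx = np.where(self.harmonic_numbers == harmonic)[0]
        if len(idx) == 0:
            raise KeyError(f"harmonic {harmonic} not stored")
        return self.data[int(idx[0])]

    @property
    def n_shift(self):
        return self.data.shape[1]

    @property
    def n_projections(self):
        return self.data.shape[2]


def bin_to_sinogram(readouts, config: ScannerConfig,
                    provenance=None) -> Sinogram:
    """Bin read-outs by shift field and projection, as the console does.

    Per projection, ROs fall into ``readouts_per_projection`` uniform
    shift-field bins spanning [-peak, +peak]; multiple ROs in a bin are
    complex-averaged, empty bins are linearly interpolated from their
    neighbors along the shift axis and flagged.  The projection angle is the
    mean measured RO angle of that projection.

    Raises
    ------
    ValueError
        If any projection has more than 50% empty bins.
    """
    n_bins = config.readouts_per_projection
    n_proj = config.projections_per_image
    if len(readouts) != n_bins * n_proj:
        raise ValueError("read-outs do not cover the full image sweep")
    peak = config.shift_field_peak
    edges = np.linspace(-peak, peak, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    data = np.zeros((len(HARMONICS), n_bins, n_proj), dtype=complex)
    counts = np.zeros((n_bins, n_proj), dtype=int)
    bin_angles = np.zeros((n_bins, n_proj))
    angle_axis = np.zeros(n_proj)
    for p in range(n_proj):
        block = readouts[p * n_bins:(p + 1) * n_bins]
        angle_axis[p] = np.mean([ro.mean_gantry_angle for ro in block])
        for ro in block:
            b = int(np.clip(np.digitize(ro.mean_shift_field, edges) - 1,
                            0, n_bins - 1))
            data[:, b, p] += ro.harmonic_amplitudes
            bin_angles[b, p] += ro.mean_gantry_angle
            counts[b, p] += 1
        empty = counts[:, p] == 0
        if empty.sum() > n_bins // 2:
            raise ValueError(f"projection {p}: more than 50% empty shift bins")
        filled = ~empty
        data[:, filled, p] /= counts[filled, p]
        bin_angles[filled, p] /= counts[filled, p]
        if empty.any():
            xi = centers[filled]
            bin_angles[empty, p] = np.interp(centers[empty], xi,
                                             bin_angles[filled, p])
            for h in range(len(HARMONICS)):
                data[h, empty, p] = (
                    np.interp(centers[empty], xi, data[h, filled, p].real)
                    + 1j * np.interp(centers[empty], xi, data[h, filled, p].imag)
                )
    interpolated = counts == 0
    prov = dict(provenance or {})
    prov.setdefault("config", config.to_yaml())
    return Sinogram(data=data, shift_axis=centers, angle_axis=angle_axis,
                    interpolated=interpolated, provenance=prov,
                    bin_angles=bin_angles)
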
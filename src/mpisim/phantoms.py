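"""Ground-truth 2D iron-concentration phantoms.

Three phantom families mirror the scanner's bench validation: parallel
capillary-tube pairs for spatial resolution, pipetted point sources (and a
dilution series of them) for the detection limit, and a large 'G'-shaped
glyph for field-of-view calibration.

Phantoms are 2D concentration maps (mg_Fe/mL) on a uniform grid with an
explicit slab ``depth`` (mm) so that pixel masses in g_Fe are well defined:
``mass = concentration * pitch^2 * depth`` (mg/mL times uL is ug).  Shapes
are rasterized with area-weighted (anti-aliased) edge pixels — exactly for
axis-aligned rectangles, by subpixel supersampling for curved shapes — so
total mass matches the analytic shape mass to well under 1% at the default
pitches.  All generators are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "PhantomImage",
    "make_line_pair",
    "make_point_source",
    "make_g_phantom",
    "dilution_series",
    "DilutionSeries",
]

_SUPERSAMPLE = 16  # subpixel grid for curved-shape coverage


@dataclass
class PhantomImage:
    """2D iron-concentration map, the simulator's ground truth.

    ``concentration_grid[row, col]`` is in mg_Fe/mL; lab-frame coordinates
    of a pixel center are ``x = (col - origin[1]) * pixel_pitch`` and
    ``y = (row - origin[0]) * pixel_pitch`` (mm), with the isocenter at
    ``origin``.
    """

    concentration_grid: np.ndarray
    pixel_pitch: float                    # mm
    origin: tuple                         # (row, col) of the isocenter
    depth: float                          # mm, slab thickness
    analytic_mass_ug: Optional[float] = None

    def __post_init__(self):
        if self.pixel_pitch <= 0 or self.depth <= 0:
            raise ValueError("pixel_pitch and depth must be positive")
        if np.any(self.concentration_grid < 0):
            raise ValueError("concentrations must be nonnegative")

    def pixel_coordinates(self, rows, cols):
        """Lab-frame (x, y) in mm of the given pixel indices."""
        x = (np.asarray(cols, float) - self.origin[1]) * self.pixel_pitch
        y = (np.asarray(rows, float) - self.origin[0]) * self.pixel_pitch
        return x, y

    @property
    def total_mass_ug(self) -> float:
        """Integrated iron mass, micrograms."""
        return float(self.concentration_grid.sum()
                     * self.pixel_pitch ** 2 * self.depth)

    def scaled(self, factor: float) -> "PhantomImage":
        return PhantomImage(self.concentration_grid * factor,
                            self.pixel_pitch, self.origin, self.depth,
                            None if self.analytic_mass_ug is None
                            else self.analytic_mass_ug * factor)


def _centered_grid(half_extent_mm: float, pitch: float):
    """Square grid covering +-half_extent, isocenter at the exact center."""
    n = int(np.ceil(2.0 * half_extent_mm / pitch)) + 2
    origin = ((n - 1) / 2.0, (n - 1) / 2.0)
    idx = np.arange(n)
    x = (idx - origin[1]) * pitch
    y = (idx - origin[0]) * pitch
    return n, origin, x, y


def _rect_coverage(x, y, pitch, x0, x1, y0, y1):
    """Exact pixel coverage fraction of an axis-aligned rectangle."""
    ox = np.clip(np.minimum(x1, x[None, :] + pitch / 2)
                 - np.maximum(x0, x[None, :] - pitch / 2), 0.0, None)
    oy = np.clip(np.minimum(y1, y[:, None] + pitch / 2)
                 - np.maximum(y0, y[:, None] - pitch / 2), 0.0, None)
    return ox * oy / pitch ** 2


def _cov_loop(x, y, pitch, inside_fn, sub):
    """Coverage fraction of an arbitrary region by subpixel supersampling."""
    cov = np.zeros((len(y), len(x)))
    for dx in sub:
        for dy in sub:
            cov += inside_fn(x[None, :] + dx * pitch, y[:, None] + dy * pitch)
    return cov / len(sub) ** 2


def make_line_pair(separation_inner_surface, tube_diameter=2.5,
                   tube_length=50.0, concentration=0.5,
                   pixel_pitch=0.5, depth=None) -> PhantomImage:
    """Two parallel capillary tubes, projected in 2D as filled rectangles.

    Tubes run along y, separated along x; the *inner surfaces* are
    ``separation_inner_surface`` apart, so center-to-center distance is
    separation + diameter.  Default depth equals the tube diameter, making
    per-tube mass = diameter * length * depth * concentration.
    """
    if separation_inner_surface < 0 or tube_diameter <= 0:
        raise ValueError("separation must be >= 0 and diameter > 0")
    if pixel_pitch > tube_diameter / 2:
        raise ValueError("pixel_pitch > diameter/2 under-resolves the tubes")
    if depth is None:
        depth = tube_diameter
    c2c = separation_inner_surface + tube_diameter
    half = c2c / 2 + tube_diameter / 2
    n, origin, x, y = _centered_grid(max(half, tube_length / 2) + 2 * pixel_pitch,
                                     pixel_pitch)
    cov = np.zeros((n, n))
    for xc in (-c2c / 2, c2c / 2):
        cov += _rect_coverage(x, y, pixel_pitch,
                              xc - tube_diameter / 2, xc + tube_diameter / 2,
                              -tube_length / 2, tube_length / 2)
    cov = np.clip(cov, 0.0, 1.0)  # touching tubes may share edge pixels
    mass = 2 * tube_diameter * tube_length * depth * concentration
    return PhantomImage(cov * concentration, pixel_pitch, origin, depth,
                        analytic_mass_ug=mass)


def make_point_source(volume_ul, concentration, pixel_pitch=0.5,
                      depth=3.0, center=(0.0, 0.0)) -> PhantomImage:
    """Small disc approximating a pipetted sample of the given volume.

    The disc radius follows from volume = pi r^2 depth; integrated mass is
    volume * concentration.
    """
    if volume_ul <= 0:
        raise ValueError("volume must be positive")
    radius = np.sqrt(volume_ul / (np.pi * depth))
    cx, cy = center
    half = max(abs(cx), abs(cy)) + radius + 2 * pixel_pitch
    n, origin, x, y = _centered_grid(half, pixel_pitch)
    sub = (np.arange(_SUPERSAMPLE) + 0.5) / _SUPERSAMPLE - 0.5

    def inside(xx, yy):
        return ((xx - cx) ** 2 + (yy - cy) ** 2 <= radius ** 2).astype(float)

    cov = _cov_loop(x, y, pixel_pitch, inside, sub)
    return PhantomImage(cov * concentration, pixel_pitch, origin, depth,
                        analytic_mass_ug=volume_ul * concentration)


def make_g_phantom(circle_diameter=136.0, line_width=4.0,
                   concentration=0.0625, pixel_pitch=1.0, depth=None,
                   gap_angle=(12.0, 60.0), bar_length=25.0) -> PhantomImage:
    """Open-ring 'G' glyph: an annulus with a gap plus a horizontal crossbar.

    ``circle_diameter`` is the centerline diameter of the ring, so the
    outermost nonzero extent is circle_diameter + line_width.  The gap
    (degrees CCW from +x) and bar length are free glyph parameters.
    """
    if line_width >= circle_diameter:
        raise ValueError("line_width must be smaller than circle_diameter")
    if depth is None:
        depth = line_width
    r_mid = circle_diameter / 2.0
    w2 = line_width / 2.0
    n, origin, x, y = _centered_grid(r_mid + w2 + 2 * pixel_pitch, pixel_pitch)
    lo, hi = gap_angle
    sub = (np.arange(_SUPERSAMPLE) + 0.5) / _SUPERSAMPLE - 0.5

    def inside(xx, yy):
        r = np.hypot(xx, yy)
        ang = np.mod(np.degrees(np.arctan2(yy, xx)), 360.0)
        ring = (np.abs(r - r_mid) <= w2) & ~((ang > lo) & (ang < hi))
        bar = (xx >= r_mid - bar_length) & (xx <= r_mid) & (np.abs(yy) <= w2)
        return (ring | bar).astype(float)

    cov = _cov_loop(x, y, pixel_pitch, inside, sub)
    return PhantomImage(cov * concentration, pixel_pitch, origin, depth)


@dataclass
class DilutionSeries:
    phantoms: list
    concentrations: np.ndarray      # mg_Fe/mL
    masses_ug: np.ndarray           # analytic iron mass per sample


def dilution_series(volume_ul=20.0, start_concentration=6.0,
                    end_concentration=0.0156, n_samples=8,
                    pixel_pitch=0.5, depth=3.0) -> DilutionSeries:
    """Geometric dilution series of point-source phantoms.

    Concentrations run from ``start_concentration`` down to
    ``end_concentration`` inclusive with constant ratio
    ``(end/start)^(1/(n-1))``; defaults give the 8-sample 6 mg/mL ->
    15.6 ug/mL series of 20 uL samples (masses 120 ug down to ~312 ng).
    """
    if not (start_concentration > end_concentration > 0):
        raise ValueError("need start > end > 0")
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    conc = start_concentration * (end_concentration / start_concentration) \
        ** (np.arange(n_samples) / (n_samples - 1))
    base = make_point_source(volume_ul, 1.0, pixel_pitch, depth)
    phantoms = [base.scaled(c) for c in conc]
    for ph, c in zip(phantoms, conc):
        ph.analytic_mass_ug = volume_ul * c
    return DilutionSeries(phantoms=phantoms, concentrations=conc,
                          masses_ug=volume_ul * conc)
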
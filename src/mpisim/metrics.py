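"""Quantitative validation statistics.

Two-peak contrast and resolution-from-series score the line-pair phantoms;
a dilution-series regression yields the detection limit (the iron mass whose
fitted image signal equals 5x the empty-bore noise standard deviation); a
known feature extent calibrates the FOV; plus image SNR and the gradiometer
feedthrough-attenuation formula.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import linregress

__all__ = [
    "ContrastResult",
    "DetectionLimitResult",
    "UnresolvedProfileError",
    "contrast",
    "resolution_from_series",
    "detection_limit",
    "fov_calibration",
    "feedthrough_attenuation",
    "image_snr",
]

UNRESOLVED = "unresolved"


class UnresolvedProfileError(ValueError):
    """Profile does not contain two identifiable peaks.

    Distinct from a *measured* contrast of <= 0.5: here no two-peak
    structure exists at all, so no contrast value can be quoted.
    """


@dataclass(frozen=True)
class ContrastResult:
    """Two-peak contrast C = 1 - S_min / (0.5 (S_max_left + S_max_right))."""

    C: float
    S_min: float
    S_max_left: float
    S_max_right: float
    peak_positions: tuple   # (left mm, right mm)


def contrast(profile, positions=None) -> ContrastResult:
    """Contrast between the two most prominent peaks of a 1D profile.

    Peaks are ranked by topographic prominence, not raw height, so ringing
    sidelobes of a sharpening reconstruction do not displace the main lobes.
    C > 0.5 is the conventional "resolved" criterion.
    """
    y = np.asarray(profile, float)
    if len(y) < 5:
        raise ValueError("profile must have at least 5 samples")
    x = np.arange(len(y), dtype=float) if positions is None \
        else np.asarray(positions, float)
    peaks, props = find_peaks(y, prominence=0.0)
    if len(peaks) < 2:
        raise UnresolvedProfileError("fewer than 2 local maxima in profile")
    top2 = peaks[np.argsort(props["prominences"])[-2:]]
    left, right = np.sort(top2)
    s_left, s_right = y[left], y[right]
    s_min = y[left:right + 1].min()
    c = 1.0 - s_min / (0.5 * (s_left + s_right))
    return ContrastResult(C=float(c), S_min=float(s_min),
                          S_max_left=float(s_left), S_max_right=float(s_right),
                          peak_positions=(float(x[left]), float(x[right])))


def resolution_from_series(images, separations, profile_axis="x",
                           clip_negative=True):
    """Smallest line-pair separation with contrast C > 0.5.

    Extracts the central profile perpendicular to the tubes from each
    reconstructed image, scores the two-peak contrast, and returns the
    smallest separation (mm) that is resolved; returns the string sentinel
    ``"unresolved"`` if none is.  Separations must be sorted ascending.

    Iron concentration is nonnegative, so by default profiles are floored
    at zero before scoring: negative reconstruction excursions are ringing
    artifacts, and letting them deepen the inter-peak valley would report
    contrasts above 1.
    """
    separations = list(separations)
    if sorted(separations) != separations:
        raise ValueError("separations must be sorted ascending")
    for sep, img in zip(separations, images):
        pos, prof = img.center_profile(profile_axis)
        if clip_negative:
            prof = np.clip(prof, 0.0, None)
        try:
            res = contrast(prof, pos)
        except UnresolvedProfileError:
            continue
        if res.C > 0.5:
            return sep
    return UNRESOLVED


@dataclass(frozen=True)
class DetectionLimitResult:
    """Linear signal-vs-mass fit and the derived 1-sigma / 5-sigma LODs."""

    slope: float            # signal per g_Fe
    intercept: float        # signal
    r_squared: float
    noise_sigma: float      # signal
    lod_1sigma: float       # g_Fe
    lod_5sigma: float       # g_Fe


def detection_limit(masses, peak_signals, noise_sigma) -> DetectionLimitResult:
    """Detection limit from a dilution-series regression.

    Ordinary least squares of peak signal against iron mass; the k-sigma LOD
    is the mass where the fitted line crosses k times the empty-bore noise
    standard deviation (the intercept is kept — a non-zero baseline signal
    shifts the LOD, so the zero-intercept shortcut lod_5 = 5 lod_1 holds
    only when b = 0).
    """
    masses = np.asarray(masses, float)
    signals = np.asarray(peak_signals, float)
    if len(masses) < 3:
        raise ValueError("need at least 3 dilution points")
    if noise_sigma <= 0:
        raise ValueError("noise_sigma must be positive")
    fit = linregress(masses, signals)
    if fit.slope <= 0:
        raise ValueError("non-positive slope: no sensitivity to iron mass")
    lod = {k: (k * noise_sigma - fit.intercept) / fit.slope for k in (1, 5)}
    return DetectionLimitResult(slope=float(fit.slope),
                                intercept=float(fit.intercept),
                                r_squared=float(fit.rvalue ** 2),
                                noise_sigma=float(noise_sigma),
                                lod_1sigma=float(lod[1]),
                                lod_5sigma=float(lod[5]))


def fov_calibration(image, known_feature_extent, measured_extent_pixels):
    """FOV diameter (mm) from a feature of known physical extent.

    FOV = known extent x (grid size) / (measured extent in pixels), the
    pixel counts being distances between outermost pixel centers.
    """
    if measured_extent_pixels < 2:
        raise ValueError("measured extent must span at least 2 pixels")
    return known_feature_extent * image.grid_n / measured_extent_pixels


def feedthrough_attenuation(v_rx_out, v_rx_in, i_drive_in, i_drive_out):
    """Gradiometer feedthrough attenuation in dBc.

    A = (V_rx,out / V_rx,in) * (I_drive,in / I_drive,out), reported as
    20 log10(A); "out" quantities are measured with the receive coil halfway
    removed (maximum coupling), "in" with it nulled in place.
    """
    vals = (v_rx_out, v_rx_in, i_drive_in, i_drive_out)
    if any(v <= 0 for v in vals):
        raise ValueError("all voltages and currents must be positive")
    a = (v_rx_out / v_rx_in) * (i_drive_in / i_drive_out)
    return 20.0 * np.log10(a)


def image_snr(image, noise_image):
    """Peak signal over the all-voxel standard deviation of an empty-bore image.

    Both images must share a grid; the noise std is taken over the in-FOV
    disc (the reconstruction support).
    """
    if image.values.shape != noise_image.values.shape:
        raise ValueError("image and noise image must share a grid")
    n = image.grid_n
    ax, ay = image.coords()
    X, Y = np.meshgrid(ax, ay)
    in_fov = np.hypot(X, Y) <= image.fov / 2.0
    sigma = noise_image.values[in_fov].std()
    if sigma == 0:
        raise ValueError("noise image has zero standard deviation")
    return float(image.values[in_fov].max() / sigma)
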
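"""Sinogram cleaning: complex linear baseline subtraction and MAD despiking.

Baseline subtraction assumes no tracer signal at the FOV perimeter: each
projection (one column of the sinogram, indexed along the shift axis) has
the complex line through the mean of its first two and the mean of its last
two points removed.

Despiking reproduces the moving-median scaled-MAD outlier rule
(``isoutlier(data, 'movmedian', 3)`` semantics): a point is an outlier when
its deviation from the local median within a 3-element window exceeds three
scaled median absolute deviations (scaled MAD = 1.4826 x MAD).  The test is
applied to complex magnitudes, which makes it phase-robust and invariant to
global complex rescaling; windows at the column ends truncate to two
elements.  Degenerate windows with MAD = 0 never flag (zero deviation is
never greater than zero), so constant regions are untouched.
"""

from __future__ import annotations

import copy

import numpy as np

from .acquisition import Sinogram

__all__ = ["subtract_baseline", "despike", "preprocess_sinogram"]

_MAD_SCALE = 1.4826  # consistency factor for Gaussian data
_MAD_THRESHOLD = 3.0


def subtract_baseline(projection: np.ndarray) -> np.ndarray:
    """Remove the complex linear baseline anchored at the profile ends.

    The line passes through (0.5, mean of points 0-1) and (N-1.5, mean of
    points N-2..N-1); after subtraction both end-pair means are zero.
    """
    v = np.asarray(projection)
    n = len(v)
    if n < 4:
        raise ValueError("projection must have at least 4 points")
    x0, y0 = 0.5, v[:2].mean()
    x1, y1 = n - 1.5, v[-2:].mean()
    slope = (y1 - y0) / (x1 - x0)
    line = y0 + slope * (np.arange(n) - x0)
    return v - line


def _window_median_mad(mag: np.ndarray):
    """Centered 3-element moving median and MAD of a 1D magnitude signal."""
    n = len(mag)
    med = np.empty(n)
    mad = np.empty(n)
    for i in range(n):
        w = mag[max(0, i - 1):i + 2]
        m = np.median(w)
        med[i] = m
        mad[i] = np.median(np.abs(w - m))
    return med, mad


def despike(plane: np.ndarray):
    """Flag and repair spike outliers in a complex sinogram plane.

    Operates column-wise along the shift axis (axis 0).  Returns
    ``(cleaned, mask)`` where ``mask`` marks the outliers; each outlier's
    complex value is replaced by the elementwise median (real and imaginary
    separately) of the non-outlier points in its window, i.e. the mean of
    its two neighbors in the interior.
    """
    data = np.atleast_2d(np.asarray(plane))
    squeeze = np.asarray(plane).ndim == 1
    if squeeze:
        data = data.T
    if data.size == 0:
        raise ValueError("empty sinogram plane")
    cleaned = data.astype(complex).copy()
    mask = np.zeros(data.shape, dtype=bool)
    n = data.shape[0]
    for j in range(data.shape[1]):
        mag = np.abs(data[:, j])
        med, mad = _window_median_mad(mag)
        out = np.abs(mag - med) > _MAD_THRESHOLD * _MAD_SCALE * mad
        mask[:, j] = out
        for i in np.nonzero(out)[0]:
            w = np.arange(max(0, i - 1), min(n, i + 2))
            good = w[~out[w]]
            if len(good) == 0:
                good = w[w != i]
            repl = np.median(cleaned[good, j].real) \
                + 1j * np.median(cleaned[good, j].imag)
            cleaned[i, j] = repl
    if squeeze:
        return cleaned[:, 0], mask[:, 0]
    return cleaned, mask


def preprocess_sinogram(sinogram: Sinogram, harmonics=None) -> Sinogram:
    """Baseline-subtract every projection, then despike, per harmonic plane.

    Returns a new Sinogram; the outlier mask (union over processed
    harmonics) is stored in ``provenance['outlier_mask']``.
    """
    out = copy.deepcopy(sinogram)
    todo = (sinogram.harmonic_numbers if harmonics is None
            else np.atleast_1d(harmonics))
    union = np.zeros(sinogram.data.shape[1:], dtype=bool)
    for h in todo:
        idx = int(np.where(sinogram.harmonic_numbers == h)[0][0])
        plane = out.data[idx]
        for p in range(plane.shape[1]):
            plane[:, p] = subtract_baseline(plane[:, p])
        cleaned, mask = despike(plane)
        out.data[idx] = cleaned
        union |= mask
    out.provenance["outlier_mask"] = union
    return out
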
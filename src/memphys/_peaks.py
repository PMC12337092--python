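"""Shared peak-metric primitives for thermograms and spectra.

All routines operate on sampled curves (x strictly increasing) and return
sub-grid quantities by local polynomial interpolation.
"""

from __future__ import annotations

import math

import numpy as np

from .exceptions import AmbiguousPeakError, DomainError


def quadratic_vertex(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Vertex of the parabola through the maximum sample and its neighbours.

    Returns (x_apex, y_apex) at sub-grid resolution.  Raises DomainError if
    the maximum sits on the boundary (no interior maximum).
    """
    i = int(np.argmax(y))
    if i == 0 or i == len(y) - 1:
        raise DomainError("no interior maximum")
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return float(x[i]), float(y1)
    delta = 0.5 * (y0 - y2) / denom
    # local grid may be slightly non-uniform; use the mean spacing here
    h = 0.5 * (x[i + 1] - x[i - 1])
    x_apex = float(x[i] + delta * h)
    y_apex = float(y1 - 0.25 * (y0 - y2) * delta)
    return x_apex, y_apex


def quadratic_apex_fit(x: np.ndarray, y: np.ndarray,
                       half_points: int = 2) -> tuple[float, float]:
    """Apex by local quadratic interpolation on the log intensity (Gaussian
    apex interpolation) over the maximum sample and ``half_points``
    neighbours on each side.

    For a Gaussian band the log intensity is exactly quadratic, so the
    vertex is unbiased regardless of where the true center falls between
    grid points; averaging over five samples also damps noise relative to
    the three-point vertex.  Falls back to the plain three-point parabola
    when the local intensities are not all positive.
    """
    i = int(np.argmax(y))
    if i == 0 or i == len(y) - 1:
        raise DomainError("no interior maximum")
    lo = max(i - half_points, 0)
    hi = min(i + half_points, len(y) - 1)
    ys = y[lo:hi + 1]
    if hi - lo + 1 < 3 or np.any(ys <= 0):
        return quadratic_vertex(x, y)
    xs = x[lo:hi + 1] - x[i]
    c2, c1, c0 = np.polyfit(xs, np.log(ys), 2)
    if c2 >= 0:  # not concave: fall back to the 3-point vertex
        return quadratic_vertex(x, y)
    dx = -c1 / (2.0 * c2)
    return float(x[i] + dx), float(math.exp(c0 - c1 ** 2 / (4.0 * c2)))


def half_max_crossings(x: np.ndarray, y: np.ndarray,
                       level: float) -> np.ndarray:
    """x-positions where the curve crosses ``level``, linearly interpolated."""
    s = y - level
    idx = np.nonzero(s[:-1] * s[1:] < 0)[0]
    crossings = []
    for i in idx:
        frac = s[i] / (s[i] - s[i + 1])
        crossings.append(x[i] + frac * (x[i + 1] - x[i]))
    # exact touches
    for i in np.nonzero(s == 0)[0]:
        crossings.append(x[i])
    return np.sort(np.asarray(crossings))


def fwhm_from_curve(x: np.ndarray, y: np.ndarray) -> float:
    """Full width at half maximum of a single-peak curve.

    Apex height via the three-point parabola; more than two half-height
    crossings raises AmbiguousPeakError (multi-peak curve: deconvolve).
    """
    _, y_apex = quadratic_vertex(x, y)
    crossings = half_max_crossings(x, y, 0.5 * y_apex)
    if len(crossings) < 2:
        raise DomainError("half-maximum level is not crossed twice")
    if len(crossings) > 2:
        raise AmbiguousPeakError(
            f"{len(crossings)} half-maximum crossings: curve is not a "
            "single peak (consider deconvolution)")
    return float(crossings[1] - crossings[0])
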
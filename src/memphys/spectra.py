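"""CH-stretch band metrics for ATR-FTIR and Raman spectra of lipid membranes.

The acyl-chain C-H stretching region carries the standard order/disorder
markers used in membrane spectroscopy:

* apex wavenumber of the CH2 antisymmetric stretch (~2920 cm^-1, FTIR):
  blue shifts of 1-2 cm^-1 signal more gauche conformers, i.e. chain
  disordering;
* bandwidth (fwhm) of the same band: broadening signals increased chain
  mobility;
* the Raman order ratio I(~2930)/I(~2850) — terminal CH3 symmetric stretch
  over methylene symmetric stretch — which grows as interchain coupling is
  lost.

Positions are apex metrics (local quadratic interpolation), matching how
such shifts are usually reported; a center-of-gravity option is exposed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as mio
from ._peaks import fwhm_from_curve, quadratic_apex_fit, quadratic_vertex
from .exceptions import AmbiguousPeakError, DomainError, SchemaError

__all__ = ["Spectrum", "normalize", "peak_position", "band_fwhm",
           "raman_order_ratio", "pseudo_voigt",
           "FTIR_NU_AS_CH2_WINDOW", "FTIR_NU_S_CH2_WINDOW",
           "RAMAN_CH3_WINDOW", "RAMAN_CH2_SYM_WINDOW"]

#: Default analysis windows (cm^-1): CH2 antisymmetric and symmetric
#: stretches (FTIR) and the terminal-CH3 / symmetric-CH2 Raman bands.
FTIR_NU_AS_CH2_WINDOW = (2910.0, 2940.0)
FTIR_NU_S_CH2_WINDOW = (2840.0, 2860.0)
RAMAN_CH3_WINDOW = (2915.0, 2945.0)
RAMAN_CH2_SYM_WINDOW = (2833.0, 2863.0)

SPECTRUM_SCHEMA = mio.TableSchema(
    required=("wavenumber_cm1", "intensity"),
    monotone=("wavenumber_cm1",),
    min_rows=5,
)


def pseudo_voigt(nu, center, height, fwhm, eta=0.2):
    """Pseudo-Voigt band: (1-eta) Gaussian + eta Lorentzian, both of the
    given fwhm, scaled to apex ``height``."""
    nu = np.asarray(nu, dtype=float)
    sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    gamma = fwhm / 2.0
    g = np.exp(-0.5 * ((nu - center) / sigma) ** 2)
    l = 1.0 / (1.0 + ((nu - center) / gamma) ** 2)
    return height * ((1.0 - eta) * g + eta * l)


@dataclass
class Spectrum:
    """Wavenumber-indexed intensity with instrument metadata."""

    nu: np.ndarray          # cm^-1, strictly increasing
    intensity: np.ndarray   # arbitrary units
    kind: str = "ATR-FTIR"  # or "Raman"
    resolution_cm1: float = 4.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.nu = np.asarray(self.nu, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.nu.ndim != 1 or len(self.nu) != len(self.intensity):
            raise DomainError("nu and intensity must be 1-D and equal length")
        if not np.all(np.diff(self.nu) > 0):
            raise DomainError("wavenumber grid must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise DomainError("intensities must be finite")

    def replace_intensity(self, intensity) -> "Spectrum":
        return Spectrum(nu=self.nu.copy(),
                        intensity=np.asarray(intensity, dtype=float),
                        kind=self.kind, resolution_cm1=self.resolution_cm1,
                        meta=dict(self.meta))

    def window(self, lo: float, hi: float) -> tuple[np.ndarray, np.ndarray]:
        if lo < self.nu[0] or hi > self.nu[-1]:
            raise DomainError(
                f"window ({lo}, {hi}) outside grid "
                f"({self.nu[0]}, {self.nu[-1]})")
        mask = (self.nu >= lo) & (self.nu <= hi)
        if mask.sum() < 3:
            raise DomainError("window contains fewer than 3 samples")
        return self.nu[mask], self.intensity[mask]

    def write(self, path, sep: str = ",") -> None:
        df = pd.DataFrame({"wavenumber_cm1": self.nu,
                           "intensity": self.intensity})
        meta = {"kind": self.kind, "resolution_cm1": self.resolution_cm1,
                **self.meta}
        mio.write_table(path, df, meta, sep=sep)

    @classmethod
    def read(cls, path) -> "Spectrum":
        df, meta = mio.read_table(path, SPECTRUM_SCHEMA)
        kind = str(meta.pop("kind", "ATR-FTIR"))
        res = float(meta.pop("resolution_cm1", 4.0))
        return cls(nu=df["wavenumber_cm1"].to_numpy(),
                   intensity=df["intensity"].to_numpy(),
                   kind=kind, resolution_cm1=res, meta=meta)


def _apex_in_window(s: Spectrum, window, robust: bool = True):
    nu, y = s.window(*window)
    if robust:
        return quadratic_apex_fit(nu, y)
    return quadratic_vertex(nu, y)


def normalize(s: Spectrum, anchor_cm1: float,
              search_halfwidth: float = 15.0) -> Spectrum:
    """Divide by the apex intensity of the band nearest ``anchor_cm1`` so
    that band's apex becomes exactly 1.0.  Idempotent."""
    lo = max(anchor_cm1 - search_halfwidth, float(s.nu[0]))
    hi = min(anchor_cm1 + search_halfwidth, float(s.nu[-1]))
    if lo >= hi:
        raise DomainError("anchor lies outside the wavenumber grid")
    _, height = _apex_in_window(s, (lo, hi))
    if height <= 0:
        raise DomainError("anchor band apex intensity is not positive")
    return s.replace_intensity(s.intensity / height)


def peak_position(s: Spectrum, window, method: str = "apex") -> float:
    """Apex wavenumber (cm^-1) of the band inside ``window``.

    ``method='apex'`` (default) fits a local parabola around the band top;
    ``method='cog'`` returns the intensity-weighted center of gravity above
    the half-maximum level.
    """
    nu, y = s.window(*window)
    if method == "apex":
        pos, _ = quadratic_apex_fit(nu, y)
        return pos
    if method == "cog":
        _, apex_height = quadratic_vertex(nu, y)
        base = float(np.min(y))
        level = base + 0.5 * (apex_height - base)
        mask = y >= level
        w = y[mask] - base
        return float(np.sum(nu[mask] * w) / np.sum(w))
    raise DomainError(f"unknown peak position method '{method}'")


def band_fwhm(s: Spectrum, window, baseline: str = "linear") -> float:
    """Band full width at half maximum (cm^-1) inside ``window``.

    With ``baseline='linear'`` (default) a straight line through the window
    edges is removed first — neighbouring CH bands shoulder each other, and
    the local baseline isolates the band of interest.  ``baseline='none'``
    measures the raw curve.
    """
    nu, y = s.window(*window)
    if baseline == "linear":
        n_edge = max(2, len(nu) // 20)
        x_edge = np.concatenate([nu[:n_edge], nu[-n_edge:]])
        y_edge = np.concatenate([y[:n_edge], y[-n_edge:]])
        coeffs = np.polyfit(x_edge, y_edge, 1)
        y = y - np.polyval(coeffs, nu)
    elif baseline != "none":
        raise DomainError(f"unknown baseline mode '{baseline}'")
    return fwhm_from_curve(nu, y)


def raman_order_ratio(s: Spectrum,
                      ch3_window=RAMAN_CH3_WINDOW,
                      ch2_window=RAMAN_CH2_SYM_WINDOW) -> float:
    """Raman order marker: apex intensity of the terminal-CH3 band (~2930)
    over that of the symmetric-CH2 band (~2848).  Invariant under global
    intensity scaling."""
    try:
        _, num = _apex_in_window(s, ch3_window)
        _, den = _apex_in_window(s, ch2_window)
    except DomainError as exc:
        raise DomainError(f"order-ratio band missing: {exc}") from exc
    if den <= 0:
        raise DomainError("symmetric CH2 band apex intensity is not positive")
    return num / den
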
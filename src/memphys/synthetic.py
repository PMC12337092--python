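"""Synthetic-data generators for every input the analyses consume.

Each generator draws from an explicit seed, embeds its truth parameters in
the output metadata (so recovery tests are self-describing) and mirrors the
study conditions of the experiments it emulates:

* trajectories: two ~100 um droplets, one pure water and one 0.1 M NaCl,
  a DOPC bilayer with P_f = 73 um/s, 1 s frames over 300 s, optical radius
  jitter sigma_R = 0.2 um;
* thermograms: one or two quasi-Gaussian excess-Cp components on a drifting
  baseline over -40..0 degC (the DOPC main transition window), SNR 50;
* spectra: pseudo-Voigt CH-stretch bands (FTIR: 2853/2923.1; Raman:
  2850/2890/2930 cm^-1) on a 4 cm^-1 grid, SNR 100;
* tension tables: per-trial Gaussian scatter around per-concentration truth
  (gamma_m, theta), n >= 10 trials per row.

Noise is Gaussian and additive throughout; SNR is defined as peak height
over noise standard deviation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dib
from .constants import (DOPC_CONTACT_ANGLE_DEG, NACL_OSMOTIC_MULTIPLIER,
                        UM_TO_M, nacl_osmolarity_mol_m3)
from .dsc import Thermogram, gaussian_peak
from .exceptions import DomainError
from .spectra import Spectrum, pseudo_voigt

__all__ = [
    "TrajectoryConfig", "ThermogramConfig", "SpectrumConfig",
    "TensionScatterConfig", "gen_trajectory", "gen_thermogram",
    "gen_spectrum", "gen_tension_table", "summarize_tension_trials",
    "CONTROL_TWO_COMPONENT_TRUTH",
]

#: Two-component DSC truth used as the generator default: component apex
#: temperatures and area fractions of a strongly perturbed membrane
#: (higher-Tm component 31% / lower-Tm 69% of a 6.03 kcal/mol total).
#: Component widths are a design choice (see docs/methods.md): 1.8 / 2.6 degC,
#: bracketing the 2.27 degC width of the unperturbed transition and producing
#: the characteristic low-temperature shoulder.
CONTROL_TWO_COMPONENT_TRUTH = (
    (-17.26, 0.31 * 6.03, 1.8),
    (-18.77, 0.69 * 6.03, 2.6),
)


def _require(cond: bool, message: str) -> None:
    if not cond:
        raise DomainError(message)


# ---------------------------------------------------------------------------
# Droplet trajectories
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryConfig:
    """Truth parameters and noise level for a synthetic DIB osmotic run."""

    seed: int
    pf_um_s: float = 73.0
    r1_um: float = 50.0              # pure-water droplet radius
    r2_um: float = 50.0              # saline droplet radius
    nacl_M: float = 0.1
    pfas_mM: float = 0.0             # added to droplet 2, fully dissociated
    osmotic_multiplier: float = NACL_OSMOTIC_MULTIPLIER
    theta_deg: float = DOPC_CONTACT_ANGLE_DEG
    dt_s: float = 1.0
    duration_s: float = 300.0
    sigma_r_um: float = 0.2
    temperature_c: float = 30.0
    geometry_mode: str = "sphere"

    def __post_init__(self):
        _require(self.sigma_r_um >= 0, "noise must be non-negative")
        _require(self.dt_s > 0 and self.duration_s > self.dt_s,
                 "time grid must be positive and span several frames")
        _require(self.r1_um > 0 and self.r2_um > 0, "radii must be positive")


def gen_trajectory(cfg: TrajectoryConfig) -> dib.TrajectoryTable:
    """Simulate an osmotic shrink/swell run and add i.i.d. Gaussian radius
    noise.  Truth parameters land in the table metadata."""
    params = dib.TransportParams(pf_um_s=cfg.pf_um_s,
                                 temperature_c=cfg.temperature_c,
                                 geometry_mode=cfg.geometry_mode)
    v2 = dib.volume_from_radius(cfg.r2_um * UM_TO_M, cfg.geometry_mode,
                                cfg.theta_deg)
    osm2 = (nacl_osmolarity_mol_m3(cfg.nacl_M, cfg.osmotic_multiplier)
            + cfg.pfas_mM)  # PFAS as a fully dissociated 1 mM = 1 mol/m^3 term
    state = dib.DropletPairState.from_radii_um(
        cfg.r1_um, cfg.r2_um, n1=0.0, n2=osm2 * v2,
        theta_deg=cfg.theta_deg, geometry_mode=cfg.geometry_mode)
    t_grid = np.arange(0.0, cfg.duration_s + 0.5 * cfg.dt_s, cfg.dt_s)
    traj = dib.simulate_pair(state, params, t_grid)
    rng = np.random.default_rng(cfg.seed)
    if cfg.sigma_r_um > 0:
        noisy = traj.data.copy()
        noisy["R1_um"] = noisy["R1_um"] + rng.normal(0, cfg.sigma_r_um,
                                                     len(noisy))
        noisy["R2_um"] = noisy["R2_um"] + rng.normal(0, cfg.sigma_r_um,
                                                     len(noisy))
        # the "measured" contact area follows the noisy small-droplet radius,
        # as image analysis of the micrographs would produce
        r_small = np.minimum(noisy["R1_um"], noisy["R2_um"])
        noisy["Ab_um2"] = (np.pi *
                           (r_small * math.sin(math.radians(cfg.theta_deg)))
                           ** 2)
        traj = dib.TrajectoryTable(data=noisy, meta=dict(traj.meta))
    traj.meta.update({
        "pf_true_um_s": cfg.pf_um_s,
        "sigma_R_um": cfg.sigma_r_um,
        "seed": cfg.seed,
    })
    return traj


# ---------------------------------------------------------------------------
# Thermograms
# ---------------------------------------------------------------------------

@dataclass
class ThermogramConfig:
    """Truth parameters for a synthetic endotherm: a sum of Gaussian
    excess-Cp components plus polynomial baseline drift plus white noise."""

    seed: int
    components: tuple = ((-16.72, 9.18, 2.27),)  # (Tm degC, area kcal/mol, fwhm degC)
    t_min_c: float = -40.0
    t_max_c: float = 0.0
    step_c: float = 0.05
    drift: tuple = (0.02, 0.001)    # polynomial coefficients (const, linear, ...)
    snr: float = 50.0               # composite peak height / noise SD; inf => none
    scan_rate_c_min: float = 5.0

    def __post_init__(self):
        _require(self.step_c > 0 and self.t_max_c > self.t_min_c,
                 "temperature grid must be increasing")
        _require(self.snr > 0, "SNR must be positive")
        for tm, area, w in self.components:
            _require(area >= 0 and w > 0, "component areas/widths invalid")
            _require(self.t_min_c < tm < self.t_max_c,
                     "component Tm outside the grid")


def gen_thermogram(cfg: ThermogramConfig, with_drift: bool = True) -> Thermogram:
    """Synthesize a thermogram; truth parameters land in metadata."""
    T = np.arange(cfg.t_min_c, cfg.t_max_c + 0.5 * cfg.step_c, cfg.step_c)
    clean = np.zeros_like(T)
    for tm, area, w in cfg.components:
        clean += gaussian_peak(T, area, tm, w)
    peak_height = float(np.max(clean)) if np.max(clean) > 0 else 1.0
    cp = clean.copy()
    if with_drift and any(c != 0 for c in cfg.drift):
        # drift coefficients are (c0, c1, ...) in kcal/mol/C per (degC)^k
        drift = np.zeros_like(T)
        for k, c in enumerate(cfg.drift):
            drift += c * T ** k
        cp = cp + drift
    rng = np.random.default_rng(cfg.seed)
    if np.isfinite(cfg.snr):
        cp = cp + rng.normal(0.0, peak_height / cfg.snr, len(T))
    meta = {"seed": cfg.seed, "snr": cfg.snr,
            "n_components_true": len(cfg.components)}
    for k, (tm, area, w) in enumerate(cfg.components):
        meta[f"tm_true_{k}"] = tm
        meta[f"area_true_{k}"] = area
        meta[f"fwhm_true_{k}"] = w
    meta["total_dh_true"] = float(sum(a for _, a, _ in cfg.components))
    return Thermogram(T_c=T, cp_excess=cp, scan_rate_c_min=cfg.scan_rate_c_min,
                      meta=meta)


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

FTIR_DEFAULT_BANDS = ((2853.0, 0.75, 20.0), (2923.1, 1.0, 24.1))
RAMAN_DEFAULT_BANDS = ((2850.0, 1.0, 14.0), (2890.0, 0.75, 18.0),
                       (2930.0, 0.60, 16.0))


@dataclass
class SpectrumConfig:
    """Truth parameters for a synthetic CH-stretch spectrum.

    ``bands`` is a tuple of (center cm^-1, height, fwhm cm^-1); the
    pseudo-Voigt Gaussian/Lorentzian mix is set by ``eta``.
    """

    seed: int
    kind: str = "ATR-FTIR"          # or "Raman"
    bands: tuple | None = None
    eta: float = 0.2
    nu_min: float = 2750.0
    nu_max: float = 3050.0
    step_cm1: float = 4.0
    snr: float = 100.0

    def __post_init__(self):
        if self.bands is None:
            self.bands = (RAMAN_DEFAULT_BANDS if self.kind == "Raman"
                          else FTIR_DEFAULT_BANDS)
        _require(self.step_cm1 > 0 and self.nu_max > self.nu_min,
                 "wavenumber grid must be increasing")
        _require(0 <= self.eta <= 1, "eta must lie in [0, 1]")
        _require(self.snr > 0, "SNR must be positive")
        for c, h, w in self.bands:
            _require(h > 0 and w > 0, "band heights/widths must be positive")


def _composite(nu, bands, eta):
    out = np.zeros_like(np.asarray(nu, dtype=float))
    for c, h, w in bands:
        out += pseudo_voigt(nu, c, h, w, eta)
    return out


def _composite_apex(bands, eta, center, halfwidth=10.0):
    """Apex of the noise-free composite model near ``center`` on a fine grid
    (the configured band heights shoulder each other, so the composite apex
    is the measurable truth)."""
    nu = np.linspace(center - halfwidth, center + halfwidth, 4001)
    y = _composite(nu, bands, eta)
    i = int(np.argmax(y))
    return float(nu[i]), float(y[i])


def gen_spectrum(cfg: SpectrumConfig) -> Spectrum:
    """Synthesize a spectrum; configured and composite (shoulder-corrected)
    truths land in metadata."""
    nu = np.arange(cfg.nu_min, cfg.nu_max + 0.5 * cfg.step_cm1, cfg.step_cm1)
    clean = _composite(nu, cfg.bands, cfg.eta)
    peak = float(np.max(clean))
    rng = np.random.default_rng(cfg.seed)
    y = clean.copy()
    if np.isfinite(cfg.snr):
        y = y + rng.normal(0.0, peak / cfg.snr, len(nu))
    meta = {"seed": cfg.seed, "snr": cfg.snr, "eta": cfg.eta}
    for k, (c, h, w) in enumerate(cfg.bands):
        meta[f"center_true_{k}"] = c
        meta[f"height_true_{k}"] = h
        meta[f"fwhm_true_{k}"] = w
        apex_pos, apex_h = _composite_apex(cfg.bands, cfg.eta, c)
        meta[f"apex_true_{k}"] = apex_pos
        meta[f"apex_height_true_{k}"] = apex_h
    return Spectrum(nu=nu, intensity=y, kind=cfg.kind,
                    resolution_cm1=cfg.step_cm1, meta=meta)


# ---------------------------------------------------------------------------
# Tension tables
# ---------------------------------------------------------------------------

@dataclass
class TensionScatterConfig:
    """Per-concentration truth (gamma_m mN/m, theta deg) with per-trial
    Gaussian scatter.  ``rows`` entries: (conc_mM, species, gamma_m, theta)."""

    seed: int
    rows: tuple = ((0.0, "none", 1.249, 28.56),)
    gamma_m_trial_sd: float = 0.02
    theta_trial_sd_deg: float = 0.5
    n_trials: int = 10

    def __post_init__(self):
        _require(self.n_trials >= 1, "need at least one trial")
        _require(self.gamma_m_trial_sd >= 0 and self.theta_trial_sd_deg >= 0,
                 "scatter must be non-negative")
        for conc, _, gm, th in self.rows:
            _require(gm > 0 and 0 <= th < 90 and conc >= 0,
                     "row truth outside domain")


def gen_tension_table(cfg: TensionScatterConfig) -> tuple[pd.DataFrame, dict]:
    """Trial-level measurements: one row per (concentration, trial).

    Returns (DataFrame with columns conc_mM, species, trial, gamma_m_mNm,
    theta_deg; metadata dict with truths).  Row means converge to the truth
    as n_trials grows.
    """
    rng = np.random.default_rng(cfg.seed)
    rows = []
    meta = {"seed": cfg.seed, "n_trials": cfg.n_trials,
            "gamma_m_trial_sd": cfg.gamma_m_trial_sd,
            "theta_trial_sd_deg": cfg.theta_trial_sd_deg}
    for k, (conc, species, gm, th) in enumerate(cfg.rows):
        meta[f"gamma_m_true_{k}"] = gm
        meta[f"theta_true_{k}"] = th
        gm_draws = gm + rng.normal(0.0, cfg.gamma_m_trial_sd, cfg.n_trials)
        th_draws = th + rng.normal(0.0, cfg.theta_trial_sd_deg, cfg.n_trials)
        for j in range(cfg.n_trials):
            rows.append((conc, species, j, gm_draws[j], th_draws[j]))
    df = pd.DataFrame(rows, columns=["conc_mM", "species", "trial",
                                     "gamma_m_mNm", "theta_deg"])
    return df, meta


def summarize_tension_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Collapse trial-level measurements to the per-concentration
    mean +/- SD layout of a printed interfacial-activity table."""
    grouped = trials.groupby(["conc_mM", "species"], sort=True)
    out = grouped.agg(
        gamma_m_mNm=("gamma_m_mNm", "mean"),
        gamma_m_sd=("gamma_m_mNm", lambda v: v.std(ddof=1) if len(v) > 1 else 0.0),
        theta_deg=("theta_deg", "mean"),
        theta_sd=("theta_deg", lambda v: v.std(ddof=1) if len(v) > 1 else 0.0),
        n_trials=("trial", "count"),
    ).reset_index()
    return out
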
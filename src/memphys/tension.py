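"""Bilayer tension from monolayer tension and contact angle.

At the three-phase line of a droplet-interface bilayer the two monolayer
tension vectors balance the bilayer tension, giving

    gamma_b = 2 * gamma_m * cos(theta)

with ``theta`` the half contact angle between the adhering droplets.  The
monolayer tension ``gamma_m`` comes from pendant-drop tensiometry and
``theta`` from imaging the droplet pair; both carry empirical standard
deviations over repeated trials, which are propagated to first order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal

import pandas as pd

from .exceptions import DomainError, SchemaError

__all__ = ["TensionRecord", "bilayer_tension", "propagate_sigma",
           "tension_table", "round_half_even", "contact_angle_from_tensions"]


@dataclass
class TensionRecord:
    """One row of an interfacial-activity table."""

    conc_mM: float
    species: str
    gamma_m: float          # mN/m
    gamma_m_sd: float
    theta_deg: float
    theta_sd_deg: float
    gamma_b: float          # mN/m, derived
    gamma_b_sd: float       # mN/m, first-order propagated
    n_trials: int | None = None


def bilayer_tension(gamma_m: float, theta_deg: float) -> float:
    """gamma_b = 2 * gamma_m * cos(theta), all tensions in mN/m."""
    if gamma_m <= 0:
        raise DomainError("monolayer tension must be positive")
    if not 0 <= theta_deg < 90:
        raise DomainError("contact angle must lie in [0, 90) degrees")
    return 2.0 * gamma_m * math.cos(math.radians(theta_deg))


def contact_angle_from_tensions(gamma_b: float, gamma_m: float) -> float:
    """Invert the tension balance: theta = arccos(gamma_b / 2 gamma_m), degrees."""
    if gamma_m <= 0:
        raise DomainError("monolayer tension must be positive")
    ratio = gamma_b / (2.0 * gamma_m)
    if not 0 < ratio <= 1:
        raise DomainError("gamma_b must lie in (0, 2*gamma_m]")
    return math.degrees(math.acos(ratio))


def propagate_sigma(gamma_m: float, gamma_m_sd: float,
                    theta_deg: float, theta_sd_deg: float) -> float:
    """First-order uncertainty of gamma_b:
    sqrt[(2 cos(theta) s_gm)^2 + (2 gamma_m sin(theta) s_theta_rad)^2].

    Note this is the analytic propagation of the component SDs; published
    tables often quote the larger empirical scatter across trials instead.
    """
    if gamma_m_sd < 0 or theta_sd_deg < 0:
        raise DomainError("standard deviations must be non-negative")
    th = math.radians(theta_deg)
    s_th = math.radians(theta_sd_deg)
    a = 2.0 * math.cos(th) * gamma_m_sd
    b = 2.0 * gamma_m * math.sin(th) * s_th
    return math.hypot(a, b)


def round_half_even(x: float, ndigits: int = 2) -> float:
    """Banker's rounding on the decimal representation, for table display."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_EVEN))


def tension_table(df: pd.DataFrame) -> pd.DataFrame:
    """Apply the tension balance row-wise to a measured table.

    Expects columns ``conc_mM, gamma_m_mNm, gamma_m_sd, theta_deg, theta_sd``
    (``species`` and others pass through).  Returns a copy with derived
    ``gamma_b_mNm`` and ``gamma_b_sd`` columns appended; input layout is
    preserved.  A malformed row raises an error naming the row.
    """
    required = ("conc_mM", "gamma_m_mNm", "gamma_m_sd", "theta_deg", "theta_sd")
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"tension table missing column '{col}'")
    out = df.copy()
    gb, gb_sd = [], []
    for idx, row in df.iterrows():
        try:
            gb.append(bilayer_tension(float(row["gamma_m_mNm"]),
                                      float(row["theta_deg"])))
            gb_sd.append(propagate_sigma(float(row["gamma_m_mNm"]),
                                         float(row["gamma_m_sd"]),
                                         float(row["theta_deg"]),
                                         float(row["theta_sd"])))
        except (DomainError, ValueError, TypeError) as exc:
            raise SchemaError(f"malformed tension table row {idx}: {exc}") from exc
    out["gamma_b_mNm"] = gb
    out["gamma_b_sd"] = gb_sd
    return out
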
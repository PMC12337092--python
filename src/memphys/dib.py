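"""Osmotic water transport across a droplet-interface bilayer (DIB).

Two aqueous microdroplets, each coated by a lipid monolayer in oil, adhere
and form a bilayer patch of area ``A_b`` at their contact zone.  When the
droplets are osmotically unbalanced, water crosses the bilayer from the
dilute droplet toward the concentrated one at a volumetric rate

    dV1/dt = -P_f * A_b * v_w * (c2 - c1),        dV2/dt = -dV1/dt

where ``c_i = n_i / V_i`` is the osmolarity of droplet *i* (the osmotically
active amount ``n_i`` is conserved — the bilayer is solute-impermeable),
``v_w`` is the molar volume of water and ``P_f`` the osmotic water
permeability coefficient of the bilayer (reported in um/s).  The droplet
diameters change measurably over minutes, and fitting the observed volume
trajectory recovers ``P_f``.

This module provides the forward model (:func:`simulate_pair`) and two
estimators: a flux/slope regression (:func:`estimate_pf_slope`) and a
full-trajectory least-squares fit (:func:`estimate_pf_ode`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from . import io as mio
from .constants import (DOPC_CONTACT_ANGLE_DEG, M3_TO_UM3, M_TO_UM, UM_TO_M,
                        UM2_TO_M2, UM3_TO_M3, WATER_MOLAR_VOLUME)
from .exceptions import (ConvergenceError, DomainError, NumericalError,
                         SchemaError, UnidentifiableError)

__all__ = [
    "DropletPairState", "TransportParams", "TrajectoryTable", "PfEstimate",
    "osmolarity", "simulate_pair", "estimate_pf_slope", "estimate_pf_ode",
    "aggregate_runs", "volume_from_radius", "radius_from_volume",
    "bilayer_area",
]

TRAJECTORY_SCHEMA = mio.TableSchema(
    required=("t_s", "R1_um", "R2_um"),
    optional=("Ab_um2",),
    monotone=("t_s",),
    positive=("R1_um", "R2_um"),
    min_rows=3,
)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def _truncation_factor(theta_deg: float) -> float:
    """Volume of a sphere truncated by the bilayer plane, as a multiple of
    R^3.  The cap removed has height h = R(1 - cos(theta)); the remaining
    volume is (pi/3) R^3 [4 - (1-cos t)^2 (2+cos t)]."""
    ct = math.cos(math.radians(theta_deg))
    return (math.pi / 3.0) * (4.0 - (1.0 - ct) ** 2 * (2.0 + ct))


def volume_from_radius(r_m: float, mode: str = "sphere",
                       theta_deg: float = DOPC_CONTACT_ANGLE_DEG) -> float:
    """Droplet volume (m^3) from its apparent radius (m)."""
    if mode == "sphere":
        return (4.0 / 3.0) * math.pi * r_m ** 3
    if mode == "truncated_sphere":
        return _truncation_factor(theta_deg) * r_m ** 3
    raise DomainError(f"unknown geometry_mode '{mode}'")


def radius_from_volume(v_m3: float, mode: str = "sphere",
                       theta_deg: float = DOPC_CONTACT_ANGLE_DEG) -> float:
    """Inverse of :func:`volume_from_radius` (m)."""
    if v_m3 <= 0:
        raise DomainError("volume must be positive")
    if mode == "sphere":
        return (3.0 * v_m3 / (4.0 * math.pi)) ** (1.0 / 3.0)
    if mode == "truncated_sphere":
        return (v_m3 / _truncation_factor(theta_deg)) ** (1.0 / 3.0)
    raise DomainError(f"unknown geometry_mode '{mode}'")


def bilayer_area(r1_m: float, r2_m: float,
                 theta_deg: float = DOPC_CONTACT_ANGLE_DEG) -> float:
    """Bilayer contact patch area (m^2): a disc of radius R_small*sin(theta)."""
    rc = min(r1_m, r2_m) * math.sin(math.radians(theta_deg))
    return math.pi * rc ** 2


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class DropletPairState:
    """Instantaneous state of two adhering droplets.

    Volumes in m^3, solute amounts in osmol (moles x van't Hoff factor x
    osmotic coefficient), contact angle in degrees (the DIB half-angle).
    """

    t: float
    v1: float
    v2: float
    n1: float
    n2: float
    theta_deg: float = DOPC_CONTACT_ANGLE_DEG

    def __post_init__(self):
        if self.v1 <= 0 or self.v2 <= 0:
            raise DomainError("droplet volumes must be positive")
        if self.n1 < 0 or self.n2 < 0:
            raise DomainError("osmole contents must be non-negative")
        if not 0 <= self.theta_deg < 90:
            raise DomainError("contact angle must lie in [0, 90) degrees")

    @classmethod
    def from_radii_um(cls, r1_um: float, r2_um: float, n1: float, n2: float,
                      theta_deg: float = DOPC_CONTACT_ANGLE_DEG,
                      geometry_mode: str = "sphere", t: float = 0.0):
        v1 = volume_from_radius(r1_um * UM_TO_M, geometry_mode, theta_deg)
        v2 = volume_from_radius(r2_um * UM_TO_M, geometry_mode, theta_deg)
        return cls(t=t, v1=v1, v2=v2, n1=n1, n2=n2, theta_deg=theta_deg)

    def bilayer_area_m2(self, geometry_mode: str = "sphere") -> float:
        r1 = radius_from_volume(self.v1, geometry_mode, self.theta_deg)
        r2 = radius_from_volume(self.v2, geometry_mode, self.theta_deg)
        return bilayer_area(r1, r2, self.theta_deg)


@dataclass
class TransportParams:
    """Parameters of the osmotic transport model.

    pf_um_s:   osmotic water permeability coefficient, um/s
    v_w:       molar volume of water, m^3/mol
    temperature_c: bath temperature (metadata only; the model itself is
               isothermal and P_f is treated as temperature-independent)
    geometry_mode: 'sphere' (default) or 'truncated_sphere' for the
               radius <-> volume mapping
    stop_volume_fraction: integration halts when either droplet falls below
               this fraction of its initial volume (a pure-water droplet
               would otherwise drain indefinitely)
    """

    pf_um_s: float = 73.0
    v_w: float = WATER_MOLAR_VOLUME
    temperature_c: float = 30.0
    geometry_mode: str = "sphere"
    stop_volume_fraction: float = 0.05
    rtol: float = 1e-8

    def __post_init__(self):
        if self.pf_um_s < 0:
            raise DomainError("P_f must be non-negative")
        if self.v_w <= 0:
            raise DomainError("molar volume of water must be positive")
        if not 0 < self.stop_volume_fraction < 1:
            raise DomainError("stop_volume_fraction must lie in (0, 1)")


@dataclass
class TrajectoryTable:
    """Time series of droplet radii and bilayer contact area.

    ``data`` columns: t_s, R1_um, R2_um and optionally Ab_um2.  ``meta``
    carries at least n1_osmol, n2_osmol, theta_deg; synthetic tables also
    record their truth parameters (pf_true_um_s, sigma_R_um, ...).
    """

    data: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.data)

    def write(self, path, sep: str = ",") -> None:
        mio.write_table(path, self.data, self.meta, sep=sep)

    @classmethod
    def read(cls, path) -> "TrajectoryTable":
        df, meta = mio.read_table(path, TRAJECTORY_SCHEMA)
        return cls(data=df, meta=meta)

    def volumes_m3(self, geometry_mode: str = "sphere"):
        theta = float(self.meta.get("theta_deg", DOPC_CONTACT_ANGLE_DEG))
        r1 = self.data["R1_um"].to_numpy(dtype=float) * UM_TO_M
        r2 = self.data["R2_um"].to_numpy(dtype=float) * UM_TO_M
        v1 = np.array([volume_from_radius(r, geometry_mode, theta) for r in r1])
        v2 = np.array([volume_from_radius(r, geometry_mode, theta) for r in r2])
        return v1, v2

    def contact_area_m2(self, geometry_mode: str = "sphere"):
        """Measured bilayer area when present, else reconstructed from the
        smaller droplet radius and the contact angle."""
        theta = float(self.meta.get("theta_deg", DOPC_CONTACT_ANGLE_DEG))
        if "Ab_um2" in self.data.columns:
            return self.data["Ab_um2"].to_numpy(dtype=float) * UM2_TO_M2
        r1 = self.data["R1_um"].to_numpy(dtype=float) * UM_TO_M
        r2 = self.data["R2_um"].to_numpy(dtype=float) * UM_TO_M
        return np.array([bilayer_area(a, b, theta) for a, b in zip(r1, r2)])


@dataclass
class PfEstimate:
    """Permeability estimate with its uncertainty (both um/s)."""

    pf_um_s: float
    stderr_um_s: float
    n_points: int
    method: str


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def osmolarity(n_osmol: float, v_m3: float) -> float:
    """Osmolarity (osmol/m^3) of a droplet holding ``n_osmol`` in ``v_m3``."""
    if v_m3 <= 0:
        raise DomainError("volume must be positive")
    return n_osmol / v_m3


def simulate_pair(initial: DropletPairState, params: TransportParams,
                  t_grid, fixed_ab_m2: float | None = None,
                  fixed_dc_osm_m3: float | None = None) -> TrajectoryTable:
    """Integrate the osmotic transport ODE on ``t_grid`` (seconds).

    Water is driven from the dilute droplet to the concentrated one:
    dV1/dt = -P_f * A_b * v_w * (c2 - c1).  Total volume and both solute
    amounts are conserved exactly (V2 is carried as V_tot - V1).

    ``fixed_ab_m2`` / ``fixed_dc_osm_m3`` freeze the contact area and the
    osmolarity difference (c2 - c1), which makes the model exactly linear —
    used to validate the integrator against the closed-form solution.

    Integration halts (table truncated) once either droplet falls below
    ``stop_volume_fraction`` of its initial volume.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or np.any(np.diff(t_grid) <= 0):
        raise DomainError("t_grid must be a 1-D strictly increasing array")

    pf = params.pf_um_s * UM_TO_M  # m/s
    v_w = params.v_w
    vtot = initial.v1 + initial.v2
    v1_floor = params.stop_volume_fraction * initial.v1
    v2_floor = params.stop_volume_fraction * initial.v2
    mode = params.geometry_mode
    theta = initial.theta_deg

    def gradient(v1):
        v2 = vtot - v1
        if fixed_dc_osm_m3 is not None:
            dc = fixed_dc_osm_m3
        else:
            dc = initial.n2 / v2 - initial.n1 / v1
        if fixed_ab_m2 is not None:
            ab = fixed_ab_m2
        else:
            r1 = radius_from_volume(v1, mode, theta)
            r2 = radius_from_volume(v2, mode, theta)
            ab = bilayer_area(r1, r2, theta)
        return ab, dc

    def rhs(t, y):
        ab, dc = gradient(y[0])
        return [-pf * ab * v_w * dc]

    def hit_floor(t, y):
        v2 = vtot - y[0]
        return min(y[0] - v1_floor, v2 - v2_floor)

    hit_floor.terminal = True
    hit_floor.direction = -1

    sol = solve_ivp(rhs, (t_grid[0], t_grid[-1]), [initial.v1],
                    t_eval=t_grid, rtol=params.rtol, atol=initial.v1 * 1e-12,
                    events=hit_floor, method="RK45")
    if sol.status == -1 or not np.all(np.isfinite(sol.y)):
        t_bad = sol.t[-1] if len(sol.t) else t_grid[0]
        raise NumericalError(f"integration failed near t={t_bad:.6g} s", t=t_bad)

    v1 = sol.y[0]
    v2 = vtot - v1
    t_out = sol.t
    rows = {
        "t_s": t_out,
        "R1_um": np.array([radius_from_volume(v, mode, theta) for v in v1]) * M_TO_UM,
        "R2_um": np.array([radius_from_volume(v, mode, theta) for v in v2]) * M_TO_UM,
    }
    if fixed_ab_m2 is not None:
        rows["Ab_um2"] = np.full_like(t_out, fixed_ab_m2 / UM2_TO_M2)
    else:
        rows["Ab_um2"] = np.array([
            bilayer_area(radius_from_volume(a, mode, theta),
                         radius_from_volume(b, mode, theta), theta)
            for a, b in zip(v1, v2)]) / UM2_TO_M2
    meta = {
        "n1_osmol": initial.n1,
        "n2_osmol": initial.n2,
        "temperature_C": params.temperature_c,
        "theta_deg": theta,
        "geometry_mode": mode,
    }
    return TrajectoryTable(data=pd.DataFrame(rows), meta=meta)


def _prepare_estimation(traj: TrajectoryTable, geometry_mode: str,
                        v_w: float, fit_fraction: float):
    if len(traj) < 3:
        raise SchemaError("trajectory must have at least 3 rows")
    if "n1_osmol" not in traj.meta or "n2_osmol" not in traj.meta:
        raise SchemaError("trajectory metadata must carry n1_osmol and n2_osmol")
    t = traj.data["t_s"].to_numpy(dtype=float)
    v1, v2 = traj.volumes_m3(geometry_mode)
    ab = traj.contact_area_m2(geometry_mode)
    n1 = float(traj.meta["n1_osmol"])
    n2 = float(traj.meta["n2_osmol"])
    dc = n2 / v2 - n1 / v1  # osmol/m^3, positive when droplet 2 is salty
    n_fit = max(3, int(math.ceil(len(t) * fit_fraction)))
    sl = slice(0, n_fit)
    return t[sl], v1[sl], v2[sl], ab[sl], dc[sl], v_w


def estimate_pf_slope(traj: TrajectoryTable, v_w: float = WATER_MOLAR_VOLUME,
                      geometry_mode: str = "sphere",
                      fit_fraction: float = 0.5) -> PfEstimate:
    """Recover P_f by regressing volume flux against the osmotic driving term.

    Per-interval dV/dt is taken by central differences (one-sided at the
    ends); both droplets contribute observations.  The regression is through
    the origin: dV1/dt = P_f * x with x = -A_b*v_w*(c2 - c1), so the slope
    is P_f.  The fit window defaults to the first half of the trajectory,
    where the quasi-constant-gradient approximation is best.
    """
    t, v1, v2, ab, dc, v_w = _prepare_estimation(
        traj, geometry_mode, v_w, fit_fraction)
    scale = float(np.max(np.abs(dc)))
    if scale == 0.0 or not np.any(np.abs(dc) > 1e-9 * max(scale, 1.0)):
        raise UnidentifiableError(
            "osmolarity difference is zero over the fitted window; "
            "P_f is unidentifiable")
    dv1 = np.gradient(v1, t)
    dv2 = np.gradient(v2, t)
    x = np.concatenate([-ab * v_w * dc, ab * v_w * dc])
    y = np.concatenate([dv1, dv2])
    sxx = float(x @ x)
    slope = float(x @ y) / sxx
    resid = y - slope * x
    dof = max(len(y) - 1, 1)
    se = math.sqrt(float(resid @ resid) / dof / sxx)
    return PfEstimate(pf_um_s=slope * M_TO_UM, stderr_um_s=se * M_TO_UM,
                      n_points=len(t), method="slope")


def estimate_pf_ode(traj: TrajectoryTable,
                    params0: TransportParams | None = None,
                    geometry_mode: str | None = None) -> PfEstimate:
    """Recover P_f by least-squares fit of the full ODE solution to the
    observed volume trajectories of both droplets."""
    params0 = params0 or TransportParams()
    if params0.pf_um_s <= 0:
        raise DomainError("initial P_f guess must be positive")
    mode = geometry_mode or params0.geometry_mode
    if len(traj) < 3:
        raise SchemaError("trajectory must have at least 3 rows")
    t = traj.data["t_s"].to_numpy(dtype=float)
    v1_obs, v2_obs = traj.volumes_m3(mode)
    n1 = float(traj.meta["n1_osmol"])
    n2 = float(traj.meta["n2_osmol"])
    theta = float(traj.meta.get("theta_deg", DOPC_CONTACT_ANGLE_DEG))
    dc0 = abs(n2 / v2_obs[0] - n1 / v1_obs[0])
    if dc0 == 0.0:
        raise UnidentifiableError("initial osmolarity difference is zero")
    v_scale = v1_obs[0]

    def residuals(p):
        prm = replace(params0, pf_um_s=float(p[0]), geometry_mode=mode)
        state = DropletPairState(t=t[0], v1=v1_obs[0], v2=v2_obs[0],
                                 n1=n1, n2=n2, theta_deg=theta)
        sim = simulate_pair(state, prm, t)
        m1, m2 = sim.volumes_m3(mode)
        if len(m1) < len(t):  # hit the stop rule before the data ends
            pad = np.full(len(t) - len(m1), m1[-1])
            m1 = np.concatenate([m1, pad])
            m2 = np.concatenate([m2, np.full(len(t) - len(m2), m2[-1])])
        return np.concatenate([(m1 - v1_obs), (m2 - v2_obs)]) / v_scale

    res = least_squares(residuals, x0=[params0.pf_um_s],
                        bounds=([0.0], [np.inf]), xtol=1e-12, ftol=1e-12)
    if not res.success:
        raise ConvergenceError("ODE permeability fit did not converge",
                               last_iterate=float(res.x[0]),
                               residual=float(res.cost))
    pf = float(res.x[0])
    m = len(res.fun)
    dof = max(m - 1, 1)
    jac = np.asarray(res.jac).ravel()
    jtj = float(jac @ jac)
    var = float(res.fun @ res.fun) / dof / jtj if jtj > 0 else float("nan")
    se = math.sqrt(var) if var == var else float("nan")
    return PfEstimate(pf_um_s=pf, stderr_um_s=1.96 * se, n_points=len(t),
                      method="ode")


def aggregate_runs(estimates) -> tuple[float, float, int]:
    """Mean, sample SD and count of per-run P_f estimates (um/s).

    With a single run the SD is undefined and reported as NaN.
    """
    arr = np.asarray(list(estimates), dtype=float)
    if arr.size == 0:
        raise DomainError("aggregate_runs needs at least one estimate")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else float("nan")
    return mean, sd, int(arr.size)
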
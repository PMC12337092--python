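"""Multi-stage analysis pipeline with reproducible, serializable reports.

A pipeline configuration names an ordered list of stages.  Each stage
generates (or loads) its input, runs the corresponding analysis and emits an
:class:`AnalysisReport` carrying the parameters used, a digest of the input
and the derived quantities with units.  The same configuration and seed
always produce byte-identical serialized reports.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import dib, dsc, io as mio, spectra, synthetic, tension
from .composition import DropletSpec, SuspensionSpec, lipid_pfas_ratio, \
    suspension_pfas_molarity
from .exceptions import MemphysError

__all__ = ["AnalysisReport", "run_pipeline", "reports_to_json",
           "reports_to_text", "demo_config"]


@dataclass
class AnalysisReport:
    """Outcome of one pipeline stage."""

    stage: str
    kind: str
    parameters: dict
    input_digest: str
    results: dict           # quantity name (with units in the key) -> value
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def _digest(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def _round_floats(obj, ndigits=10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def reports_to_json(reports) -> str:
    """Deterministic machine-readable serialization."""
    payload = [_round_floats(r.to_dict()) for r in reports]
    return json.dumps(payload, indent=2, sort_keys=True)


def reports_to_text(reports) -> str:
    """Human-readable rendering of a report list."""
    lines = []
    for r in reports:
        lines.append(f"== {r.stage} ({r.kind}) ==")
        lines.append(f"input sha256[:16]: {r.input_digest}")
        for key, value in r.results.items():
            if isinstance(value, float):
                lines.append(f"  {key}: {value:.6g}")
            else:
                lines.append(f"  {key}: {value}")
        for w in r.warnings:
            lines.append(f"  warning: {w}")
        lines.append("")
    return "\n".join(lines)


def _stage_seed(base_seed: int, index: int) -> int:
    children = np.random.SeedSequence(base_seed).spawn(index + 1)
    return int(children[index].generate_state(1)[0] % (2 ** 31))


def _run_trajectory(params: dict, seed: int) -> AnalysisReport:
    cfg = synthetic.TrajectoryConfig(seed=seed, **params.get("generator", {}))
    traj = synthetic.gen_trajectory(cfg)
    digest = _digest(mio.table_text(traj.data, traj.meta))
    method = params.get("method", "slope")
    if method == "ode":
        est = dib.estimate_pf_ode(traj)
    else:
        est = dib.estimate_pf_slope(traj)
    results = {
        "pf_um_s": est.pf_um_s,
        "pf_stderr_um_s": est.stderr_um_s,
        "pf_true_um_s": traj.meta["pf_true_um_s"],
        "n_frames": len(traj),
        "method": est.method,
    }
    return AnalysisReport(stage=params.get("name", "trajectory"),
                          kind="trajectory",
                          parameters={"seed": seed, **params},
                          input_digest=digest, results=results)


def _run_thermogram(params: dict, seed: int) -> AnalysisReport:
    cfg = synthetic.ThermogramConfig(seed=seed, **params.get("generator", {}))
    tg = synthetic.gen_thermogram(cfg)
    digest = _digest(mio.table_text(
        pd.DataFrame({"T_C": tg.T_c,
                                        "cp": tg.cp_excess}), tg.meta))
    span = tg.T_c[-1] - tg.T_c[0]
    flanks = params.get("flank_windows",
                        ((tg.T_c[0], tg.T_c[0] + 0.2 * span),
                         (tg.T_c[-1] - 0.1 * span, tg.T_c[-1])))
    flat = dsc.subtract_baseline(tg, flanks)
    results: dict = {
        "tm_C": dsc.find_tm(flat),
        "dh_kcal_mol": dsc.integrate_dh(flat),
    }
    warnings: list = []
    if params.get("components", 1) == 2:
        fit = dsc.deconvolve_two(flat)
        for i, comp in enumerate(fit.components, start=1):
            results[f"component{i}_tm_C"] = comp.tm_c
            results[f"component{i}_fraction_pct"] = comp.fraction_pct
            results[f"component{i}_fwhm_C"] = comp.fwhm_c
        results["fit_rmse"] = fit.rmse
        if fit.fallback_single:
            warnings.append("two-component fit rejected; single component used")
    else:
        results["fwhm_C"] = dsc.fwhm(flat)
    return AnalysisReport(stage=params.get("name", "thermogram"),
                          kind="thermogram",
                          parameters={"seed": seed, **params},
                          input_digest=digest, results=results,
                          warnings=warnings)


def _run_spectrum(params: dict, seed: int) -> AnalysisReport:
    cfg = synthetic.SpectrumConfig(seed=seed, **params.get("generator", {}))
    sp = synthetic.gen_spectrum(cfg)
    digest = _digest(mio.table_text(
        pd.DataFrame({"nu": sp.nu, "I": sp.intensity}),
        sp.meta))
    results: dict = {}
    if cfg.kind == "Raman":
        sp_n = spectra.normalize(sp, 2850.0)
        results["order_ratio_2930_2848"] = spectra.raman_order_ratio(sp_n)
        results["ch2_sym_apex_cm1"] = spectra.peak_position(
            sp_n, spectra.RAMAN_CH2_SYM_WINDOW)
    else:
        sp_n = spectra.normalize(sp, 2923.0)
        results["nu_as_ch2_apex_cm1"] = spectra.peak_position(
            sp_n, spectra.FTIR_NU_AS_CH2_WINDOW)
        results["nu_as_ch2_fwhm_cm1"] = spectra.band_fwhm(
            sp_n, (2890.0, 2960.0))
        results["nu_s_ch2_apex_cm1"] = spectra.peak_position(
            sp_n, spectra.FTIR_NU_S_CH2_WINDOW)
    return AnalysisReport(stage=params.get("name", "spectrum"),
                          kind="spectrum",
                          parameters={"seed": seed, **params},
                          input_digest=digest, results=results)


def _run_tension(params: dict, seed: int) -> AnalysisReport:
    gen = dict(params.get("generator", {}))
    if "rows" in gen:
        gen["rows"] = tuple(tuple(r) for r in gen["rows"])
    cfg = synthetic.TensionScatterConfig(seed=seed, **gen)
    trials, meta = synthetic.gen_tension_table(cfg)
    digest = _digest(mio.table_text(trials, meta))
    summary = synthetic.summarize_tension_trials(trials)
    table = tension.tension_table(summary)
    results: dict = {"n_rows": int(len(table))}
    for _, row in table.iterrows():
        key = f"gamma_b_mNm[{row['species']}@{row['conc_mM']}mM]"
        results[key] = tension.round_half_even(float(row["gamma_b_mNm"]), 2)
    return AnalysisReport(stage=params.get("name", "tension"),
                          kind="tension",
                          parameters={"seed": seed, **params},
                          input_digest=digest, results=results)


def _run_composition(params: dict, seed: int) -> AnalysisReport:
    droplet = DropletSpec(**params.get("droplet", {}))
    suspension = SuspensionSpec(**params.get("suspension", {}))
    results = {
        "lipid_to_pfas_ratio": lipid_pfas_ratio(droplet),
        "suspension_pfas_mM": suspension_pfas_molarity(suspension),
    }
    return AnalysisReport(stage=params.get("name", "composition"),
                          kind="composition",
                          parameters={"seed": seed, **params},
                          input_digest=_digest(json.dumps(params, sort_keys=True)),
                          results=results)


_RUNNERS = {
    "trajectory": _run_trajectory,
    "thermogram": _run_thermogram,
    "spectrum": _run_spectrum,
    "tension": _run_tension,
    "composition": _run_composition,
}


def run_pipeline(config: dict) -> list[AnalysisReport]:
    """Execute the configured stages in order.

    ``config`` = {"seed": int, "stages": [{"kind": ..., "name": ...,
    "generator": {...}, ...}, ...]}.  Stage seeds are derived
    deterministically from the top-level seed.  A stage failure halts the
    pipeline with the stage name attached.
    """
    base_seed = int(config.get("seed", 0))
    reports = []
    for i, stage in enumerate(config.get("stages", [])):
        kind = stage.get("kind")
        if kind not in _RUNNERS:
            raise MemphysError(f"stage {i}: unknown kind '{kind}'")
        seed = _stage_seed(base_seed, i)
        try:
            reports.append(_RUNNERS[kind](stage, seed))
        except MemphysError as exc:
            raise MemphysError(
                f"stage {i} ('{stage.get('name', kind)}') failed: {exc}"
            ) from exc
    return reports


def demo_config(seed: int = 1) -> dict:
    """A small configuration exercising every stage kind."""
    return {
        "seed": seed,
        "stages": [
            {"kind": "trajectory", "name": "dib-permeability",
             "generator": {"duration_s": 200.0}},
            {"kind": "thermogram", "name": "dsc-control",
             "generator": {"components": [[-16.72, 9.18, 2.27]]},
             "components": 1},
            {"kind": "thermogram", "name": "dsc-two-component",
             "generator": {"components": [list(c) for c in
                                          synthetic.CONTROL_TWO_COMPONENT_TRUTH]},
             "components": 2},
            {"kind": "spectrum", "name": "ftir-ch2",
             "generator": {"kind": "ATR-FTIR"}},
            {"kind": "spectrum", "name": "raman-order",
             "generator": {"kind": "Raman"}},
            {"kind": "tension", "name": "tension-control",
             "generator": {"rows": [[0.0, "none", 1.249, 28.56],
                                    [2.0, "PFOA", 0.299, 36.73]]}},
            {"kind": "composition", "name": "stoichiometry"},
        ],
    }
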
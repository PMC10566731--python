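"""Flow-through tank analysis (residence-time x irradiance experiment).

Each record is one tank at one light step: inflow and outflow pH/TA/DO
measured at steady state. Deltas are outflow minus inflow (uptake-positive
for DIC), *not* biomass-normalised — the same kelp biomass was used in every
tank — and feed directly into per-tank P-I curve fits whose parameters are
then summarised per treatment (scenario x flow) as mean +/- SE, the form in
which treatments are compared with Welch tests and consumed by the
amelioration predictor.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .carbonate import (
    InfeasibleStateError,
    solve_from_pH_TA,
    umol_per_kg_to_umol_per_l,
)
from .constants import SeawaterConditions
from .light import LightCurveModel, welch_from_summary

__all__ = [
    "compute_tank_deltas",
    "fit_tank_curves",
    "summarize_treatments",
    "compare_flows",
]

_REQUIRED = [
    "tank_id", "scenario", "flow_l_min", "light_pct", "light_umol_m2_s",
    "ph_in", "ph_out", "ta_in", "ta_out", "do_in", "do_out",
    "temp_c", "sal", "biomass_fw", "volume_l",
]

DELTA_VARS = ("d_do", "d_dic", "d_ph", "d_omega")


def compute_tank_deltas(tanks: pd.DataFrame) -> pd.DataFrame:
    """Outflow-minus-inflow deltas per tank x light step.

    DIC/Omega at both ends come from the carbonate solver; DIC delta is
    reported volumetric (µmol/L) and uptake-positive (inflow minus outflow).
    """
    missing = [c for c in _REQUIRED if c not in tanks.columns]
    if missing:
        raise ValueError(f"tank table missing columns: {missing}")
    rows = []
    for rec in tanks.itertuples(index=False):
        cond = SeawaterConditions(rec.temp_c, rec.sal)
        try:
            s_in = solve_from_pH_TA(rec.ph_in, rec.ta_in, cond)
            s_out = solve_from_pH_TA(rec.ph_out, rec.ta_out, cond)
        except (InfeasibleStateError, ValueError) as exc:
            raise InfeasibleStateError(
                f"tank {rec.tank_id} @ {rec.light_pct}% light: {exc}") from exc
        rows.append({
            "tank_id": rec.tank_id,
            "scenario": rec.scenario,
            "flow_l_min": rec.flow_l_min,
            "is_control": bool(getattr(rec, "is_control", False)),
            "light_pct": rec.light_pct,
            "light_umol_m2_s": rec.light_umol_m2_s,
            "d_do": rec.do_out - rec.do_in,
            "d_dic": umol_per_kg_to_umol_per_l(s_in.dic - s_out.dic),
            "d_ph": rec.ph_out - rec.ph_in,
            "d_omega": s_out.omega_ar - s_in.omega_ar,
            "biomass_fw": rec.biomass_fw,
            "volume_l": rec.volume_l,
        })
    return pd.DataFrame(rows)


def fit_tank_curves(deltas: pd.DataFrame, variable: str,
                    include_controls: bool = False, **fit_options) -> pd.DataFrame:
    """One P-I fit per tank for the chosen delta variable.

    Returns a table with one row per tank: treatment labels, Pmax, alpha,
    Ek, RSS and convergence flag. Control tanks (no kelp) are excluded by
    default; their flat response makes the fit degenerate by design.
    """
    if variable not in DELTA_VARS:
        raise ValueError(f"variable must be one of {DELTA_VARS}")
    data = deltas if include_controls else deltas[~deltas["is_control"]]
    rows = []
    for (tank, scen, flow), g in data.groupby(["tank_id", "scenario", "flow_l_min"]):
        resp = g[variable].to_numpy()
        fit = LightCurveModel(g["light_umol_m2_s"].to_numpy(),
                              resp, **fit_options).fit()
        # A curve that never approaches saturation leaves Pmax on an
        # unbounded ridge; a fitted Pmax beyond twice the largest observed
        # response marks such an unidentified fit as failed.
        runaway = fit.p_max > 2.0 * float(np.max(np.abs(resp)))
        rows.append({
            "tank_id": tank, "scenario": scen, "flow_l_min": flow,
            "variable": variable, "p_max": fit.p_max, "alpha": fit.alpha,
            "e_k": fit.e_k, "rss": fit.rss,
            "converged": fit.converged and not runaway,
            "runaway": runaway,
        })
    return pd.DataFrame(rows)


def summarize_treatments(tank_fits: pd.DataFrame,
                         drop_failed: bool = True) -> pd.DataFrame:
    """Treatment-level mean and SE of Pmax, alpha, Ek over replicate tanks.

    Failed (non-converged or runaway) fits are excluded by default and the
    per-treatment ``n`` reports the fits actually used.
    """
    if drop_failed and "converged" in tank_fits.columns:
        tank_fits = tank_fits[tank_fits["converged"]]
    out = []
    for (scen, flow), g in tank_fits.groupby(["scenario", "flow_l_min"]):
        n = len(g)
        row = {"scenario": scen, "flow_l_min": flow, "n": n}
        for par in ("p_max", "alpha", "e_k"):
            row[f"{par}_mean"] = g[par].mean()
            row[f"{par}_se"] = g[par].std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
        out.append(row)
    return pd.DataFrame(out)


def compare_flows(summary: pd.DataFrame, scenario: str,
                  parameter: str = "p_max") -> "pd.Series":
    """Welch comparison of a fitted parameter between the two flow levels
    within one scenario, from the treatment summary table."""
    g = summary[summary["scenario"] == scenario].sort_values("flow_l_min")
    if len(g) != 2:
        raise ValueError(f"expected exactly 2 flow levels for scenario {scenario!r}")
    lo, hi = g.iloc[0], g.iloc[1]
    w = welch_from_summary(lo[f"{parameter}_mean"], lo[f"{parameter}_se"], int(lo["n"]),
                           hi[f"{parameter}_mean"], hi[f"{parameter}_se"], int(hi["n"]))
    return pd.Series({"scenario": scenario, "parameter": parameter,
                      "t": w.t, "df": w.df, "p_value": w.p_value})
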
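"""Predictive model of macrophyte amelioration of seawater acidity.

Scales the flow-through tank results to arbitrary kelp stands: given mean
P-I parameters per treatment (scenario x flow), the per-biomass-density
rate of DO release or DIC uptake at irradiance E and water volume flow f is

    rate(E, f) = P(E; Pmax_f, alpha_f) * v / B        [µmol L-1 per (g FW / L)]

evaluated exactly at the two fitted flow endpoints (0.5 and 1.4 L/min) and
interpolated linearly in flow between them (the experiment's assumption of a
linear residence-time relationship). Multiplying by a stand's biomass
density B/V gives the bulk water-chemistry change, and a DIC change is
translated into pH and Omega by removing it from a background water parcel
at constant alkalinity through the carbonate solver.

Treatment parameters default to the flow-through experiment's fitted means
(see ``TABLE_FITS`` below) with ~150 g FW kelp in ~30 L tanks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .carbonate import (
    CarbonateSystem,
    solve_from_DIC_TA,
    umol_per_l_to_umol_per_kg,
)
from .constants import SeawaterConditions
from .light import jassby_platt

__all__ = [
    "CurveParams",
    "TreatmentFits",
    "default_treatment_fits",
    "per_density_rate",
    "predict_bulk_change",
    "apply_to_background",
    "fw_to_dw",
    "dw_to_fw",
    "amelioration_threshold",
    "surface_grid",
    "residence_time_min",
]

FLOW_LOW = 0.5   # L/min, 60 min residence in 30 L
FLOW_HIGH = 1.4  # L/min, ~21 min residence in 30 L

_FW_DW_SLOPE = 0.1187
_FW_DW_INTERCEPT = -0.0086


@dataclass(frozen=True)
class CurveParams:
    """Treatment-mean P-I parameters (Pmax in µmol/L of tank delta;
    alpha in µmol/L per µmol photons m-2 s-1)."""

    p_max: float
    alpha: float

    def __post_init__(self):
        if self.p_max <= 0 or self.alpha <= 0:
            raise ValueError("p_max and alpha must be positive")


#: Treatment-mean fitted parameters of the flow-through experiment
#: (DO release and DIC uptake, µmol/L tank delta), keyed
#: (scenario, flow L/min, variable).
TABLE_FITS: dict[tuple[str, float, str], CurveParams] = {
    ("ambient", FLOW_LOW, "DO"): CurveParams(32.44, 0.16),
    ("ambient", FLOW_HIGH, "DO"): CurveParams(20.54, 0.10),
    ("future", FLOW_LOW, "DO"): CurveParams(42.59, 0.23),
    ("future", FLOW_HIGH, "DO"): CurveParams(22.56, 0.15),
    ("ambient", FLOW_LOW, "DIC"): CurveParams(19.15, 0.16),
    ("ambient", FLOW_HIGH, "DIC"): CurveParams(7.32, 0.08),
    ("future", FLOW_LOW, "DIC"): CurveParams(25.79, 0.17),
    ("future", FLOW_HIGH, "DIC"): CurveParams(22.89, 0.14),
}


@dataclass
class TreatmentFits:
    """P-I parameters per (scenario, flow, variable) plus the tank biomass
    and volume those fits refer to.

    Both flow endpoints must be present for every (scenario, variable) pair
    that is queried; ``biomass_fw`` (g) and ``volume_l`` (L) set the tank
    biomass density that the per-density normalisation divides out.
    """

    fits: dict[tuple[str, float, str], CurveParams] = field(
        default_factory=lambda: dict(TABLE_FITS))
    biomass_fw: float = 150.0
    volume_l: float = 30.0

    def __post_init__(self):
        if self.biomass_fw <= 0 or self.volume_l <= 0:
            raise ValueError("biomass_fw and volume_l must be positive")

    def get(self, scenario: str, flow: float, variable: str) -> CurveParams:
        try:
            return self.fits[(scenario, float(flow), variable)]
        except KeyError:
            raise KeyError(
                f"no fitted parameters for ({scenario!r}, flow={flow}, {variable!r})"
            ) from None

    def endpoints(self, scenario: str, variable: str) -> tuple[CurveParams, CurveParams]:
        return (self.get(scenario, FLOW_LOW, variable),
                self.get(scenario, FLOW_HIGH, variable))

    @property
    def density(self) -> float:
        """Tank biomass density, g FW per L."""
        return self.biomass_fw / self.volume_l

    # -- plain-text round trip -------------------------------------------
    def to_yaml(self, path) -> None:
        doc = {
            "biomass_fw": self.biomass_fw,
            "volume_l": self.volume_l,
            "fits": [
                {"scenario": s, "flow_l_min": f, "variable": v,
                 "p_max": cp.p_max, "alpha": cp.alpha}
                for (s, f, v), cp in sorted(self.fits.items())
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "TreatmentFits":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        fits = {
            (e["scenario"], float(e["flow_l_min"]), e["variable"]):
                CurveParams(e["p_max"], e["alpha"])
            for e in doc["fits"]
        }
        return cls(fits=fits, biomass_fw=doc["biomass_fw"], volume_l=doc["volume_l"])

    @classmethod
    def from_treatment_summary(cls, summary: pd.DataFrame, variable: str,
                               biomass_fw: float = 150.0,
                               volume_l: float = 30.0) -> "TreatmentFits":
        """Build from a ``tanks.summarize_treatments`` table (one variable)."""
        fits = {}
        for row in summary.itertuples(index=False):
            fits[(row.scenario, float(row.flow_l_min), variable)] = CurveParams(
                row.p_max_mean, row.alpha_mean)
        return cls(fits=fits, biomass_fw=biomass_fw, volume_l=volume_l)


def default_treatment_fits() -> TreatmentFits:
    """The flow-through experiment's treatment-mean parameters (DO and DIC)."""
    return TreatmentFits()


def _clamp_flow(flow: float, strict: bool) -> float:
    if FLOW_LOW <= flow <= FLOW_HIGH:
        return flow
    if strict:
        raise ValueError(
            f"flow {flow} L/min outside fitted range [{FLOW_LOW}, {FLOW_HIGH}]")
    warnings.warn(
        f"flow {flow} L/min outside fitted range [{FLOW_LOW}, {FLOW_HIGH}]; "
        "clamping to the nearest endpoint", RuntimeWarning, stacklevel=3)
    return min(max(flow, FLOW_LOW), FLOW_HIGH)


def per_density_rate(E: float, flow: float, scenario: str, variable: str,
                     fits: TreatmentFits | None = None, *,
                     dark_offset: float = 0.0,
                     strict: bool = False) -> float:
    """Per-biomass-density delta rate, µmol L-1 per (g FW / L).

    Evaluates the treatment P-I curve at both flow endpoints, normalises each
    by the tank biomass density, subtracts ``dark_offset`` (a tank-scale
    respiration term, µmol/L, default 0), and interpolates linearly in flow.
    At an endpoint flow the result equals that endpoint's curve exactly.
    Flows outside the fitted range are clamped with a warning, or rejected
    when ``strict``.
    """
    if E < 0:
        raise ValueError("irradiance must be non-negative")
    fits = fits if fits is not None else default_treatment_fits()
    flow = _clamp_flow(flow, strict)
    lo, hi = fits.endpoints(scenario, variable)
    r_lo = (jassby_platt(E, lo.p_max, lo.alpha) - dark_offset) / fits.density
    r_hi = (jassby_platt(E, hi.p_max, hi.alpha) - dark_offset) / fits.density
    w = (flow - FLOW_LOW) / (FLOW_HIGH - FLOW_LOW)
    return float((1.0 - w) * r_lo + w * r_hi)


def predict_bulk_change(rate: float, biomass_fw: float, volume_l: float) -> float:
    """Bulk water-chemistry change, µmol/L: rate x biomass density.

    ``rate`` is a per-density rate (µmol L-1 per g FW/L); ``biomass_fw`` in
    grams, ``volume_l`` in litres (convert m3/kg upstream: 1 m3 = 1000 L,
    1 kg = 1000 g — the ratio is unchanged).
    """
    if biomass_fw < 0:
        raise ValueError("biomass must be non-negative")
    if volume_l <= 0:
        raise ValueError("volume must be positive")
    return rate * (biomass_fw / volume_l)


def apply_to_background(bulk_ddic: float, dic: float, ta: float,
                        sal: float, temp_c: float,
                        ) -> tuple[CarbonateSystem, CarbonateSystem]:
    """Remove a bulk DIC change from a background water parcel.

    ``bulk_ddic`` is a volumetric uptake (µmol/L, positive = removal),
    converted to µmol/kg with the fixed 1.024 kg/L factor and subtracted
    from the background DIC at constant alkalinity (photosynthetic CO2
    removal does not change TA). Returns the solved (before, after) states;
    pH and Omega changes are read off them.
    """
    cond = SeawaterConditions(temp_c, sal)
    before = solve_from_DIC_TA(dic, ta, cond)
    after = solve_from_DIC_TA(dic - umol_per_l_to_umol_per_kg(bulk_ddic), ta, cond)
    return before, after


def fw_to_dw(fw: float) -> float:
    """Fresh weight to dry weight, g: 0.1187*FW - 0.0086, floored at 0."""
    if fw < 0:
        raise ValueError("fresh weight must be non-negative")
    return max(_FW_DW_SLOPE * fw + _FW_DW_INTERCEPT, 0.0)


def dw_to_fw(dw: float) -> float:
    """Inverse of :func:`fw_to_dw` above the floor."""
    if dw < 0:
        raise ValueError("dry weight must be non-negative")
    return (dw - _FW_DW_INTERCEPT) / _FW_DW_SLOPE


def amelioration_threshold(fits: TreatmentFits, flow: float, scenario: str,
                           variable: str, dark_offset: float,
                           strict: bool = False) -> float:
    """Smallest irradiance at which the net (dark-corrected) rate is >= 0.

    ``dark_offset`` is the tank-scale dark respiration/uptake magnitude in
    µmol/L; it must be smaller than the interpolated Pmax or the curve never
    ameliorates. Found by bisection on E to 1e-3 µmol photons m-2 s-1.
    """
    if dark_offset < 0:
        raise ValueError("dark_offset must be non-negative")
    if dark_offset == 0.0:
        return 0.0
    fits = fits if fits is not None else default_treatment_fits()
    flow = _clamp_flow(flow, strict)
    lo, hi = fits.endpoints(scenario, variable)
    w = (flow - FLOW_LOW) / (FLOW_HIGH - FLOW_LOW)
    pmax_interp = (1.0 - w) * lo.p_max + w * hi.p_max
    if dark_offset >= pmax_interp:
        raise ValueError(
            f"dark offset {dark_offset} >= interpolated Pmax {pmax_interp:.3f}: "
            "the curve never ameliorates")

    def net(E: float) -> float:
        return per_density_rate(E, flow, scenario, variable, fits,
                                dark_offset=dark_offset)

    e_hi = 1.0
    while net(e_hi) < 0:
        e_hi *= 2.0
        if e_hi > 1e7:  # unreachable given dark < Pmax, defensive
            raise ValueError("failed to bracket the amelioration threshold")
    e_lo = 0.0
    while e_hi - e_lo > 1e-3:
        mid = 0.5 * (e_lo + e_hi)
        if net(mid) >= 0:
            e_hi = mid
        else:
            e_lo = mid
    return e_hi


def surface_grid(fits: TreatmentFits, scenario: str, variable: str,
                 E_grid, flow_grid, dark_offset: float = 0.0) -> pd.DataFrame:
    """Dense per-density-rate table over irradiance x flow, for export or
    contour plotting (monotone nondecreasing in E along every flow row)."""
    rows = []
    for f in np.asarray(flow_grid, dtype=float):
        for E in np.asarray(E_grid, dtype=float):
            rows.append({
                "scenario": scenario, "variable": variable,
                "flow_l_min": float(f), "irradiance": float(E),
                "rate": per_density_rate(float(E), float(f), scenario,
                                         variable, fits,
                                         dark_offset=dark_offset),
            })
    return pd.DataFrame(rows)


def residence_time_min(flow_l_min: float, volume_l: float = 30.0) -> float:
    """Mean residence time (min) of a tank: volume / flow. Labelled
    conversion only — flow, not residence time, is the interpolation axis."""
    if flow_l_min <= 0:
        raise ValueError("flow must be positive")
    return volume_l / flow_l_min
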
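"""Surface seawater CO2-system solver on the total pH scale.

Solves the full carbonate state of a water parcel from measured pairs —
(pH, total alkalinity), (DIC, total alkalinity) or (pCO2, total alkalinity) —
returning DIC speciation, pCO2 and the aragonite saturation state Omega.

The alkalinity model is

    TA = [HCO3-] + 2[CO3--] + [B(OH)4-] + [OH-] - [H+]_free - [HSO4-] - [HF]

i.e. the carbonate, borate and water contributions that the chamber and tank
experiments actually constrain; phosphate, silicate and ammonia terms are
omitted (those nutrients were not measured) and no pressure or air-sea
exchange corrections are applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

from .constants import (
    SEAWATER_KG_PER_L,
    EquilibriumConstants,
    SeawaterConditions,
    compute_constants,
)

__all__ = [
    "CarbonateSystem",
    "InfeasibleStateError",
    "solve_from_pH_TA",
    "solve_from_DIC_TA",
    "solve_from_pCO2_TA",
    "speciate",
    "umol_per_l_to_umol_per_kg",
    "umol_per_kg_to_umol_per_l",
]

_PH_LO, _PH_HI = 3.0, 12.0
_PH_TOL = 1e-12  # root-finder tolerance, pH units


class InfeasibleStateError(ValueError):
    """The requested (pH/DIC/pCO2, TA) pair has no physical solution."""


@dataclass(frozen=True)
class CarbonateSystem:
    """Complete carbonate state of one water parcel.

    Concentrations are gravimetric (µmol kg-1); ``pco2`` and ``fco2`` are in
    µatm; ``omega_ar`` is the aragonite saturation state. By construction
    ``dic == co2_aq + hco3 + co3`` and the alkalinity components reconstruct
    ``ta`` to well under 1e-3 µmol kg-1.
    """

    ph_total: float
    ta: float
    dic: float
    pco2: float
    fco2: float
    co2_aq: float
    hco3: float
    co3: float
    omega_ar: float
    conditions: SeawaterConditions

    def ta_residual(self, consts: EquilibriumConstants | None = None) -> float:
        """Reconstructed-minus-stored TA, µmol kg-1 (diagnostic)."""
        k = consts if consts is not None else compute_constants(self.conditions)
        return _total_alkalinity(10.0 ** -self.ph_total, self.dic * 1e-6, k) * 1e6 - self.ta


def umol_per_l_to_umol_per_kg(x: float) -> float:
    """Volumetric to gravimetric concentration via the fixed 1.024 kg/L factor."""
    return x / SEAWATER_KG_PER_L


def umol_per_kg_to_umol_per_l(x: float) -> float:
    """Gravimetric to volumetric concentration via the fixed 1.024 kg/L factor."""
    return x * SEAWATER_KG_PER_L


def _carbonate_fractions(h: float, k: EquilibriumConstants) -> tuple[float, float, float]:
    """Mole fractions of (CO2*, HCO3-, CO3--) at total-scale [H+] = h."""
    denom = h * h + k.K1 * h + k.K1 * k.K2
    return h * h / denom, k.K1 * h / denom, k.K1 * k.K2 / denom


def _noncarbonate_alkalinity(h: float, k: EquilibriumConstants) -> float:
    """Borate + hydroxide - free H+ - bisulfate - HF, mol kg-1."""
    h_free = h / k.free_to_total
    b_alk = k.BT * k.KB / (k.KB + h)
    oh = k.KW / h
    hso4 = k.ST * h_free / (k.KS + h_free)
    hf = k.FT * h_free / (k.KF_free + h_free)
    return b_alk + oh - h_free - hso4 - hf


def _total_alkalinity(h: float, dic: float, k: EquilibriumConstants) -> float:
    """TA (mol kg-1) at total-scale [H+] = h and the given DIC (mol kg-1)."""
    _, f_hco3, f_co3 = _carbonate_fractions(h, k)
    return dic * (f_hco3 + 2.0 * f_co3) + _noncarbonate_alkalinity(h, k)


def _assemble(ph: float, dic_mol: float, ta_umol: float,
              k: EquilibriumConstants) -> CarbonateSystem:
    h = 10.0 ** -ph
    f_co2, f_hco3, f_co3 = _carbonate_fractions(h, k)
    co2_aq = dic_mol * f_co2
    hco3 = dic_mol * f_hco3
    co3 = dic_mol * f_co3
    fco2 = co2_aq / k.K0 * 1e6  # µatm
    pco2 = fco2 / k.fugacity_factor
    omega = k.Ca * co3 / k.KspAr
    if omega <= 0.0:
        raise InfeasibleStateError("non-positive aragonite saturation state")
    return CarbonateSystem(
        ph_total=ph,
        ta=ta_umol,
        dic=dic_mol * 1e6,
        pco2=pco2,
        fco2=fco2,
        co2_aq=co2_aq * 1e6,
        hco3=hco3 * 1e6,
        co3=co3 * 1e6,
        omega_ar=omega,
        conditions=k.conditions,
    )


def _validate_ta(ta: float) -> None:
    if not (0.0 < ta <= 5000.0):
        raise ValueError(f"TA {ta!r} µmol/kg outside supported range (0, 5000]")


def solve_from_pH_TA(ph_total: float, ta: float,
                     cond: SeawaterConditions) -> CarbonateSystem:
    """Solve the carbonate system from measured pH (total scale) and TA (µmol/kg).

    Direct algebraic solution: the non-carbonate alkalinity terms are
    subtracted from TA to obtain carbonate alkalinity, which together with
    [H+] fixes DIC and its speciation.

    Raises
    ------
    InfeasibleStateError
        If the carbonate alkalinity is non-positive after subtracting the
        borate/water/acid terms (no physical DIC exists).
    """
    if not (_PH_LO <= ph_total <= _PH_HI):
        raise ValueError(f"pH {ph_total!r} outside supported range [3, 12]")
    _validate_ta(ta)
    k = compute_constants(cond)
    h = 10.0 ** -ph_total
    carb_alk = ta * 1e-6 - _noncarbonate_alkalinity(h, k)
    if carb_alk <= 0.0:
        raise InfeasibleStateError(
            f"carbonate alkalinity <= 0 at pH={ph_total}, TA={ta} µmol/kg"
        )
    _, f_hco3, f_co3 = _carbonate_fractions(h, k)
    dic_mol = carb_alk / (f_hco3 + 2.0 * f_co3)
    return _assemble(ph_total, dic_mol, ta, k)


def solve_from_DIC_TA(dic: float, ta: float,
                      cond: SeawaterConditions) -> CarbonateSystem:
    """Solve the carbonate system from DIC and TA (both µmol/kg).

    pH is found by bracketed root-finding of the alkalinity residual on
    pH in [3, 12]; the bracket is never silently clamped.
    """
    if not (0.0 < dic <= 5000.0):
        raise ValueError(f"DIC {dic!r} µmol/kg outside supported range (0, 5000]")
    _validate_ta(ta)
    k = compute_constants(cond)
    dic_mol = dic * 1e-6
    ta_mol = ta * 1e-6

    def residual(ph: float) -> float:
        return _total_alkalinity(10.0 ** -ph, dic_mol, k) - ta_mol

    lo, hi = residual(_PH_LO), residual(_PH_HI)
    if lo * hi > 0.0:
        raise InfeasibleStateError(
            f"no pH in [3, 12] satisfies DIC={dic}, TA={ta} µmol/kg"
        )
    ph = brentq(residual, _PH_LO, _PH_HI, xtol=_PH_TOL)
    return _assemble(ph, dic_mol, ta, k)


def solve_from_pCO2_TA(pco2: float, ta: float,
                       cond: SeawaterConditions) -> CarbonateSystem:
    """Solve the carbonate system from pCO2 (µatm) and TA (µmol/kg).

    Used to construct treatment inflow/initial states at a target CO2 level;
    pH is root-found so that the solved state reproduces the requested pCO2.
    """
    if pco2 <= 0.0:
        raise ValueError("pCO2 must be positive")
    _validate_ta(ta)
    k = compute_constants(cond)
    co2_mol = pco2 * k.fugacity_factor * k.K0 * 1e-6  # mol/kg of CO2*
    ta_mol = ta * 1e-6

    def residual(ph: float) -> float:
        h = 10.0 ** -ph
        # DIC implied by [CO2*] at this pH
        dic_mol = co2_mol * (h * h + k.K1 * h + k.K1 * k.K2) / (h * h)
        return _total_alkalinity(h, dic_mol, k) - ta_mol

    lo, hi = residual(_PH_LO), residual(_PH_HI)
    if lo * hi > 0.0:
        raise InfeasibleStateError(
            f"no pH in [3, 12] satisfies pCO2={pco2}, TA={ta}"
        )
    ph = brentq(residual, _PH_LO, _PH_HI, xtol=_PH_TOL)
    h = 10.0 ** -ph
    dic_mol = co2_mol * (h * h + k.K1 * h + k.K1 * k.K2) / (h * h)
    return _assemble(ph, dic_mol, ta, k)


def speciate(ph_total: float, dic: float,
             consts: EquilibriumConstants) -> tuple[float, float, float]:
    """Split DIC (µmol/kg) into (CO2*, HCO3-, CO3--) at the given total-scale pH.

    The three components sum to DIC exactly; their mole fractions sum to 1.
    """
    if dic <= 0.0:
        raise ValueError("DIC must be positive")
    if not (_PH_LO <= ph_total <= _PH_HI):
        raise ValueError(f"pH {ph_total!r} outside supported range [3, 12]")
    f_co2, f_hco3, f_co3 = _carbonate_fractions(10.0 ** -ph_total, consts)
    co2 = dic * f_co2
    co3 = dic * f_co3
    return co2, dic - co2 - co3, co3
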
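"""Equilibrium constants of the seawater CO2 system on the total pH scale.

The stoichiometric dissociation and solubility constants are evaluated from
temperature (deg C) and practical salinity at surface pressure, using one fixed
set of formulations:

* K1, K2 — Lueker, Dickson & Keeling (2000), total scale
* KB     — Dickson (1990b), total scale
* KW     — Millero (1995)
* KS     — Dickson (1990a), free scale
* KF     — Perez & Fraga (1987), total scale
* K0     — Weiss (1974) CO2 solubility
* KspAr  — Mucci (1983) aragonite solubility product
* totals — boron Uppstroem (1974), sulfate Morris & Riley (1966),
  fluoride Riley (1965), calcium Riley & Tongudai (1967), all salinity-scaled

This is the default constant set of the seacarb/CO2SYS family for total-scale
work and is frozen here so that every solve in the package is reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "SeawaterConditions",
    "EquilibriumConstants",
    "compute_constants",
]

#: Mean density used for the volumetric <-> gravimetric conversion, kg per L.
SEAWATER_KG_PER_L = 1.024

_R_GAS = 83.14462618  # cm3 bar K-1 mol-1, for the CO2 fugacity virial correction
_P_ATM_BAR = 1.01325


@dataclass(frozen=True)
class SeawaterConditions:
    """Physical state of a surface water parcel.

    Parameters
    ----------
    temperature : float
        In-situ temperature, degrees Celsius. Valid range [-2, 40].
    salinity : float
        Practical salinity (dimensionless). Valid range [0, 45].
    pressure : float
        Hydrostatic pressure in decibar; only surface pressure (0) is
        supported — the experiments this package models are run in
        tanks and chambers at the surface.
    """

    temperature: float
    salinity: float
    pressure: float = 0.0

    def __post_init__(self) -> None:
        if not (-2.0 <= self.temperature <= 40.0):
            raise ValueError(
                f"temperature {self.temperature!r} degC outside supported range [-2, 40]"
            )
        if not (0.0 <= self.salinity <= 45.0):
            raise ValueError(
                f"salinity {self.salinity!r} outside supported range [0, 45]"
            )
        if self.pressure != 0.0:
            raise ValueError("pressure must be 0 dbar (surface only)")


@dataclass(frozen=True)
class EquilibriumConstants:
    """Stoichiometric constants and element totals at one (T, S).

    All constants are in mol/kg-solution units (K0 in mol kg-1 atm-1,
    KW and KspAr in mol2 kg-2); acid-base constants are on the total pH
    scale except ``KS`` and ``KF_free`` which are on the free scale, as
    they define the free/total conversion itself.
    """

    K0: float
    K1: float
    K2: float
    KB: float
    KW: float
    KS: float
    KF: float
    KspAr: float
    BT: float
    ST: float
    FT: float
    Ca: float
    fugacity_factor: float
    conditions: SeawaterConditions

    def __post_init__(self) -> None:
        for name in ("K0", "K1", "K2", "KB", "KW", "KS", "KF", "KspAr",
                     "BT", "ST", "FT", "Ca"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"constant {name} must be strictly positive")
        if self.K1 <= self.K2:
            raise ValueError("K1 must exceed K2")

    @property
    def free_to_total(self) -> float:
        """Factor converting free-scale [H+] to total-scale: 1 + ST/KS."""
        return 1.0 + self.ST / self.KS

    @property
    def KF_free(self) -> float:
        """HF dissociation constant re-expressed on the free scale."""
        return self.KF / self.free_to_total


def compute_constants(cond: SeawaterConditions) -> EquilibriumConstants:
    """Evaluate the frozen constant set at the given temperature and salinity.

    Deterministic; raises ``ValueError`` (via ``SeawaterConditions``) for
    out-of-range inputs.
    """
    T = cond.temperature + 273.15
    S = cond.salinity
    lnT = math.log(T)
    sqS = math.sqrt(S)

    # CO2 solubility, Weiss (1974), mol kg-1 atm-1 (fugacity form)
    lnK0 = (
        -60.2409
        + 93.4517 * (100.0 / T)
        + 23.3585 * math.log(T / 100.0)
        + S * (0.023517 - 0.023656 * (T / 100.0) + 0.0047036 * (T / 100.0) ** 2)
    )
    K0 = math.exp(lnK0)

    # Carbonic acid, Lueker et al. (2000), total scale
    pK1 = 3633.86 / T - 61.2172 + 9.6777 * lnT - 0.011555 * S + 0.0001152 * S * S
    pK2 = 471.78 / T + 25.929 - 3.16967 * lnT - 0.01781 * S + 0.0001122 * S * S
    K1 = 10.0 ** (-pK1)
    K2 = 10.0 ** (-pK2)

    # Boric acid, Dickson (1990b), total scale
    lnKB = (
        (-8966.90 - 2890.53 * sqS - 77.942 * S + 1.728 * S * sqS - 0.0996 * S * S) / T
        + 148.0248
        + 137.1942 * sqS
        + 1.62142 * S
        + (-24.4344 - 25.085 * sqS - 0.2474 * S) * lnT
        + 0.053105 * sqS * T
    )
    KB = math.exp(lnKB)

    # Water, Millero (1995)
    lnKW = (
        148.9802
        - 13847.26 / T
        - 23.6521 * lnT
        + (118.67 / T - 5.977 + 1.0495 * lnT) * sqS
        - 0.01615 * S
    )
    KW = math.exp(lnKW)

    # Bisulfate, Dickson (1990a), free scale; ionic strength of seawater
    I = 19.924 * S / (1000.0 - 1.005 * S)
    sqI = math.sqrt(I)
    lnKS = (
        -4276.1 / T
        + 141.328
        - 23.093 * lnT
        + (-13856.0 / T + 324.57 - 47.986 * lnT) * sqI
        + (35474.0 / T - 771.54 + 114.723 * lnT) * I
        - 2698.0 / T * I * sqI
        + 1776.0 / T * I * I
        + math.log(1.0 - 0.001005 * S)
    )
    KS = math.exp(lnKS)

    # Hydrogen fluoride, Perez & Fraga (1987), total scale
    KF = math.exp(874.0 / T - 9.68 + 0.111 * sqS)

    # Aragonite solubility product, Mucci (1983)
    log10KspAr = (
        -171.945
        - 0.077993 * T
        + 2903.293 / T
        + 71.595 * math.log10(T)
        + (-0.068393 + 0.0017276 * T + 88.135 / T) * sqS
        - 0.10018 * S
        + 0.0059415 * S * sqS
    )
    KspAr = 10.0 ** log10KspAr

    # Element totals from salinity, mol kg-1
    BT = 0.000232 / 10.811 * S / 1.80655
    ST = 0.14 / 96.062 * S / 1.80655
    FT = 0.000067 / 18.998 * S / 1.80655
    Ca = 0.02128 / 40.087 * S / 1.80655

    # Weiss (1974) virial fugacity correction at 1 atm total pressure
    delta = 57.7 - 0.118 * T
    b_vir = -1636.75 + 12.0408 * T - 0.0327957 * T * T + 3.16528e-5 * T ** 3
    fugfac = math.exp((b_vir + 2.0 * delta) * _P_ATM_BAR / (_R_GAS * T))

    return EquilibriumConstants(
        K0=K0, K1=K1, K2=K2, KB=KB, KW=KW, KS=KS, KF=KF, KspAr=KspAr,
        BT=BT, ST=ST, FT=FT, Ca=Ca, fugacity_factor=fugfac, conditions=cond,
    )
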
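"""Monte-Carlo propagation of pH and alkalinity measurement error.

Spectrophotometric pH and open-cell titration alkalinity each carry an
instrument precision (0.01 pH units and 5 µmol/kg here). Those errors
propagate nonlinearly into the derived quantities DIC, pCO2 and Omega_ar.
This module quantifies that propagation by perturbing the measured pair with
independent Gaussian noise, re-solving the carbonate system for each draw,
and reporting one standard deviation of each derived quantity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .carbonate import InfeasibleStateError, solve_from_pH_TA
from .constants import SeawaterConditions

__all__ = ["UncertaintyReport", "propagate_mc"]


@dataclass(frozen=True)
class UncertaintyReport:
    """One-standard-deviation uncertainties of the derived carbonate quantities.

    ``sd_*`` are absolute (µmol/kg for DIC, µatm for pCO2, dimensionless for
    Omega); ``rel_*`` are percentages of the central value. ``n_excluded``
    counts perturbed draws that produced an infeasible carbonate state and
    were dropped from the statistics.
    """

    central_dic: float
    central_pco2: float
    central_omega: float
    sd_dic: float
    sd_pco2: float
    sd_omega: float
    rel_dic: float
    rel_pco2: float
    rel_omega: float
    n_sims: int
    n_excluded: int
    seed: int | None


def propagate_mc(
    ph_total: float,
    ta: float,
    cond: SeawaterConditions,
    n_sims: int = 100,
    sigma_ph: float = 0.01,
    sigma_ta: float = 5.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> UncertaintyReport:
    """Propagate (sigma_ph, sigma_ta) measurement error into DIC, pCO2, Omega.

    Draws ``n_sims`` independent pairs (pH + e1, TA + e2) with
    e1 ~ N(0, sigma_ph^2), e2 ~ N(0, sigma_ta^2), solves each perturbed
    state, and reports the sample SD of each derived quantity (ddof=1).
    Infeasible perturbed states are excluded — never clamped — and counted;
    a warning is emitted if any occur.

    Reproducible under a fixed ``seed`` (or an explicit ``rng``; then the
    stored seed is whatever was passed, possibly None).
    """
    if n_sims < 2:
        raise ValueError("n_sims must be >= 2")
    if sigma_ph < 0 or sigma_ta < 0:
        raise ValueError("noise SDs must be non-negative")
    if rng is None:
        rng = np.random.default_rng(seed)

    central = solve_from_pH_TA(ph_total, ta, cond)

    ph_draws = ph_total + rng.normal(0.0, sigma_ph, n_sims) if sigma_ph else np.full(n_sims, ph_total)
    ta_draws = ta + rng.normal(0.0, sigma_ta, n_sims) if sigma_ta else np.full(n_sims, ta)

    dic, pco2, omega = [], [], []
    n_excluded = 0
    for p, a in zip(ph_draws, ta_draws):
        try:
            s = solve_from_pH_TA(float(p), float(a), cond)
        except (InfeasibleStateError, ValueError):
            n_excluded += 1
            continue
        dic.append(s.dic)
        pco2.append(s.pco2)
        omega.append(s.omega_ar)
    if n_excluded:
        warnings.warn(
            f"{n_excluded}/{n_sims} perturbed states were infeasible and excluded",
            RuntimeWarning,
            stacklevel=2,
        )
    if len(dic) < 2:
        raise InfeasibleStateError("fewer than 2 feasible Monte-Carlo draws")

    sd_dic = float(np.std(dic, ddof=1))
    sd_pco2 = float(np.std(pco2, ddof=1))
    sd_omega = float(np.std(omega, ddof=1))
    return UncertaintyReport(
        central_dic=central.dic,
        central_pco2=central.pco2,
        central_omega=central.omega_ar,
        sd_dic=sd_dic,
        sd_pco2=sd_pco2,
        sd_omega=sd_omega,
        rel_dic=100.0 * sd_dic / central.dic,
        rel_pco2=100.0 * sd_pco2 / central.pco2,
        rel_omega=100.0 * sd_omega / central.omega_ar,
        n_sims=n_sims,
        n_excluded=n_excluded,
        seed=seed,
    )
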
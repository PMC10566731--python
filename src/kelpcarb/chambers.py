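"""Closed-chamber incubation analysis (species comparison experiment).

Each record is one sealed, headspace-free 1 L chamber holding a single
macrophyte thallus (or nothing, for controls), incubated for 1.5 h at a
target pCO2 level. pH/TA/DO are measured before and after; DIC and Omega at
each time point come from the carbonate solver, and the per-chamber response
is the biomass- and time-normalised delta.

Sign conventions (stated in the output headers):

* ``d_do``, ``d_ph``, ``d_omega`` — final minus initial (release / increase
  positive);
* ``d_dic`` — initial minus final, i.e. *uptake*, positive = DIC removal.

Species effects are modelled with ordinary least squares,
``delta ~ C(species) * pco2``, with a sequential (Type-I) ANOVA in the fixed
order species, pCO2, interaction, and per-species pCO2 slopes extracted from
the interaction contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .carbonate import (
    InfeasibleStateError,
    solve_from_pH_TA,
    umol_per_kg_to_umol_per_l,
)
from .constants import SeawaterConditions

__all__ = [
    "CONTROL_SPECIES",
    "compute_chamber_deltas",
    "SpeciesPCO2Model",
    "SpeciesPCO2Results",
    "fit_species_pco2_model",
]

CONTROL_SPECIES = "control"

#: delta-response columns produced per chamber
DELTA_COLUMNS = ("d_do", "d_dic", "d_ph", "d_omega")

_REQUIRED = [
    "chamber_id", "species", "pco2_level",
    "ph_initial", "ph_final", "ta_initial", "ta_final",
    "do_initial", "do_final", "temp_c", "sal",
    "biomass_dw", "volume_l", "duration_h",
]


def compute_chamber_deltas(chambers: pd.DataFrame) -> pd.DataFrame:
    """Per-chamber normalised delta responses.

    DIC and Omega at each time point are solved from (pH, TA) at the
    chamber's measured temperature and salinity; DIC is converted to
    volumetric units (µmol/L) so all rates share the field-standard
    µmol L-1 g-1 h-1 scale. Macrophyte chambers are normalised by dry-weight
    biomass and incubation time; control chambers (no biomass) by time only.

    Raises ``InfeasibleStateError`` naming the chamber when a measured state
    has no carbonate solution.
    """
    missing = [c for c in _REQUIRED if c not in chambers.columns]
    if missing:
        raise ValueError(f"chamber table missing columns: {missing}")
    rows = []
    for rec in chambers.itertuples(index=False):
        if rec.duration_h <= 0:
            raise ValueError(f"chamber {rec.chamber_id}: non-positive duration")
        is_control = rec.species == CONTROL_SPECIES
        if not is_control and not rec.biomass_dw > 0:
            raise ValueError(f"chamber {rec.chamber_id}: macrophyte chamber needs biomass_dw > 0")
        cond = SeawaterConditions(rec.temp_c, rec.sal)
        try:
            s0 = solve_from_pH_TA(rec.ph_initial, rec.ta_initial, cond)
            s1 = solve_from_pH_TA(rec.ph_final, rec.ta_final, cond)
        except (InfeasibleStateError, ValueError) as exc:
            raise InfeasibleStateError(f"chamber {rec.chamber_id}: {exc}") from exc
        norm = rec.duration_h if is_control else rec.biomass_dw * rec.duration_h
        rows.append({
            "chamber_id": rec.chamber_id,
            "species": rec.species,
            "pco2_level": rec.pco2_level,
            "d_do": (rec.do_final - rec.do_initial) / norm,
            "d_dic": umol_per_kg_to_umol_per_l(s0.dic - s1.dic) / norm,
            "d_ph": (rec.ph_final - rec.ph_initial) / norm,
            "d_omega": (s1.omega_ar - s0.omega_ar) / norm,
            "dic_initial": s0.dic,
            "dic_final": s1.dic,
            "omega_initial": s0.omega_ar,
            "omega_final": s1.omega_ar,
        })
    return pd.DataFrame(rows)


@dataclass
class SpeciesPCO2Results:
    """Fitted species x pCO2 response model for one delta variable.

    ``anova`` is the sequential (Type-I) table in the order species, pCO2,
    interaction, residual. ``slopes`` has one row per species with the
    per-µatm slope, its SE, and the 95% CI from the OLS covariance.
    """

    response: str
    anova: pd.DataFrame
    slopes: pd.DataFrame
    intercepts: pd.Series
    ols_results: object = field(repr=False)

    @property
    def params(self) -> pd.Series:
        return self.ols_results.params

    def summary(self) -> str:
        out = [
            f"Linear model: {self.response} ~ species * pCO2 (Type-I ANOVA)",
            self.anova.to_string(float_format=lambda v: f"{v:.4g}"),
            "",
            "Per-species pCO2 slopes (response units per µatm):",
            self.slopes.to_string(float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(out)


class SpeciesPCO2Model:
    """OLS model ``delta ~ C(species) * pco2`` for one response variable."""

    def __init__(self, deltas: pd.DataFrame, response: str):
        if response not in deltas.columns:
            raise ValueError(f"response column {response!r} not in table")
        data = deltas[deltas["species"] != CONTROL_SPECIES].copy()
        if data["species"].nunique() < 2:
            raise ValueError("need at least 2 macrophyte species")
        if data["pco2_level"].nunique() < 2:
            raise ValueError("need at least 2 pCO2 levels")
        self.data = data
        self.response = response

    @classmethod
    def from_dataframe(cls, deltas: pd.DataFrame, response: str) -> "SpeciesPCO2Model":
        return cls(deltas, response)

    def fit(self) -> SpeciesPCO2Results:
        formula = f"{self.response} ~ C(species) * pco2_level"
        res = smf.ols(formula, data=self.data).fit()
        if np.linalg.matrix_rank(res.model.exog) < res.model.exog.shape[1]:
            raise ValueError("design matrix is rank deficient (collinear species x pCO2 term)")
        anova = sm.stats.anova_lm(res, typ=1)
        anova.index = ["species", "pco2", "species:pco2", "residual"]

        species = sorted(self.data["species"].unique())
        ref = species[0]
        names = list(res.params.index)
        cov = res.cov_params().to_numpy()
        slope_rows, intercepts = [], {}
        for sp in species:
            w = np.zeros(len(names))
            w[names.index("pco2_level")] = 1.0
            inter = f"C(species)[T.{sp}]:pco2_level"
            if inter in names:
                w[names.index(inter)] = 1.0
            slope = float(w @ res.params.to_numpy())
            se = float(np.sqrt(w @ cov @ w))
            tcrit = stats.t.ppf(0.975, res.df_resid)
            slope_rows.append({
                "species": sp, "slope": slope, "se": se,
                "ci_low": slope - tcrit * se, "ci_high": slope + tcrit * se,
            })
            b0 = float(res.params["Intercept"])
            main = f"C(species)[T.{sp}]"
            intercepts[sp] = b0 + (float(res.params[main]) if main in names else 0.0)
        _ = ref
        return SpeciesPCO2Results(
            response=self.response,
            anova=anova,
            slopes=pd.DataFrame(slope_rows).set_index("species"),
            intercepts=pd.Series(intercepts, name="intercept"),
            ols_results=res,
        )


def fit_species_pco2_model(deltas: pd.DataFrame, response: str) -> SpeciesPCO2Results:
    """Convenience wrapper: build and fit a :class:`SpeciesPCO2Model`."""
    return SpeciesPCO2Model(deltas, response).fit()
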
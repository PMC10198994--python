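"""Expanded-liquid (solid-liquid equilibrium) solubility model with the
Wilson activity coefficient at infinite dilution.

The solute is treated as a subcooled liquid dissolved in the supercritical
solvent.  Equating solid- and fluid-phase fugacities gives

    y2 = (f2_S / f2_L) / gamma2_inf

where the solid/subcooled-liquid fugacity ratio follows from the fusion
enthalpy alone (the heat-capacity integral is dropped),

    ln(f2_S / f2_L) = dH_m / (R T) * (T / T_m - 1),

and the infinite-dilution activity coefficient comes from the Wilson model
written in reduced variables,

    ln gamma2_inf = 1 - Lambda12 - ln Lambda21
    Lambda12 = v2 * rho_c * rho_r * exp(-lam12 / T_r)
    Lambda21 = exp(-lam21 / T_r) / (v2 * rho_c * rho_r)

with the solute molar volume correlated linearly in reduced density,
``v2 = alpha rho_r + beta`` (m^3/mol).  The four fitted constants are
``alpha``, ``beta`` and the dimensionless interaction energies ``lam12``,
``lam21`` (the dimensional Wilson energies scaled by ``R T_c``).
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .core_data import R_GAS, SoluteInfo, SolventInfo
from .empirical_models import ModelEvaluationError, ModelSpec, register_model

__all__ = ["SLEParams", "fugacity_ratio", "wilson_gamma_inf", "sle_y2"]


class SLEParams(NamedTuple):
    alpha: float  # molar-volume slope, m^3/mol per unit reduced density
    beta: float   # molar-volume intercept, m^3/mol
    lam12: float  # dimensionless interaction energy lambda'_12
    lam21: float  # dimensionless interaction energy lambda'_21


def fugacity_ratio(solute: SoluteInfo, T):
    """Solid / subcooled-liquid fugacity ratio of the solute.

    Less than 1 below the melting point and exactly 1 at ``T = T_m``.
    """
    if solute.dH_m is None or solute.T_m is None:
        raise ValueError(
            f"solute {solute.name!r} lacks melting data (dH_m, T_m) required "
            "by the expanded-liquid model"
        )
    T = np.asarray(T, dtype=float)
    return np.exp(solute.dH_m / (R_GAS * T) * (T / solute.T_m - 1.0))


def wilson_gamma_inf(p: SLEParams, T, rho1, solvent: SolventInfo):
    """Infinite-dilution Wilson activity coefficient gamma2_inf.

    Raises
    ------
    ModelEvaluationError
        if the molar-volume correlation ``alpha rho_r + beta`` is
        non-positive anywhere (Lambda21 undefined).
    """
    p = SLEParams(*p)
    T = np.asarray(T, dtype=float)
    rho_r = solvent.rho_r(rho1)
    T_r = solvent.T_r(T)
    v2 = p.alpha * rho_r + p.beta
    if np.any(v2 <= 0):
        raise ModelEvaluationError(
            f"molar volume alpha*rho_r + beta <= 0 (min {np.min(v2):.3g} m^3/mol) "
            f"at rho_r = {np.asarray(rho_r).ravel()[np.argmin(v2)]:.4g}"
        )
    pref = v2 * solvent.rho_c * rho_r
    lam12 = pref * np.exp(-p.lam12 / T_r)
    lam21 = np.exp(-p.lam21 / T_r) / pref
    return np.exp(1.0 - lam12 - np.log(lam21))


def sle_y2(p: SLEParams, solute: SoluteInfo, T, rho1, solvent: SolventInfo):
    """Expanded-liquid solubility: fugacity_ratio / wilson_gamma_inf."""
    return fugacity_ratio(solute, T) / wilson_gamma_inf(p, T, rho1, solvent)


register_model(ModelSpec(
    name="sle_wilson",
    param_names=("alpha", "beta", "lam12", "lam21"),
    predict=lambda p, T, P, rho1, solute, solvent: sle_y2(
        SLEParams(*p), solute, T, rho1, solvent
    ),
    bounds=((1e-4, 0.05), (-0.02, 0.02), (-20.0, 20.0), (-20.0, 20.0)),
    unit_convention={"v2": "m^3/mol, linear in reduced density",
                     "energies": "scaled by R*T_c (dimensionless)"},
))
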
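"""Solvate-complex solubility models with a density-dependent association
number.

The solute A and kappa solvent molecules B are assumed to associate
reversibly into a complex ``AB_kappa``; writing the equilibrium in terms of
fugacities, absorbing the fugacity-coefficient / sublimation-pressure terms
into three fitted constants ``L`` (K), ``M`` (m^3/kg) and ``N``
(dimensionless), and converting the complex mole fraction into solute
solubility gives

    y2 = x / (1 + kappa * x),      x = (P/P*)^(kappa-1) exp(L/T + M rho1 + N)

with reference pressure ``P* = 1 bar``.  The association number kappa may be
taken constant or as a linear or quadratic polynomial of reduced density,

    kappa = a1 + a2 rho_r + a3 rho_r^2,

giving a family with 4, 5 or 6 fitted constants.  Dropping the denominator
recovers the Rajasekhar-Madras correlation; since ``kappa * x`` is of order
1e-5 for sparingly soluble drugs, the two forms are numerically almost
identical.

Registry names: ``solvate_quadratic``, ``solvate_linear``,
``solvate_constant``, ``rajasekhar_madras``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_data import SolubilityDataset, SolventInfo
from .empirical_models import ModelSpec, guarded_exp, register_model

__all__ = [
    "SolvateComplexParams",
    "association_number",
    "solvate_complex_y2",
    "rajasekhar_madras_y2",
    "average_association_number",
]

_MODES = ("constant", "linear", "quadratic")


@dataclass(frozen=True)
class SolvateComplexParams:
    """Parameters of the solvate-complex family.

    ``kappa_mode`` selects the association-number polynomial: ``constant``
    uses only ``a1``, ``linear`` adds ``a2 * rho_r``, ``quadratic`` adds
    ``a3 * rho_r^2``.  ``L`` is in K, ``M`` in m^3/kg, ``N`` dimensionless;
    ``P_star`` is the reference pressure in bar.
    """

    kappa_mode: str
    a1: float
    a2: float = 0.0
    a3: float = 0.0
    L: float = 0.0
    M: float = 0.0
    N: float = 0.0
    P_star: float = 1.0

    def __post_init__(self) -> None:
        if self.kappa_mode not in _MODES:
            raise ValueError(f"kappa_mode must be one of {_MODES}, got {self.kappa_mode!r}")
        if not self.P_star > 0:
            raise ValueError(f"P_star must be positive, got {self.P_star}")
        if self.kappa_mode == "constant" and (self.a2 != 0.0 or self.a3 != 0.0):
            raise ValueError("constant mode uses a1 only; a2 and a3 must be 0")
        if self.kappa_mode == "linear" and self.a3 != 0.0:
            raise ValueError("linear mode uses a1, a2 only; a3 must be 0")


def association_number(p: SolvateComplexParams, rho_r):
    """kappa at reduced density rho_r under the parameter set's mode."""
    rho_r = np.asarray(rho_r, dtype=float)
    if p.kappa_mode == "constant":
        return np.broadcast_to(np.float64(p.a1), rho_r.shape).copy() if rho_r.shape else np.float64(p.a1)
    if p.kappa_mode == "linear":
        return p.a1 + p.a2 * rho_r
    return p.a1 + p.a2 * rho_r + p.a3 * rho_r**2


def _x_term(p: SolvateComplexParams, kappa, T, P, rho1):
    T = np.asarray(T, dtype=float)
    P = np.asarray(P, dtype=float)
    rho1 = np.asarray(rho1, dtype=float)
    return (P / p.P_star) ** (kappa - 1.0) * guarded_exp(
        p.L / T + p.M * rho1 + p.N, "solvate_complex"
    )


def solvate_complex_y2(p: SolvateComplexParams, T, P, rho1, solvent: SolventInfo):
    """Full solvate-complex solubility y2 = x / (1 + kappa x)."""
    kappa = association_number(p, solvent.rho_r(rho1))
    x = _x_term(p, kappa, T, P, rho1)
    return x / (1.0 + kappa * x)


def rajasekhar_madras_y2(p: SolvateComplexParams, T, P, rho1):
    """Rajasekhar-Madras form: the x term alone (no association denominator).

    kappa is constant in this correlation; the parameter set's a1 is used.
    """
    return _x_term(p, p.a1, T, P, rho1)


def average_association_number(p: SolvateComplexParams, ds: SolubilityDataset) -> float:
    """Unweighted mean of kappa over the dataset's experimental conditions."""
    if len(ds) == 0:
        raise ValueError("empty dataset")
    return float(np.mean(association_number(p, ds.solvent.rho_r(ds.rho1))))


# ---------------------------------------------------------------------------
# registry entries: parameter vectors are (a1[, a2[, a3]], L, M, N)
# ---------------------------------------------------------------------------

def params_from_vector(name: str, vec) -> SolvateComplexParams:
    """Build :class:`SolvateComplexParams` from a registry parameter vector."""
    vec = np.asarray(vec, dtype=float)
    if name == "solvate_quadratic":
        return SolvateComplexParams("quadratic", vec[0], vec[1], vec[2],
                                    L=vec[3], M=vec[4], N=vec[5])
    if name == "solvate_linear":
        return SolvateComplexParams("linear", vec[0], vec[1],
                                    L=vec[2], M=vec[3], N=vec[4])
    if name in ("solvate_constant", "rajasekhar_madras"):
        return SolvateComplexParams("constant", vec[0],
                                    L=vec[1], M=vec[2], N=vec[3])
    raise KeyError(f"not a solvate-complex model: {name!r}")


def _seed_solvate(n_kappa_terms):
    # ln y2 ~ (kappa(rho_r)-1) ln P + L/T + M rho1 + N for kappa*x << 1
    def seed(T, P, rho1, y2, solute, solvent):
        rho_r = solvent.rho_r(rho1)
        lnP = np.log(P)
        cols = [lnP]
        if n_kappa_terms >= 2:
            cols.append(rho_r * lnP)
        if n_kappa_terms >= 3:
            cols.append(rho_r**2 * lnP)
        cols += [1.0 / T, rho1, np.ones_like(T)]
        A = np.c_[tuple(cols)]
        c, *_ = np.linalg.lstsq(A, np.log(y2), rcond=None)
        c = list(c)
        c[0] += 1.0  # exponent is kappa - 1
        return np.array(c)

    return seed


_KLM_BOUNDS = ((-2e4, 2e4), (-0.05, 0.05), (-50.0, 50.0))

register_model(ModelSpec(
    name="solvate_quadratic",
    param_names=("a1", "a2", "a3", "L", "M", "N"),
    predict=lambda p, T, P, rho1, solute, solvent: solvate_complex_y2(
        params_from_vector("solvate_quadratic", p), T, P, rho1, solvent
    ),
    bounds=((-5.0, 8.0), (-4.0, 4.0), (-2.0, 2.0)) + _KLM_BOUNDS,
    unit_convention={"pressure": "bar", "P_star": 1.0, "rho_r": "rho1/rho_c"},
    seed_fn=_seed_solvate(3),
))

register_model(ModelSpec(
    name="solvate_linear",
    param_names=("a1", "a2", "L", "M", "N"),
    predict=lambda p, T, P, rho1, solute, solvent: solvate_complex_y2(
        params_from_vector("solvate_linear", p), T, P, rho1, solvent
    ),
    bounds=((-5.0, 8.0), (-4.0, 4.0)) + _KLM_BOUNDS,
    unit_convention={"pressure": "bar", "P_star": 1.0, "rho_r": "rho1/rho_c"},
    seed_fn=_seed_solvate(2),
))

register_model(ModelSpec(
    name="solvate_constant",
    param_names=("kappa", "L", "M", "N"),
    predict=lambda p, T, P, rho1, solute, solvent: solvate_complex_y2(
        params_from_vector("solvate_constant", p), T, P, rho1, solvent
    ),
    bounds=((0.5, 8.0),) + ((-2e4, 0.0), (-0.05, 0.05), (-50.0, 50.0)),
    unit_convention={"pressure": "bar", "P_star": 1.0},
    seed_fn=_seed_solvate(1),
))

register_model(ModelSpec(
    name="rajasekhar_madras",
    param_names=("kappa", "L", "M", "N"),
    predict=lambda p, T, P, rho1, solute, solvent: rajasekhar_madras_y2(
        params_from_vector("rajasekhar_madras", p), T, P, rho1
    ),
    bounds=((0.5, 8.0),) + ((-2e4, 0.0), (-0.05, 0.05), (-50.0, 50.0)),
    unit_convention={"pressure": "bar", "P_star": 1.0},
    seed_fn=_seed_solvate(1),
))
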
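"""Density-based empirical solubility correlations and the model registry.

Six literature models are provided behind one evaluation contract
``predict(params, T, P, rho1, solute, solvent) -> y2``:

* Chrastil (association-law, density power law), in both the g/L
  concentration form and the mole-fraction form;
* reformulated Chrastil (dimensionless density group ``R T rho1 / (M f°)``);
* Mendez-Santiago & Teja (MST), the linear self-consistency correlation
  ``T ln(y2 P) = A3 + B3 rho1 + C3 T``;
* Bartle et al., ``ln(y2 P / P_ref) = A4 + B4/T + C4 (rho1 - rho_ref)``,
  whose ``B4`` carries the sublimation enthalpy;
* Reddy-Garlapati, bilinear in reduced temperature / quadratic in reduced
  pressure;
* Sodeifian et al., a six-constant mixed ``(T, P, rho1)`` surface.

Unit conventions (recovered by back-substituting the reference fits):
pressure in bar except inside MST (MPa); density in kg/m^3; Bartle
``P_ref = 1 bar``, ``rho_ref = 700 kg/m^3``; the reformulated-Chrastil group
uses R = 8.314 J/mol/K, T in K, rho1 in kg/m^3, M in g/mol and a reference
fugacity ``f° = 1`` in those mixed units.  Each :class:`ModelSpec` records
its convention; a refit absorbs any rescaling into the constants.

The registry maps name strings to :class:`ModelSpec` instances; the solvate
complex and SLE-Wilson modules register their models here on import.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, NamedTuple

import numpy as np

from .core_data import R_GAS, SoluteInfo, SolventInfo
from .conversions import y_from_s

__all__ = [
    "ModelEvaluationError",
    "ModelSpec",
    "MODEL_REGISTRY",
    "register_model",
    "get_model",
    "available_models",
    "ChrastilParams",
    "ReformChrastilParams",
    "MSTParams",
    "BartleParams",
    "ReddyGarlapatiParams",
    "SodeifianParams",
    "chrastil_c2",
    "chrastil_y2",
    "reformulated_chrastil_y2",
    "mst_y2",
    "bartle_y2",
    "reddy_garlapati_y2",
    "sodeifian_y2",
]

#: exp() argument beyond which evaluation aborts instead of overflowing.
_EXP_GUARD = 700.0


class ModelEvaluationError(ValueError):
    """A model could not be evaluated at the given parameters/conditions."""


def guarded_exp(arg, context: str):
    """exp() that raises :class:`ModelEvaluationError` on overflow.

    The error message echoes the offending argument and the evaluation
    context so a diverging parameter vector can be identified.
    """
    arg = np.asarray(arg, dtype=float)
    if np.any(arg > _EXP_GUARD):
        raise ModelEvaluationError(
            f"exp overflow in {context}: argument max {np.max(arg):.3g} > {_EXP_GUARD:g}"
        )
    return np.exp(arg)


# ---------------------------------------------------------------------------
# parameter vectors
# ---------------------------------------------------------------------------

class ChrastilParams(NamedTuple):
    kappa: float  # association number (density exponent)
    A1: float
    B1: float  # K; -B1*R is the total dissolution enthalpy


class ReformChrastilParams(NamedTuple):
    kappa: float
    A2: float
    B2: float  # K


class MSTParams(NamedTuple):
    A3: float  # K
    B3: float  # K m^3/kg
    C3: float


class BartleParams(NamedTuple):
    A4: float
    B4: float  # K; -B4*R is the sublimation enthalpy
    C4: float  # m^3/kg


class ReddyGarlapatiParams(NamedTuple):
    A5: float
    B5: float
    C5: float
    D5: float
    E5: float
    F5: float


class SodeifianParams(NamedTuple):
    A6: float
    B6: float
    C6: float
    D6: float
    E6: float
    F6: float


# ---------------------------------------------------------------------------
# model forms
# ---------------------------------------------------------------------------

def chrastil_c2(p: ChrastilParams, T, rho1):
    """Chrastil concentration form: c2 = rho1^kappa exp(A1 + B1/T), g/L."""
    p = ChrastilParams(*p)
    T = np.asarray(T, dtype=float)
    rho1 = np.asarray(rho1, dtype=float)
    return rho1**p.kappa * guarded_exp(p.A1 + p.B1 / T, "chrastil_c2")


def chrastil_y2(p: ChrastilParams, T, rho1):
    """Chrastil mole-fraction form: y2 = x/(1+x), x = rho1^(kappa-1) exp(A1+B1/T)."""
    p = ChrastilParams(*p)
    T = np.asarray(T, dtype=float)
    rho1 = np.asarray(rho1, dtype=float)
    x = rho1 ** (p.kappa - 1.0) * guarded_exp(p.A1 + p.B1 / T, "chrastil_y2")
    return x / (1.0 + x)


def reformulated_chrastil_y2(
    p: ReformChrastilParams, T, rho1, solvent: SolventInfo, f_ref: float = 1.0
):
    """Reformulated Chrastil: y2 = (R T rho1 / (M f°))^(kappa-1) exp(A2 + B2/T).

    The dimensionless density group is formed with R = 8.314, T in K, rho1 in
    kg/m^3, M in g/mol and reference fugacity ``f_ref`` = 1 in those units.
    """
    p = ReformChrastilParams(*p)
    if not f_ref > 0:
        raise ModelEvaluationError(f"reference fugacity must be positive, got {f_ref}")
    T = np.asarray(T, dtype=float)
    rho1 = np.asarray(rho1, dtype=float)
    group = R_GAS * T * rho1 / (solvent.M * f_ref)
    return group ** (p.kappa - 1.0) * guarded_exp(p.A2 + p.B2 / T, "reformulated_chrastil_y2")


def mst_y2(p: MSTParams, T, P, rho1):
    """MST: T ln(y2 P) = A3 + B3 rho1 + C3 T, with P in MPa inside the model.

    ``P`` is accepted in bar (package convention) and converted.
    """
    p = MSTParams(*p)
    T = np.asarray(T, dtype=float)
    P_MPa = np.asarray(P, dtype=float) / 10.0
    rho1 = np.asarray(rho1, dtype=float)
    return guarded_exp((p.A3 + p.B3 * rho1) / T + p.C3, "mst_y2") / P_MPa


def bartle_y2(p: BartleParams, T, P, rho1, P_ref: float = 1.0, rho_ref: float = 700.0):
    """Bartle et al.: y2 = (P_ref/P) exp(A4 + B4/T + C4 (rho1 - rho_ref))."""
    p = BartleParams(*p)
    T = np.asarray(T, dtype=float)
    P = np.asarray(P, dtype=float)
    rho1 = np.asarray(rho1, dtype=float)
    return (P_ref / P) * guarded_exp(
        p.A4 + p.B4 / T + p.C4 * (rho1 - rho_ref), "bartle_y2"
    )


def reddy_garlapati_y2(p: ReddyGarlapatiParams, T, P, solvent: SolventInfo):
    """Reddy-Garlapati: y2 = (A5 + B5 Pr + C5 Pr^2) Tr + (D5 + E5 Pr + F5 Pr^2).

    May be negative for unphysical parameters; the fitting objective
    penalizes (rather than clips) such predictions.
    """
    p = ReddyGarlapatiParams(*p)
    Tr = solvent.T_r(T)
    Pr = solvent.P_r(P)
    return (p.A5 + p.B5 * Pr + p.C5 * Pr**2) * Tr + (p.D5 + p.E5 * Pr + p.F5 * Pr**2)


def sodeifian_y2(p: SodeifianParams, T, P, rho1):
    """Sodeifian et al. six-constant surface; P in bar, rho1 in kg/m^3."""
    p = SodeifianParams(*p)
    T = np.asarray(T, dtype=float)
    P = np.asarray(P, dtype=float)
    rho1 = np.asarray(rho1, dtype=float)
    return (
        p.A6
        + p.B6 * P**2 / T
        + p.C6 * np.log(rho1 * T)
        + p.D6 * rho1 * np.log(rho1)
        + p.E6 * P * np.log(T)
        + p.F6 * np.log(rho1) / T
    )


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

PredictFn = Callable[..., np.ndarray]
SeedFn = Callable[..., np.ndarray]


@dataclass(frozen=True)
class ModelSpec:
    """A named model form with a uniform evaluation contract.

    ``predict(params, T, P, rho1, solute, solvent)`` returns predicted mole
    fractions for parameter vector ``params`` (ordered as ``param_names``).
    ``bounds`` is the default multistart search box; ``seed_fn`` optionally
    produces an analytic warm start (typically a linearized least-squares
    solution) from the data arrays.
    """

    name: str
    param_names: tuple[str, ...]
    predict: PredictFn
    bounds: tuple[tuple[float, float], ...]
    unit_convention: Mapping[str, object] = field(default_factory=dict)
    seed_fn: SeedFn | None = None

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def __post_init__(self) -> None:
        if len(self.bounds) != len(self.param_names):
            raise ValueError(
                f"model {self.name}: {len(self.bounds)} bounds for "
                f"{len(self.param_names)} parameters"
            )


MODEL_REGISTRY: dict[str, ModelSpec] = {}


def register_model(spec: ModelSpec) -> ModelSpec:
    MODEL_REGISTRY[spec.name] = spec
    return spec


def get_model(name: str) -> ModelSpec:
    try:
        return MODEL_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; available: {', '.join(sorted(MODEL_REGISTRY))}"
        ) from None


def available_models() -> tuple[str, ...]:
    return tuple(sorted(MODEL_REGISTRY))


# -- analytic warm starts (log/weighted linearizations) ---------------------

def _seed_chrastil(T, P, rho1, y2, solute, solvent):
    # ln y2 ~ (kappa-1) ln rho1 + A1 + B1/T for y2 << 1
    A = np.c_[np.log(rho1), np.ones_like(T), 1.0 / T]
    c, *_ = np.linalg.lstsq(A, np.log(y2), rcond=None)
    return np.array([c[0] + 1.0, c[1], c[2]])


def _seed_reform_chrastil(T, P, rho1, y2, solute, solvent):
    g = np.log(R_GAS * T * rho1 / solvent.M)
    A = np.c_[g, np.ones_like(T), 1.0 / T]
    c, *_ = np.linalg.lstsq(A, np.log(y2), rcond=None)
    return np.array([c[0] + 1.0, c[1], c[2]])


def _seed_mst(T, P, rho1, y2, solute, solvent):
    A = np.c_[np.ones_like(T), rho1, T]
    c, *_ = np.linalg.lstsq(A, T * np.log(y2 * P / 10.0), rcond=None)
    return c


def _seed_bartle(T, P, rho1, y2, solute, solvent):
    A = np.c_[np.ones_like(T), 1.0 / T, rho1 - 700.0]
    c, *_ = np.linalg.lstsq(A, np.log(y2 * P), rcond=None)
    return c


def _wls_seed(X, y2):
    # minimize sum(((y - X c)/y)^2)  ==  ||diag(1/y) X c - 1||^2
    c, *_ = np.linalg.lstsq(X / y2[:, None], np.ones_like(y2), rcond=None)
    return c


def _seed_reddy_garlapati(T, P, rho1, y2, solute, solvent):
    Tr, Pr = solvent.T_r(T), solvent.P_r(P)
    X = np.c_[Tr, Pr * Tr, Pr**2 * Tr, np.ones_like(T), Pr, Pr**2]
    return _wls_seed(X, y2)


def _seed_sodeifian(T, P, rho1, y2, solute, solvent):
    X = np.c_[
        np.ones_like(T), P**2 / T, np.log(rho1 * T),
        rho1 * np.log(rho1), P * np.log(T), np.log(rho1) / T,
    ]
    return _wls_seed(X, y2)


register_model(ModelSpec(
    name="chrastil",
    param_names=("kappa", "A1", "B1"),
    predict=lambda p, T, P, rho1, solute, solvent: chrastil_y2(p, T, rho1),
    bounds=((0.5, 12.0), (-50.0, 50.0), (-5e4, 0.0)),
    unit_convention={"density": "kg/m^3", "form": "mole fraction (c2/(rho+c2) algebra)"},
    seed_fn=_seed_chrastil,
))

register_model(ModelSpec(
    name="chrastil_c2",
    param_names=("kappa", "A1", "B1"),
    predict=lambda p, T, P, rho1, solute, solvent: y_from_s(
        chrastil_c2(p, T, rho1), rho1, solute, solvent
    ),
    bounds=((0.5, 12.0), (-50.0, 50.0), (-5e4, 0.0)),
    unit_convention={"density": "kg/m^3", "c2": "g/L",
                     "note": "A1 differs from the y2 form by ln(M_s/M)"},
    seed_fn=lambda T, P, rho1, y2, solute, solvent: _seed_chrastil(
        T, P, rho1, y2, solute, solvent
    ) + np.array([0.0, np.log(solute.M_s / solvent.M), 0.0]),
))

register_model(ModelSpec(
    name="ref_chrastil",
    param_names=("kappa", "A2", "B2"),
    predict=lambda p, T, P, rho1, solute, solvent: reformulated_chrastil_y2(
        p, T, rho1, solvent
    ),
    bounds=((0.5, 12.0), (-80.0, 20.0), (-5e4, 0.0)),
    unit_convention={"group": "R T rho1 / (M f°)", "R": R_GAS, "f_ref": 1.0},
    seed_fn=_seed_reform_chrastil,
))

register_model(ModelSpec(
    name="mst",
    param_names=("A3", "B3", "C3"),
    predict=lambda p, T, P, rho1, solute, solvent: mst_y2(p, T, P, rho1),
    bounds=((-5e4, 0.0), (0.0, 10.0), (0.0, 100.0)),
    unit_convention={"pressure": "MPa (converted from bar)", "density": "kg/m^3"},
    seed_fn=_seed_mst,
))

register_model(ModelSpec(
    name="bartle",
    param_names=("A4", "B4", "C4"),
    predict=lambda p, T, P, rho1, solute, solvent: bartle_y2(p, T, P, rho1),
    bounds=((-50.0, 100.0), (-5e4, 0.0), (-0.05, 0.05)),
    unit_convention={"pressure": "bar", "P_ref": 1.0, "rho_ref": 700.0},
    seed_fn=_seed_bartle,
))

register_model(ModelSpec(
    name="reddy_garlapati",
    param_names=("A5", "B5", "C5", "D5", "E5", "F5"),
    predict=lambda p, T, P, rho1, solute, solvent: reddy_garlapati_y2(
        p, T, P, solvent
    ),
    bounds=(((-1e-3, 1e-3),) * 6),
    unit_convention={"variables": "reduced T_r, P_r (solvent critical constants)"},
    seed_fn=_seed_reddy_garlapati,
))

register_model(ModelSpec(
    name="sodeifian",
    param_names=("A6", "B6", "C6", "D6", "E6", "F6"),
    predict=lambda p, T, P, rho1, solute, solvent: sodeifian_y2(p, T, P, rho1),
    bounds=(((-10.0, 10.0),) * 6),
    unit_convention={"pressure": "bar", "density": "kg/m^3"},
    seed_fn=_seed_sodeifian,
))
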
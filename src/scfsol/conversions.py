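"""Conversions between assay concentrations, g/L solubility and mole fraction.

In a static solubility measurement a saturated sample of volume ``V1``
(the sampling loop) is discharged into a collection vial of volume ``Vs``
and the drug concentration ``Cs`` (g/L) in the vial is quantified.  The
mole-fraction solubility follows from the mole counts

    n_drug = Cs * Vs / M_s          n_solvent = V1 * rho1 / M_solvent

with ``rho1`` the supercritical-phase density in kg/m^3 — numerically equal
to g/L, so no unit factor appears.  The equilibrium solubility on a
g-per-litre-of-fluid basis is ``S = Cs * Vs / V1`` and relates to the mole
fraction through

    S = rho1 * (M_s / M_solvent) * y2 / (1 - y2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_data import SoluteInfo, SolventInfo

__all__ = [
    "SamplingGeometry",
    "mole_fraction_from_assay",
    "solubility_gL_from_assay",
    "s_from_y",
    "y_from_s",
]


@dataclass(frozen=True)
class SamplingGeometry:
    """Sampling-loop and collection-vial volumes, in litres.

    Defaults are the reference apparatus values: a 600 uL loop discharged
    into a 5 mL vial.
    """

    V1: float = 600e-6
    Vs: float = 5e-3

    def __post_init__(self) -> None:
        if not (self.V1 > 0 and self.Vs > 0):
            raise ValueError(f"volumes must be positive, got V1={self.V1}, Vs={self.Vs}")


def mole_fraction_from_assay(
    Cs: float,
    geom: SamplingGeometry,
    rho1: float,
    solute: SoluteInfo,
    solvent: SolventInfo,
):
    """Mole-fraction solubility from the vial assay concentration.

    Parameters
    ----------
    Cs : drug concentration measured in the collection vial, g/L.
    rho1 : supercritical-phase density, kg/m^3 (== g/L).
    """
    if np.any(np.asarray(rho1) <= 0):
        raise ValueError(f"density must be positive, got rho1={rho1}")
    n_drug = np.asarray(Cs) * geom.Vs / solute.M_s
    n_solvent = geom.V1 * np.asarray(rho1) / solvent.M
    return n_drug / (n_drug + n_solvent)


def solubility_gL_from_assay(Cs: float, geom: SamplingGeometry):
    """Equilibrium solubility S (g per litre of fluid) = Cs * Vs / V1."""
    return np.asarray(Cs) * geom.Vs / geom.V1


def s_from_y(y2, rho1, solute: SoluteInfo, solvent: SolventInfo):
    """g/L solubility from mole fraction: S = rho1 (M_s/M) y2/(1-y2)."""
    y2 = np.asarray(y2, dtype=float)
    if np.any(y2 >= 1.0) or np.any(y2 < 0.0):
        raise ValueError(f"y2 must lie in [0, 1), got {y2}")
    return np.asarray(rho1, dtype=float) * solute.M_s / solvent.M * y2 / (1.0 - y2)


def y_from_s(s_gL, rho1, solute: SoluteInfo, solvent: SolventInfo):
    """Inverse of :func:`s_from_y`: y2 = S M / (rho1 M_s + S M)."""
    s = np.asarray(s_gL, dtype=float) * solvent.M
    return s / (np.asarray(rho1, dtype=float) * solute.M_s + s)
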
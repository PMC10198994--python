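"""Domain types, physical constants and dataset I/O for solubility data
in supercritical fluids.

The central container is :class:`SolubilityDataset`, an ordered collection of
isothermal ``(T, P, rho1, y2)`` observations of a solid solute dissolved in a
supercritical solvent, together with the physical constants of the solute
(:class:`SoluteInfo`) and solvent (:class:`SolventInfo`).

A reference dataset for hydroxychloroquine sulfate (HCQS) in supercritical
CO2 — 24 points on a 4 temperature x 6 pressure grid, 308-338 K and
120-270 bar — ships with the package and is returned by :func:`hcqs_dataset`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "R_GAS",
    "SolubilityRecord",
    "SolubilityDataset",
    "SoluteInfo",
    "SolventInfo",
    "DatasetSchemaError",
    "DatasetParseError",
    "DatasetValidationError",
    "co2_defaults",
    "hcqs_solute",
    "hcqs_dataset",
    "load_dataset",
    "CSV_COLUMNS",
]

#: Universal gas constant, J mol^-1 K^-1, used throughout the package.
R_GAS = 8.314

#: Canonical CSV header (comma separated, '.' decimal, UTF-8).
CSV_COLUMNS = ("T_K", "P_bar", "rho_kg_m3", "y2", "s_g_L")

#: Relative tolerance for the y2 <-> S(g/L) cross-check of printed values.
_S_CONSISTENCY_RTOL = 0.015


class DatasetSchemaError(ValueError):
    """A required column is missing from an input table."""


class DatasetParseError(ValueError):
    """A cell could not be parsed as a number; the message names the cell."""


class DatasetValidationError(ValueError):
    """A row violates a physical invariant; the message names the row."""


@dataclass(frozen=True)
class SoluteInfo:
    """Physical constants of the solid solute.

    Parameters
    ----------
    name : str
    M_s : float
        Molecular weight, g/mol.
    dH_m : float, optional
        Molar enthalpy of fusion, J/mol.  Required only by the
        expanded-liquid (SLE) model.
    T_m : float, optional
        Melting temperature, K.
    v2_ref : float, optional
        Solid molar volume, m^3/mol (informational).
    """

    name: str
    M_s: float
    dH_m: float | None = None
    T_m: float | None = None
    v2_ref: float | None = None

    def __post_init__(self) -> None:
        if not self.M_s > 0:
            raise ValueError(f"M_s must be positive, got {self.M_s}")
        if self.dH_m is not None and not self.dH_m > 0:
            raise ValueError(f"dH_m must be positive, got {self.dH_m}")
        if self.T_m is not None and not self.T_m > 0:
            raise ValueError(f"T_m must be positive, got {self.T_m}")


@dataclass(frozen=True)
class SolventInfo:
    """Physical constants of the supercritical solvent.

    Reduced-state helpers divide by the critical constants:
    ``T_r = T/T_c``, ``P_r = P/P_c``, ``rho_r = rho1/rho_c``.
    """

    name: str
    M: float  # g/mol
    T_c: float  # K
    P_c: float  # bar
    rho_c: float  # kg/m^3

    def __post_init__(self) -> None:
        for f in ("M", "T_c", "P_c", "rho_c"):
            if not getattr(self, f) > 0:
                raise ValueError(f"{f} must be positive, got {getattr(self, f)}")

    def T_r(self, T):
        return np.asarray(T, dtype=float) / self.T_c

    def P_r(self, P):
        return np.asarray(P, dtype=float) / self.P_c

    def rho_r(self, rho1):
        return np.asarray(rho1, dtype=float) / self.rho_c


def co2_defaults() -> SolventInfo:
    """Carbon dioxide constants.

    M = 44.01 g/mol; critical point T_c = 304.13 K, P_c = 73.8 bar,
    rho_c = 467.6 kg/m^3 (NIST values).
    """
    return SolventInfo(name="carbon dioxide", M=44.01, T_c=304.13, P_c=73.8, rho_c=467.6)


def hcqs_solute() -> SoluteInfo:
    """Hydroxychloroquine sulfate (HCQS, C18H28ClN3O5S) constants.

    M_s = 434 g/mol; fusion enthalpy 65 208 J/mol (group contribution
    estimate); melting point 240 degC = 513.15 K (MSDS); molar volume
    3.306e-4 m^3/mol.
    """
    return SoluteInfo(
        name="hydroxychloroquine sulfate",
        M_s=434.0,
        dH_m=65208.0,
        T_m=513.15,
        v2_ref=3.306e-4,
    )


def _s_gl(y2: float, rho1: float, solute: SoluteInfo, solvent: SolventInfo) -> float:
    # S = rho * (M_s/M_solvent) * y2/(1-y2); kept local to avoid an import
    # cycle with the conversions module, whose s_from_y is the public form.
    return rho1 * solute.M_s / solvent.M * y2 / (1.0 - y2)


@dataclass(frozen=True)
class SolubilityRecord:
    """One equilibrium observation: (T, P, rho1, y2) plus optional S in g/L.

    Invariants (checked by :meth:`validate` against a solvent): supercritical
    state (``T > T_c``, ``P > P_c``), ``rho1 > 0``, ``0 < y2 < 1``, and the
    g/L solubility — when present — consistent with the mole fraction within
    1.5 % (rounding of printed values).
    """

    T: float
    P: float
    rho1: float
    y2: float
    s_gL: float | None = None

    def validate(self, solute: SoluteInfo, solvent: SolventInfo, row: object = "?") -> None:
        if not self.T > solvent.T_c:
            raise DatasetValidationError(
                f"row {row}: T = {self.T} K is subcritical (T_c = {solvent.T_c} K)"
            )
        if not self.P > solvent.P_c:
            raise DatasetValidationError(
                f"row {row}: P = {self.P} bar is subcritical (P_c = {solvent.P_c} bar)"
            )
        if not self.rho1 > 0:
            raise DatasetValidationError(f"row {row}: rho1 = {self.rho1} must be positive")
        if not 0.0 < self.y2 < 1.0:
            raise DatasetValidationError(f"row {row}: y2 = {self.y2} outside (0, 1)")
        if self.s_gL is not None:
            s_calc = _s_gl(self.y2, self.rho1, solute, solvent)
            if abs(s_calc - self.s_gL) > _S_CONSISTENCY_RTOL * self.s_gL:
                raise DatasetValidationError(
                    f"row {row}: s_gL = {self.s_gL} inconsistent with y2 = {self.y2} "
                    f"(expected {s_calc:.4g} g/L, tolerance 1.5%)"
                )


@dataclass(frozen=True)
class SolubilityDataset:
    """Ordered isothermal solubility data with solute/solvent constants.

    Records are grouped by isotherm; within an isotherm pressure and density
    are strictly increasing.
    """

    records: tuple[SolubilityRecord, ...]
    solute: SoluteInfo
    solvent: SolventInfo
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SolubilityRecord]:
        return iter(self.records)

    # -- array views -------------------------------------------------
    @property
    def T(self) -> np.ndarray:
        return np.array([r.T for r in self.records])

    @property
    def P(self) -> np.ndarray:
        return np.array([r.P for r in self.records])

    @property
    def rho1(self) -> np.ndarray:
        return np.array([r.rho1 for r in self.records])

    @property
    def y2(self) -> np.ndarray:
        return np.array([r.y2 for r in self.records])

    def isotherms(self) -> dict[float, tuple[SolubilityRecord, ...]]:
        """Records grouped by temperature, preserving order."""
        out: dict[float, list[SolubilityRecord]] = {}
        for r in self.records:
            out.setdefault(r.T, []).append(r)
        return {T: tuple(rs) for T, rs in out.items()}

    def validate(self) -> None:
        """Check every record and the isotherm ordering invariants."""
        if not self.records:
            raise DatasetValidationError("dataset is empty")
        for i, r in enumerate(self.records):
            r.validate(self.solute, self.solvent, row=i)
        for T, recs in self.isotherms().items():
            P = [r.P for r in recs]
            rho = [r.rho1 for r in recs]
            if any(b <= a for a, b in zip(P, P[1:])):
                raise DatasetValidationError(
                    f"isotherm {T} K: pressures not strictly increasing"
                )
            if any(b <= a for a, b in zip(rho, rho[1:])):
                raise DatasetValidationError(
                    f"isotherm {T} K: density not strictly increasing with pressure"
                )

    # -- I/O ---------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "T_K": self.T,
                "P_bar": self.P,
                "rho_kg_m3": self.rho1,
                "y2": self.y2,
                "s_g_L": [r.s_gL for r in self.records],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _coerce_cell(value, column: str, row: int) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise DatasetParseError(
            f"column {column!r}, row {row}: cannot parse {value!r} as a number"
        ) from None


def load_dataset(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    solute: SoluteInfo | None = None,
    solvent: SolventInfo | None = None,
    label: str | None = None,
) -> SolubilityDataset:
    """Read a solubility dataset from CSV and validate it.

    Parameters
    ----------
    path : path to a CSV file with a header row.
    schema : optional mapping from the canonical names
        ``{"T_K", "P_bar", "rho_kg_m3", "y2", "s_g_L"}`` to the column names
        actually used in the file.
    solute, solvent : constants attached to the dataset; default to the HCQS
        and CO2 values.

    Raises
    ------
    DatasetSchemaError  if a required column is absent.
    DatasetParseError   if a cell is not numeric (names the cell).
    DatasetValidationError  if a row violates a physical invariant
        (names the row).
    """
    solute = solute if solute is not None else hcqs_solute()
    solvent = solvent if solvent is not None else co2_defaults()
    schema = dict(schema) if schema else {}
    colname = {canon: schema.get(canon, canon) for canon in CSV_COLUMNS}

    frame = pd.read_csv(path, dtype=str)
    required = ["T_K", "P_bar", "rho_kg_m3", "y2"]
    missing = [colname[c] for c in required if colname[c] not in frame.columns]
    if missing:
        raise DatasetSchemaError(f"missing required column(s): {', '.join(missing)}")
    has_s = colname["s_g_L"] in frame.columns

    records = []
    for i, row in frame.iterrows():
        vals = {c: _coerce_cell(row[colname[c]], colname[c], i) for c in required}
        s = None
        if has_s and str(row[colname["s_g_L"]]).strip() not in ("", "nan"):
            s = _coerce_cell(row[colname["s_g_L"]], colname["s_g_L"], i)
        records.append(
            SolubilityRecord(
                T=vals["T_K"], P=vals["P_bar"], rho1=vals["rho_kg_m3"],
                y2=vals["y2"], s_gL=s,
            )
        )
    ds = SolubilityDataset(
        records=tuple(records),
        solute=solute,
        solvent=solvent,
        label=label if label is not None else str(path),
    )
    ds.validate()
    return ds


def hcqs_dataset() -> SolubilityDataset:
    """The bundled 24-point HCQS / scCO2 dataset.

    Four isotherms (308, 318, 328, 338 K) at six pressures (120-270 bar),
    with NIST CO2 densities and measured mole-fraction solubilities between
    3.04e-6 (308 K, 120 bar) and 5.515e-5 (338 K, 270 bar).
    """
    with resources.as_file(
        resources.files("scfsol.data").joinpath("hcqs_scco2.csv")
    ) as p:
        return load_dataset(p, label="HCQS in scCO2 (built-in)")
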
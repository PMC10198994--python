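"""Model fitting, goodness-of-fit statistics, ranking and derived enthalpies.

Fitting
-------
Any registered model is fitted to a :class:`~scfsol.core_data.SolubilityDataset`
by seeded multistart derivative-free minimization: a Latin-hypercube pool of
``n_restarts`` points inside the model's search box is screened by objective
value, Nelder-Mead simplex descent is run from the best screened points plus
the model's analytic warm start (a linearized least-squares solution where
one exists), and the incumbent is polished at tight tolerance.  The whole
procedure is deterministic given ``seed``.

Two relative-deviation losses are available.  The default,
``"squared_relative"``, minimizes

    sum_i ((y_exp_i - y_calc_i) / y_exp_i)^2,

which is smooth and identifies stable optima on sparingly-soluble drug data;
``"absolute_relative"`` minimizes the sum of absolute relative deviations
(the quantity whose per-point mean x100 is the AARD%).  Predictions that are
non-finite or non-positive contribute a fixed penalty of 1e3 per point, so
the optimizer is steered away from unphysical regions without discontinuity
in the feasible set.

Model selection
---------------
Fit quality is summarized by AARD%, SSE, RMSE, R^2, adjusted R^2 and the
(corrected) Akaike information criterion computed from the squared-error sum:

    AIC  = N ln(SSE/N) + 2Q
    AICc = AIC + 2Q(Q+1) / (N - Q - 1)

with N data points and Q fitted constants.  AICc is the ranking criterion
for small samples (N < 40); the smallest value wins, ties broken by fewer
parameters.

Enthalpies
----------
The temperature constants of the density-power-law fits carry dissolution
energetics: total enthalpy ``-B1*R`` (Chrastil) or ``-B2*R`` (reformulated),
sublimation enthalpy ``-B4*R`` (Bartle), and solvation enthalpy as the
difference total - sublimation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize
from scipy.stats import qmc

from .core_data import SolubilityDataset
from .empirical_models import ModelSpec, get_model

__all__ = [
    "FitError",
    "FitResult",
    "EnthalpyReport",
    "MSTConsistency",
    "objective",
    "aard_pct",
    "fit_model",
    "aic_from_sse",
    "aicc_from_sse",
    "rmse_from_sse",
    "information_criteria",
    "rank_models",
    "derive_enthalpies",
    "mst_consistency",
]

#: penalty per point for non-finite / non-positive predictions
_PENALTY = 1.0e3

_LOSSES = ("squared_relative", "absolute_relative")


class FitError(RuntimeError):
    """Raised when no finite-objective starting point can be found."""


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------

def _predict_or_none(model: ModelSpec, params, ds: SolubilityDataset):
    try:
        with np.errstate(all="ignore"):
            y = np.asarray(
                model.predict(np.asarray(params, dtype=float),
                              ds.T, ds.P, ds.rho1, ds.solute, ds.solvent),
                dtype=float,
            )
    except Exception:
        return None
    return y


def _relative_deviations(model: ModelSpec, params, ds: SolubilityDataset):
    """Per-point (y_exp - y_calc)/y_exp with penalties for bad predictions."""
    y_exp = ds.y2
    y_calc = _predict_or_none(model, params, ds)
    if y_calc is None or y_calc.shape != y_exp.shape:
        return np.full(len(ds), _PENALTY)
    with np.errstate(all="ignore"):
        r = (y_exp - y_calc) / y_exp
    bad = ~np.isfinite(y_calc) | (y_calc <= 0.0) | ~np.isfinite(r)
    return np.where(bad, _PENALTY, np.where(bad, 0.0, r))


def objective(model: ModelSpec | str, params, ds: SolubilityDataset) -> float:
    """Sum of absolute relative deviations, the classic correlation objective.

    Non-finite or non-positive predictions contribute 1e3 per point.
    """
    if len(ds) == 0:
        raise ValueError("empty dataset")
    model = get_model(model) if isinstance(model, str) else model
    return float(np.sum(np.abs(_relative_deviations(model, params, ds))))


def aard_pct(model: ModelSpec | str, params, ds: SolubilityDataset) -> float:
    """Average absolute relative deviation in percent: 100 * objective / N."""
    return 100.0 * objective(model, params, ds) / len(ds)


def _loss_fn(model: ModelSpec, ds: SolubilityDataset, loss: str):
    if loss == "squared_relative":
        def f(p):
            r = _relative_deviations(model, p, ds)
            with np.errstate(over="ignore"):
                return float(np.sum(np.where(r >= _PENALTY, _PENALTY,
                                             np.minimum(np.abs(r), _PENALTY) ** 2)))
    elif loss == "absolute_relative":
        def f(p):
            return float(np.sum(np.abs(_relative_deviations(model, p, ds))))
    else:
        raise ValueError(f"loss must be one of {_LOSSES}, got {loss!r}")
    return f


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def aic_from_sse(sse: float, n: int, q: int) -> float:
    """Akaike information criterion from the squared-error sum.

    A perfect fit (SSE = 0) maps to ``-inf``, the natural limit of the
    log-likelihood form.
    """
    if sse < 0:
        raise ValueError(f"SSE must be non-negative, got {sse}")
    if sse == 0:
        return -math.inf
    return n * math.log(sse / n) + 2 * q


def aicc_from_sse(sse: float, n: int, q: int) -> float:
    """Small-sample corrected AIC; requires n > q + 1."""
    if n <= q + 1:
        raise ValueError(f"AICc undefined for N={n}, Q={q} (need N > Q + 1)")
    return aic_from_sse(sse, n, q) + 2 * q * (q + 1) / (n - q - 1)


def rmse_from_sse(sse: float, n: int) -> float:
    return math.sqrt(sse / n)


@dataclass(frozen=True)
class FitResult:
    """A fitted model with its per-point predictions and fit statistics."""

    model: ModelSpec
    params: np.ndarray
    per_point: pd.DataFrame  # columns T_K, P_bar, rho_kg_m3, y_exp, y_calc, rel_dev
    aard_pct: float
    sse: float
    rmse: float
    r2: float
    r2_adj: float
    aic: float
    aicc: float
    n_points: int
    n_params: int
    objective_value: float  # sum |rel dev| at the optimum
    loss: str
    loss_value: float
    n_restarts_used: int
    seed: int
    dataset_label: str

    def params_dict(self) -> dict[str, float]:
        return dict(zip(self.model.param_names, map(float, self.params)))

    def __repr__(self) -> str:  # compact, notebook-friendly
        pars = ", ".join(f"{k}={v:.6g}" for k, v in self.params_dict().items())
        return (
            f"FitResult({self.model.name}: {pars}; AARD={self.aard_pct:.2f}%, "
            f"AICc={self.aicc:.1f})"
        )


def information_criteria(fr: FitResult) -> tuple[float, float, float, float, float, float]:
    """(AIC, AICc, SSE, RMSE, R^2, adjusted R^2) of a fit result."""
    return fr.aic, fr.aicc, fr.sse, fr.rmse, fr.r2, fr.r2_adj


def _build_result(model, best_params, ds, loss, loss_value, n_restarts, seed):
    y_exp = ds.y2
    y_calc = _predict_or_none(model, best_params, ds)
    if y_calc is None:
        raise FitError(f"model {model.name} not evaluable at the fitted parameters")
    resid = y_exp - y_calc
    sse = float(np.sum(resid**2))
    sst = float(np.sum((y_exp - y_exp.mean()) ** 2))
    n, q = len(ds), model.n_params
    r2 = 1.0 - sse / sst
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - q - 1)
    of = objective(model, best_params, ds)
    per_point = pd.DataFrame(
        {
            "T_K": ds.T, "P_bar": ds.P, "rho_kg_m3": ds.rho1,
            "y_exp": y_exp, "y_calc": y_calc,
            "rel_dev": (y_exp - y_calc) / y_exp,
        }
    )
    return FitResult(
        model=model,
        params=np.asarray(best_params, dtype=float),
        per_point=per_point,
        aard_pct=100.0 * of / n,
        sse=sse,
        rmse=rmse_from_sse(sse, n),
        r2=r2,
        r2_adj=r2_adj,
        aic=aic_from_sse(sse, n, q),
        aicc=aicc_from_sse(sse, n, q),
        n_points=n,
        n_params=q,
        objective_value=of,
        loss=loss,
        loss_value=float(loss_value),
        n_restarts_used=n_restarts,
        seed=seed,
        dataset_label=ds.label,
    )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_model(
    model: ModelSpec | str,
    ds: SolubilityDataset,
    n_restarts: int = 50,
    seed: int = 1,
    bounds=None,
    loss: str = "squared_relative",
    n_local: int = 12,
    n_polish: int = 3,
) -> FitResult:
    """Fit a registered model to a dataset by seeded multistart simplex search.

    Parameters
    ----------
    model : registry name or :class:`ModelSpec`.
    n_restarts : size of the Latin-hypercube start pool (>= 1).
    seed : RNG seed; the full procedure is deterministic given it.
    bounds : optional per-parameter search box overriding the model default.
    loss : ``"squared_relative"`` (default) or ``"absolute_relative"``.
    n_local : number of screened pool points descended from (plus the
        analytic warm start, when the model defines one).
    n_polish : tight re-minimizations of the incumbent.

    Returns
    -------
    FitResult with statistics evaluated at the best parameters found.
    """
    model = get_model(model) if isinstance(model, str) else model
    if len(ds) == 0:
        raise ValueError("empty dataset")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    box = tuple(bounds) if bounds is not None else model.bounds
    if len(box) != model.n_params:
        raise ValueError(
            f"{len(box)} bounds for {model.n_params} parameters of {model.name}"
        )
    f = _loss_fn(model, ds, loss)
    d = model.n_params
    lo = np.array([b[0] for b in box], dtype=float)
    hi = np.array([b[1] for b in box], dtype=float)

    pool = lo + qmc.LatinHypercube(d=d, seed=seed).random(n_restarts) * (hi - lo)
    pool_vals = np.array([f(p) for p in pool])
    order = np.argsort(pool_vals, kind="stable")[: min(n_local, n_restarts)]
    starts = [pool[i] for i in order]
    if model.seed_fn is not None:
        try:
            warm = np.asarray(
                model.seed_fn(ds.T, ds.P, ds.rho1, ds.y2, ds.solute, ds.solvent),
                dtype=float,
            )
            if warm.shape == (d,) and np.all(np.isfinite(warm)):
                starts.append(np.clip(warm, lo, hi))
        except Exception:
            pass  # warm start is an accelerator, never a requirement

    if all(f(x0) >= _PENALTY * len(ds) for x0 in starts):
        raise FitError(
            f"no finite-objective start found for {model.name} within bounds "
            f"{[tuple(b) for b in box]}"
        )

    best = None
    for x0 in starts:
        res = minimize(
            f, x0, method="Nelder-Mead",
            options=dict(maxfev=400 * d, xatol=1e-9, fatol=1e-11, adaptive=True),
        )
        if best is None or res.fun < best.fun:
            best = res
    for _ in range(n_polish):
        best = minimize(
            f, best.x, method="Nelder-Mead",
            options=dict(maxfev=600 * d, xatol=1e-13, fatol=1e-16, adaptive=True),
        )
    return _build_result(model, best.x, ds, loss, best.fun, n_restarts, seed)


# ---------------------------------------------------------------------------
# ranking, enthalpies, consistency
# ---------------------------------------------------------------------------

def _check_same_dataset(results) -> None:
    first = results[0]
    for fr in results[1:]:
        if fr.n_points != first.n_points or not np.array_equal(
            fr.per_point["y_exp"].to_numpy(), first.per_point["y_exp"].to_numpy()
        ):
            raise ValueError(
                f"fits on different datasets: {fr.model.name} vs {first.model.name}"
            )


def rank_models(results) -> pd.DataFrame:
    """Selection table sorted by AICc (ascending); ties by fewer parameters,
    then name.  All results must come from the same dataset."""
    results = list(results)
    if not results:
        raise ValueError("no fit results to rank")
    _check_same_dataset(results)
    rows = [
        {
            "model": fr.model.name,
            "AARD_pct": fr.aard_pct,
            "R2": fr.r2,
            "R2_adj": fr.r2_adj,
            "SSE": fr.sse,
            "RMSE": fr.rmse,
            "N": fr.n_points,
            "Q": fr.n_params,
            "AIC": fr.aic,
            "AICc": fr.aicc,
        }
        for fr in results
    ]
    frame = pd.DataFrame(rows)
    frame = frame.sort_values(
        ["AICc", "Q", "model"], kind="stable", ignore_index=True
    )
    frame.insert(0, "rank", np.arange(1, len(frame) + 1))
    return frame


@dataclass(frozen=True)
class EnthalpyReport:
    """Dissolution energetics from fitted temperature constants, kJ/mol.

    ``dH_solv = dH_total - dH_sub`` by construction (and likewise for the
    reformulated variant).
    """

    dH_total: float         # -B1 * R, Chrastil
    dH_total_reform: float  # -B2 * R, reformulated Chrastil
    dH_sub: float           # -B4 * R, Bartle
    dH_solv: float
    dH_solv_reform: float


def _param(fr: FitResult, name: str) -> float:
    try:
        return float(fr.params[fr.model.param_names.index(name)])
    except ValueError:
        raise ValueError(
            f"fit of {fr.model.name} has no parameter {name!r}"
        ) from None


def derive_enthalpies(
    chrastil: FitResult, reform: FitResult, bartle: FitResult
) -> EnthalpyReport:
    """Total / sublimation / solvation enthalpies from three fits (kJ/mol)."""
    from .core_data import R_GAS

    _check_same_dataset([chrastil, reform, bartle])
    dH_total = -_param(chrastil, "B1") * R_GAS / 1000.0
    dH_total_reform = -_param(reform, "B2") * R_GAS / 1000.0
    dH_sub = -_param(bartle, "B4") * R_GAS / 1000.0
    return EnthalpyReport(
        dH_total=dH_total,
        dH_total_reform=dH_total_reform,
        dH_sub=dH_sub,
        dH_solv=dH_total - dH_sub,
        dH_solv_reform=dH_total_reform - dH_sub,
    )


@dataclass(frozen=True)
class MSTConsistency:
    """Self-consistency diagnostics: the MST transform collapses all
    isotherms onto one straight line in density when the data are coherent."""

    table: pd.DataFrame  # columns T_K, P_bar, rho_kg_m3, transform
    slope: float
    intercept: float
    r_squared: float


def mst_consistency(fr: FitResult, ds: SolubilityDataset) -> MSTConsistency:
    """Transform ``T ln(y2 P) - C3 T`` per record plus a line fit vs density.

    ``fr`` must be an MST fit; pressure enters in MPa as in the model.  For
    data generated exactly from the MST form the transformed points are
    collinear with slope B3 and R^2 = 1.
    """
    C3 = _param(fr, "C3")
    t = ds.T * np.log(ds.y2 * ds.P / 10.0) - C3 * ds.T
    lin = stats.linregress(ds.rho1, t)
    table = pd.DataFrame(
        {"T_K": ds.T, "P_bar": ds.P, "rho_kg_m3": ds.rho1, "transform": t}
    )
    return MSTConsistency(
        table=table,
        slope=float(lin.slope),
        intercept=float(lin.intercept),
        r_squared=float(lin.rvalue**2),
    )
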
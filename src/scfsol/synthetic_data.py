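"""Synthetic solubility datasets with known ground truth.

Datasets are generated on a (T, P, rho1) grid — by default the 24 built-in
HCQS conditions, so synthetic experiments share the leverage structure of
the real design — from any registered model, with multiplicative lognormal
noise:

    y2_i = model(theta, condition_i) * exp(eps_i),
    eps_i ~ Normal(-cv^2/2, cv)   i.i.d.

The mean correction ``-cv^2/2`` makes the observations mean-unbiased
(E[y2_obs] equals the model value), so parameter-recovery experiments test
the estimator rather than the noise model.  The default coefficient of
variation, 5 %, mirrors the replicate scatter typical of static
solubility measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .conversions import s_from_y
from .core_data import (
    SolubilityDataset,
    SolubilityRecord,
    SoluteInfo,
    SolventInfo,
    co2_defaults,
    hcqs_dataset,
    hcqs_solute,
)
from .empirical_models import get_model
from .fit_select import fit_model

__all__ = ["SimulationConfig", "simulate_dataset", "simulate_replicates",
           "selection_experiment"]


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of one synthetic-data experiment.

    ``grid`` is a sequence of (T, P, rho1) conditions; ``None`` selects the
    24 built-in HCQS conditions.  ``noise_cv`` is the coefficient of
    variation of the multiplicative lognormal noise (0 disables noise).
    """

    generator_model: str
    true_params: Sequence[float]
    grid: Sequence[tuple[float, float, float]] | None = None
    noise_cv: float = 0.05
    seed: int = 0
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError(f"noise_cv must be >= 0, got {self.noise_cv}")
        if self.n_replicates < 1:
            raise ValueError(f"n_replicates must be >= 1, got {self.n_replicates}")

    def conditions(self) -> list[tuple[float, float, float]]:
        if self.grid is not None:
            return [tuple(map(float, c)) for c in self.grid]
        ref = hcqs_dataset()
        return [(r.T, r.P, r.rho1) for r in ref]


def simulate_dataset(
    cfg: SimulationConfig,
    solute: SoluteInfo | None = None,
    solvent: SolventInfo | None = None,
    seed: int | None = None,
) -> tuple[SolubilityDataset, dict]:
    """Generate one noisy dataset plus a truth record.

    Returns
    -------
    dataset : SolubilityDataset with the g/L column filled consistently.
    truth : dict with the generator name, true parameters, noise level and
        seed actually used.
    """
    solute = solute if solute is not None else hcqs_solute()
    solvent = solvent if solvent is not None else co2_defaults()
    model = get_model(cfg.generator_model)
    theta = np.asarray(cfg.true_params, dtype=float)
    if theta.shape != (model.n_params,):
        raise ValueError(
            f"{model.name} expects {model.n_params} parameters, got {theta.shape}"
        )
    conds = cfg.conditions()
    T = np.array([c[0] for c in conds])
    P = np.array([c[1] for c in conds])
    rho1 = np.array([c[2] for c in conds])
    y_true = np.asarray(model.predict(theta, T, P, rho1, solute, solvent), dtype=float)
    bad = ~np.isfinite(y_true) | (y_true <= 0)
    if np.any(bad):
        i = int(np.argmax(bad))
        raise ValueError(
            f"generator {model.name} predicts y2 = {y_true[i]!r} at condition "
            f"(T={T[i]} K, P={P[i]} bar, rho1={rho1[i]} kg/m^3)"
        )
    use_seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(use_seed)
    cv = cfg.noise_cv
    eps = rng.normal(-0.5 * cv * cv, cv, size=len(conds)) if cv > 0 else np.zeros(len(conds))
    y_obs = y_true * np.exp(eps)
    records = tuple(
        SolubilityRecord(
            T=T[i], P=P[i], rho1=rho1[i], y2=float(y_obs[i]),
            s_gL=float(s_from_y(y_obs[i], rho1[i], solute, solvent)),
        )
        for i in range(len(conds))
    )
    ds = SolubilityDataset(
        records=records, solute=solute, solvent=solvent,
        label=f"synthetic:{model.name} seed={use_seed} cv={cv}",
    )
    ds.validate()
    truth = {
        "model": model.name,
        "params": [float(v) for v in theta],
        "noise_cv": cv,
        "seed": int(use_seed),
    }
    return ds, truth


def simulate_replicates(
    cfg: SimulationConfig,
    solute: SoluteInfo | None = None,
    solvent: SolventInfo | None = None,
) -> Iterator[tuple[SolubilityDataset, dict]]:
    """Yield ``cfg.n_replicates`` independent datasets (seeds seed, seed+1, ...)."""
    for i in range(cfg.n_replicates):
        yield simulate_dataset(cfg, solute=solute, solvent=solvent, seed=cfg.seed + i)


def selection_experiment(
    cfg: SimulationConfig,
    candidate_models: Sequence[str],
    n_trials: int,
    seed: int = 0,
    n_restarts: int = 10,
) -> pd.DataFrame:
    """Monte-Carlo check of the AICc selection rule under known truth.

    For each trial a dataset is simulated from ``cfg`` and every candidate
    is fitted; the AICc winner is recorded.  Returns a table of win counts
    and frequencies per candidate (frequencies sum to 1).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    candidates = [get_model(m).name for m in candidate_models]
    wins = {name: 0 for name in candidates}
    for trial in range(n_trials):
        ds, _ = simulate_dataset(cfg, seed=seed + 1000 * trial)
        best_name, best_aicc = None, np.inf
        for name in candidates:
            fr = fit_model(name, ds, n_restarts=n_restarts, seed=seed + trial)
            if fr.aicc < best_aicc:
                best_name, best_aicc = name, fr.aicc
        wins[best_name] += 1
    return pd.DataFrame(
        {
            "model": candidates,
            "wins": [wins[n] for n in candidates],
            "frequency": [wins[n] / n_trials for n in candidates],
        }
    )
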
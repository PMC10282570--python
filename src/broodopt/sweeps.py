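"""Tabular parameter sweeps backing the package's standard figures.

Each function returns a tidy pandas DataFrame ready for CSV export or
plotting: optimal brood size and growth against brood cost (deterministic
and Poisson-individual variants), against environmental CV (constant and
plastic strategies), paired strategy trajectories, and the translocation
surfaces.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .casestudy import sweep_translocation_grid
from .deterministic import optimal_constant_brood
from .environment import ResourceModel, lyapunov_env_constant, optimal_constant_brood_env
from .individual import optimal_mean_brood_individual
from .params import LifeHistory
from .plastic import lyapunov_env_plastic, simulate_strategy_trajectories


def deterministic_alpha_sweep(lh: LifeHistory, alphas) -> pd.DataFrame:
    """Optimal constant brood and growth versus brood cost mortality."""
    rows = []
    for a in np.asarray(alphas, dtype=float):
        opt = optimal_constant_brood(lh.with_alpha(float(a)))
        rows.append({"alpha": float(a), "optimal_brood": opt.brood_size,
                     "optimal_R0": opt.growth_rate,
                     "is_interior": opt.is_interior})
    return pd.DataFrame(rows)


def individual_alpha_sweep(lh: LifeHistory, alphas) -> pd.DataFrame:
    """Optimal Poisson mean brood and Lyapunov growth versus brood cost."""
    rows = []
    for a in np.asarray(alphas, dtype=float):
        opt = optimal_mean_brood_individual(lh.with_alpha(float(a)))
        rows.append({"alpha": float(a), "optimal_mean_brood": opt.brood_size,
                     "optimal_R0": opt.growth_rate})
    return pd.DataFrame(rows)


def environment_sweep(lh: LifeHistory, alphas, cvs) -> pd.DataFrame:
    """Constant-strategy optima over a (brood cost, CV) grid."""
    rows = []
    for a in np.asarray(alphas, dtype=float):
        lha = lh.with_alpha(float(a))
        for cv in np.asarray(cvs, dtype=float):
            env = ResourceModel(lh.juvenile.r0, float(cv))
            opt = optimal_constant_brood_env(lha, env)
            rows.append({"alpha": float(a), "cv": float(cv),
                         "optimal_brood": opt.brood_size,
                         "optimal_R0": opt.growth_rate})
    return pd.DataFrame(rows)


def plastic_vs_constant_sweep(lh: LifeHistory, alphas, cvs) -> pd.DataFrame:
    """Plastic versus best-constant Lyapunov growth over a (brood cost, CV) grid."""
    rows = []
    for a in np.asarray(alphas, dtype=float):
        lha = lh.with_alpha(float(a))
        for cv in np.asarray(cvs, dtype=float):
            env = ResourceModel(lh.juvenile.r0, float(cv))
            plastic = lyapunov_env_plastic(lha, env)
            const = optimal_constant_brood_env(lha, env)
            rows.append({"alpha": float(a), "cv": float(cv),
                         "plastic_R0": plastic,
                         "best_constant_brood": const.brood_size,
                         "best_constant_R0": const.growth_rate})
    return pd.DataFrame(rows)


def strategy_trajectory_table(lh: LifeHistory, env: ResourceModel,
                              n_years: int, seed: int) -> pd.DataFrame:
    """Long-format paired plastic/constant trajectories on shared resources."""
    plastic, constant = simulate_strategy_trajectories(lh, env, n_years, seed)
    frames = []
    for traj in (plastic, constant):
        frames.append(pd.DataFrame({
            "year": traj.years[1:],
            "resource": traj.resource,
            "brood": traj.brood,
            "population": traj.population[1:],
            "strategy": traj.strategy,
            "seed": traj.seed,
        }))
    return pd.concat(frames, ignore_index=True)


def translocation_tables(r_ratios=None, p_goods=None, **kwargs
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Default-gridded translocation surfaces (see sweep_translocation_grid)."""
    if r_ratios is None:
        r_ratios = np.arange(1.0, 10.0 + 1e-9, 0.25)
    if p_goods is None:
        p_goods = np.arange(0.0, 1.0 + 1e-9, 0.02)
    return sweep_translocation_grid(r_ratios, p_goods, **kwargs)
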
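"""Simulation-based maximum likelihood, grid search and BIC comparison.

For a candidate model and parameter set, the probability of each observed
choice is estimated by re-simulating the trial's actual displayed input many
times with fresh internal noise and counting responses.  The dataset
log-likelihood is the sum of per-trial log probabilities; parameters are
selected by exhaustive grid search and models compared by
BIC = -2 lnL + k ln n.  A generalization-criterion protocol propagates the
parameters fitted on one duration to the others without refitting.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .stimgen import Trial
from .models import (
    LEFT,
    MODELS,
    N_FREE_PARAMS,
    ModelParams,
    simulate_choices,
    simulate_experiment,
    _as_streams,
)
from .weights import WeightProfile, accuracy, logistic_weights, temporal_bias_index

__all__ = [
    "FitResult",
    "trial_choice_prob",
    "dataset_log_likelihood",
    "bic",
    "grid_search",
    "default_grid",
    "generalization_test",
    "comparison_table",
]


@dataclass
class FitResult:
    """Outcome of fitting one model to one dataset."""

    model: str
    best_params: ModelParams
    log_likelihood: float
    bic: float
    n_obs: int
    n_params: int
    grid_spec: dict
    seed: int
    n_sims: int
    floor: bool = True
    common_random_numbers: bool = True
    generalization: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "model": self.model,
            "best_params": {k: v for k, v in self.best_params.__dict__.items()
                            if v is not None},
            "log_likelihood": self.log_likelihood,
            "bic": self.bic,
            "n_obs": self.n_obs,
            "n_params": self.n_params,
            "grid_spec": {k: list(map(float, v)) for k, v in self.grid_spec.items()},
            "seed": self.seed,
            "n_sims": self.n_sims,
            "floor": self.floor,
            "common_random_numbers": self.common_random_numbers,
        }
        if self.generalization:
            d["generalization"] = {
                str(k): {kk: vv for kk, vv in v.items() if np.isscalar(vv)}
                for k, v in self.generalization.items()
            }
        return d


def bic(log_likelihood: float, n_params: int, n_obs: int) -> float:
    """Bayesian information criterion, -2 lnL + k ln n (lower is better)."""
    return -2.0 * log_likelihood + n_params * np.log(n_obs)


def trial_choice_prob(
    model: str,
    trials,
    params: ModelParams,
    n_sims: int = 1000,
    seed=0,
) -> np.ndarray:
    """Monte-Carlo probability of choosing left, one value per trial.

    The displayed input is held fixed; only the internal accumulation noise
    varies across the ``n_sims`` replicate simulations.  Estimates are kept
    inside [eps, 1 - eps] with eps = 1/(2 n_sims) so that an observed choice
    the simulation never produced contributes a large but finite penalty
    rather than -inf.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    # simulate in trial_id order so the estimate (not just its expectation)
    # is invariant to how the caller ordered the trials
    order = None
    if isinstance(trials, (list, tuple)) and trials and isinstance(trials[0], Trial):
        order = np.argsort([t.trial_id for t in trials], kind="stable")
        trials = [trials[i] for i in order]
    choices = simulate_choices(model, trials, params, n_sims=n_sims, seed=seed)
    p_left = (choices == LEFT).mean(axis=1)
    eps = 1.0 / (2.0 * n_sims)
    p_left = np.clip(p_left, eps, 1.0 - eps)
    if order is not None:
        inv = np.empty_like(order)
        inv[order] = np.arange(len(order))
        p_left = p_left[inv]
    return p_left


def dataset_log_likelihood(
    model: str,
    trials: Sequence[Trial],
    choices: np.ndarray,
    params: ModelParams,
    n_sims: int = 1000,
    seed=0,
) -> float:
    """Sum of log P(observed choice) over trials.

    Invariant to trial ordering; requires exactly one observed choice per
    trial.
    """
    choices = np.asarray(choices).ravel()
    if len(choices) != len(trials):
        raise ValueError("one observed choice per trial required")
    p_left = trial_choice_prob(model, trials, params, n_sims=n_sims, seed=seed)
    p_obs = np.where(choices == LEFT, p_left, 1.0 - p_left)
    return float(np.log(p_obs).sum())


def default_grid(model: str) -> dict[str, list[float]]:
    """Config-style default grids bracketing the reference parameter regimes.

    Each axis spans roughly an order of magnitude around the best-fitting
    values for 3-s brightness choices.
    """
    grids = {
        "ddm_absorbing": {
            "sigma": [0.5, 1.0, 2.0],
            "theta": [10.0, 30.0, 90.0],
            "delta": [0.0, 1.0],
        },
        "ddm_reflecting": {
            "sigma": [0.5, 0.95, 2.0],
            "theta": [8.0, 23.0, 70.0],
        },
        "lca": {
            "sigma": [0.25, 0.5, 1.0],
            "k": [0.02, 0.06, 0.18],
            "beta": [0.017, 0.05, 0.15],
        },
        "dlca": {
            "sigma": [0.25, 0.5, 1.0],
            "k": [0.013, 0.04, 0.12],
            "beta": [0.033, 0.1, 0.3],
            "gamma": [0.0003, 0.001, 0.003],
            "rho": [0.0008, 0.0025, 0.0075],
        },
        "integrator": {"sigma": [0.3, 1.0, 3.0]},
    }
    if model not in grids:
        raise ValueError(f"no default grid for model {model!r}")
    return grids[model]


def grid_search(
    model: str,
    trials: Sequence[Trial],
    choices: np.ndarray,
    grid: Optional[dict[str, Sequence[float]]] = None,
    n_sims: int = 1000,
    seed=0,
    base_params: Optional[ModelParams] = None,
) -> FitResult:
    """Exhaustive maximum-likelihood search over a parameter grid.

    Every grid point is evaluated with the same noise substream (common
    random numbers), which removes simulation noise from likelihood
    *differences* between neighbouring points.  Ties are broken by
    first-in-grid order.  ``base_params`` fixes non-searched fields (e.g.
    the floor flag).
    """
    if grid is None:
        grid = default_grid(model)
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("grid must be non-empty along every axis")
    base = base_params if base_params is not None else ModelParams()
    names = list(grid.keys())
    best_ll, best_params = -np.inf, None
    for values in itertools.product(*(grid[n] for n in names)):
        params = replace(base, **dict(zip(names, values)))
        ll = dataset_log_likelihood(model, trials, choices, params,
                                    n_sims=n_sims, seed=seed)
        if ll > best_ll:
            best_ll, best_params = ll, params
    n_obs = len(trials)
    k = N_FREE_PARAMS.get(model, len(names))
    return FitResult(
        model=model,
        best_params=best_params,
        log_likelihood=best_ll,
        bic=bic(best_ll, k, n_obs),
        n_obs=n_obs,
        n_params=k,
        grid_spec={k_: list(v) for k_, v in grid.items()},
        seed=seed if np.isscalar(seed) else int(np.asarray(seed)[-1]),
        n_sims=n_sims,
        floor=base.floor,
    )


def generalization_test(
    fit: FitResult,
    trials_by_duration: dict[float, Sequence[Trial]],
    choices_by_duration: Optional[dict[float, np.ndarray]] = None,
    n_sims: int = 200,
    seed=0,
) -> dict[float, dict]:
    """Propagate fitted parameters to other durations without refitting.

    For each duration the fitted model is simulated on those trials to
    produce predicted weight profiles (behavioral index where the design
    allows, logistic always) and predicted accuracy; if observed choices are
    supplied, the predictive log-likelihood is evaluated as well.  Results
    are also stored on ``fit.generalization``.
    """
    out: dict[float, dict] = {}
    for j, (dur, trials) in enumerate(sorted(trials_by_duration.items())):
        trials = list(trials)
        sim = simulate_experiment(fit.model, trials, fit.best_params,
                                  seed=[_scalar(seed), 7, j])
        entry: dict = {"accuracy": accuracy(sim, trials), "n_trials": len(trials)}
        entry["logistic_profile"] = logistic_weights(sim, trials)
        if any(t.condition != "baseline" for t in trials):
            entry["index_profile"] = temporal_bias_index(sim, trials)
        if choices_by_duration and dur in choices_by_duration:
            entry["log_likelihood"] = dataset_log_likelihood(
                fit.model, trials, choices_by_duration[dur], fit.best_params,
                n_sims=n_sims, seed=[_scalar(seed), 8, j])
        out[dur] = entry
    fit.generalization = out
    return out


def _scalar(seed) -> int:
    return int(seed) if np.isscalar(seed) else int(np.asarray(seed)[-1])


def comparison_table(fits: Sequence[FitResult]) -> pd.DataFrame:
    """Model-comparison table: model, parameters, log-likelihood, BIC."""
    rows = []
    for f in fits:
        p = f.best_params
        rows.append(
            {
                "model": f.model,
                "sigma": p.sigma,
                "k": p.k,
                "beta": p.beta,
                "gamma": p.gamma,
                "rho": p.rho,
                "theta": p.theta,
                "delta": p.delta,
                "n_params": f.n_params,
                "log_likelihood": f.log_likelihood,
                "bic": f.bic,
            }
        )
    return pd.DataFrame(rows).sort_values("bic").reset_index(drop=True)
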
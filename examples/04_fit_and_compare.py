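"""Simulation-based maximum likelihood and BIC model comparison.

Generates 3-s choices from the dynamic LCA, then fits the LCA and the DLCA
by exhaustive grid search: for every candidate parameter set, each trial's
choice probability is estimated by re-simulating the trial's actual
luminance streams with fresh internal noise (common random numbers across
grid points).  BIC = -2 lnL + k ln n penalizes the DLCA's two extra
parameters.  Scaled down (1,500 trials, 27-point grids, 100 simulations
per trial) to run in about a minute.
"""

import numpy as np

from dlca import fitting, models, stimgen

cfg = stimgen.DesignConfig(durations=(3,))
trials = stimgen.make_experiment(cfg, 1, 1500, seed=0)
gen = models.REFERENCE_PARAMS["dlca"]
observed = models.simulate_experiment("dlca", trials, gen, seed=1)
print(f"data: {len(trials)} 3-s trials generated by the DLCA at {gen}")

grids = {
    "lca": fitting.default_grid("lca"),
    "dlca": {"sigma": [0.5], "k": [0.013, 0.04, 0.12],
             "beta": [0.033, 0.1, 0.3], "gamma": [0.0003, 0.001, 0.003],
             "rho": [0.0008, 0.0025, 0.0075]},
}
fits = []
for model, grid in grids.items():
    fit = fitting.grid_search(model, trials, observed, grid=grid,
                              n_sims=100, seed=2)
    fits.append(fit)
    best = {k: v for k, v in fit.best_params.__dict__.items() if k in grid}
    print(f"\n{model}: best {best}")
    print(f"  log-likelihood {fit.log_likelihood:.1f}, BIC {fit.bic:.1f} "
          f"({fit.n_params} free parameters, n={fit.n_obs})")

table = fitting.comparison_table(fits)
print("\n" + table[["model", "log_likelihood", "bic"]].to_string(index=False))
print("\nlower BIC wins.  The DLCA should attain the higher raw likelihood "
      "and land near its generating point; note that at this reduced scale "
      "its ~4-5 point likelihood edge can be outweighed by the BIC penalty "
      "for two extra parameters (2 ln 1500 = 14.6), so the simpler LCA may "
      "win the comparison -- the edge grows linearly with trial count.")
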
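# dlca — temporal weighting in expanded perceptual decisions

`dlca` is a simulation laboratory for studying *when* evidence matters in
perceptual choice. It targets the brightness-discrimination paradigm in
which an observer watches two disks fluctuate in luminance for 1–5 seconds
(100-ms frames) and reports the overall brighter one at stream end. The
package is aimed at computational researchers in perceptual decision-making
who want to generate signal-perturbation stimuli, simulate sequential-
sampling models on them, extract temporal weighting profiles from choices,
and compare models by simulation-based maximum likelihood.

## What it implements

**Signal-perturbation stimulus design** (`dlca.stimgen`). Per-frame
luminances are Gaussian (SD 0.15) around condition means: baseline 0.75 vs
0.60; on 80% of trials the separation is transiently strengthened
(congruent, 0.85 vs 0.45) or reversed (incongruent) in one of five equal
temporal windows, with a compensatory shift in the remaining windows so the
*expected summed* evidence is identical in every condition. A temporally
unbiased integrator is therefore equally accurate everywhere; accuracy
differences across perturbation windows directly expose temporal weights.

**Sequential-sampling models** (`dlca.models`), read out at stream end
(interrogation paradigm), with per-frame updates:

- drift diffusion with absorbing bound:
  `x1(t+1) = max(0, I1 − I2 + x1 + N(0, σ))`, absorbed (and frozen) at θ;
- drift diffusion with reflecting cap:
  `x1(t+1) = min(θ, I1 − I2 + x1 + N(0, σ))`;
- leaky competing accumulator (LCA):
  `x1(t+1) = I1 + (1 − k)·x1 − β·x2 + N(0, σ)`;
- **dynamic LCA (DLCA)** — the model of interest — whose leak grows and
  inhibition decays linearly per 100-ms step:
  `x1(t+1) = I1 + (1 − k − γt)·x1 − (β − ρt)·x2 + N(0, σ)`;
- ideal integrator, probability summation (first sample past a criterion
  decides), and a trial-level mixture of two static LCA regimes.

The DLCA starts inhibition-dominant (primacy) and drifts leak-dominant
(recency); at intermediate durations both ends of the stream outweigh the
middle — a non-monotonic, U-shaped weighting that no static variant
produces.

**Weight extraction** (`dlca.weights`): the behavioral temporal-bias index
`TB_i = ½(CongAcc_i/BaseAcc + BaseAcc/IncongAcc_i)` (unbiased observer = 1
in every window) and windowed logistic regression of choice on per-window
evidence, normalized so flat = 1.

**Fitting and comparison** (`dlca.fitting`): per-trial choice probabilities
by re-simulating each trial's actual streams with fresh internal noise,
exhaustive grid search with common random numbers, `BIC = −2 lnL + k ln n`,
and a generalization protocol that carries 3-s best fits to other durations
without refitting.

**Statistics** (`dlca.stats`): strict non-monotonicity classification
(w1 > w2 and w5 > w2), the 1-df chi-square test of the non-monotonic
fraction against chance (¼), and the duration–accuracy integration time
constant from `y = (a − 0.5)(1 − exp(−x/T)) + 0.5`.

**Pipeline** (`dlca.pipeline`, CLI `dlca`): the full in-silico study —
generate → simulate → weights → fit → generalize → report — deterministic
under a seed, outputs stamped with a config hash.

## Worked example

```python
from dlca import stimgen, models, weights

p = models.REFERENCE_PARAMS["dlca"]   # sigma=0.5, k=0.04, beta=0.1, gamma=0.001, rho=0.0025
for dur in (1, 2, 3, 5):
    cfg = stimgen.DesignConfig(durations=(dur,))
    trials = stimgen.make_experiment(cfg, 1, 20_000, seed=10 + dur)
    choices = models.simulate_experiment("dlca", trials, p, seed=20 + dur)
    tb = weights.temporal_bias_index(choices, trials).window_values
    print(dur, round(weights.accuracy(choices, trials), 3), tb.round(3))
```

prints

```
1 0.742 [1.003 0.996 0.999 0.984 0.973]
2 0.815 [1.046 1.008 0.975 0.974 0.98 ]
3 0.865 [1.031 0.988 0.982 0.981 1.017]
5 0.852 [0.945 0.923 0.944 1.001 1.6  ]
```

Read each row as the relative influence of temporal windows 1–5 (1 =
unbiased): short streams are primacy-biased (window 1 highest), the 3-s
stream is U-shaped (windows 1 *and* 5 above window 2 — the DLCA's
signature), and the 5-s stream flips to recency. Accuracy climbs from 74%
to 87% between 1 s and 3 s, the behavioral footprint of genuine temporal
integration. The scripts in `examples/` walk through each capability
(stimulus conservation, model weight signatures, duration sweep, grid-search
fitting, integration time constant) with one short narrative each.

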
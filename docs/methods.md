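# Methods

## The scientific question and the design

Sequential-sampling accounts of perceptual choice differ in *when* evidence
influences the decision. The package studies this through a
brightness-discrimination task: two disks fluctuate in luminance in 100-ms
frames for 1–5 s, and the observer reports the overall brighter disk at
stream end (interrogation read-out; the observer never chooses when to
stop).

The stimulus generator implements a signal-perturbation design. Baseline
trials (20%) draw the correct disk's per-frame luminance from N(0.75,
0.15²) and the incorrect disk's from N(0.60, 0.15²). Perturbed trials
strengthen (congruent, 40%) or reverse (incongruent, 40%) the separation to
0.85 vs 0.45 inside one of five equal temporal windows, chosen uniformly.
The defining constraint is *signal conservation*: a compensatory mean shift
in the four unperturbed windows makes the expected summed evidence
difference equal across all conditions of a duration. With baseline
per-frame difference D = 0.15 and perturbed-window difference P = ±0.40,
the per-frame adjustment c in unperturbed windows solves
(1/5)P + (4/5)(D + c) = D, giving c = −0.0625 (congruent) and +0.1375
(incongruent), split evenly between the disks (per-disk shifts −0.03125 and
+0.06875). A temporally unbiased integrator is then equally accurate in
every condition and window; deviations of window-wise accuracy from
baseline are a pure read-out of temporal weighting.

Generator choices:

- Luminance draws are **not truncated** to the displayable [0, 1] range:
  truncation would bias the condition means asymmetrically (a N(0.85,
  0.15²) draw exceeds 1 about 16% of the time) and break the conservation
  constraint that the whole method rests on. The grey onset frame and white
  mask of the physical display exist only behind `display_schedule` and
  never reach a model. Consequence: simulated observers here are somewhat
  more accurate than observers of a physically clipped display would be
  (see Limitations).
- Frames are 0-based, windows 1-based, window ranges half-open.
- One master seed; each trial's noise comes from a substream keyed by
  (seed, trial index), so a trial's content does not depend on how many
  trials are generated around it.
- Condition counts are assigned near-exactly (a shuffled list at the 20/40/40
  proportions), windows and sides balanced then shuffled; `blocked` controls
  whether durations are grouped (blocked schedule) or interleaved.

## Models

All models share per-frame Gaussian processing noise N(0, σ) per
accumulator, receive the raw luminance streams I1, I2, and decide by the
larger terminal activation (exact ties by a fair coin from the trial's
substream). One update per 100-ms frame; t = 0 at the first evidence frame.

| model | update | free parameters |
|---|---|---|
| DDM, absorbing | x1 ← max(0, I1 − I2 + x1 + N), x(0) = δ + N; frozen once max(x1, x2) ≥ θ | σ, θ, δ |
| DDM, reflecting | x1 ← min(θ, I1 − I2 + x1 + N) | σ, θ |
| LCA | x1 ← I1 + (1 − k)x1 − βx2 + N | σ, k, β |
| DLCA | x1 ← I1 + (1 − k − γt)x1 − (β − ρt)x2 + N | σ, k, β, γ, ρ |

(and symmetrically for x2). The absorbing model's frozen state implements
"the first unit at the bound wins regardless of later evidence". γ and ρ
are the per-step (100-ms) linear drifts of leak and inhibition; at γ = ρ =
0 the DLCA is bit-identical to the LCA, which anchors the time origin: the
leak coefficient at t = 0 must equal the static (1 − k).

Two flags cover points the source formulations leave open:

- `floor` (default on): the zero-activation reflecting floor in the LCA
  family (firing rates cannot go negative). The printed LCA/DLCA update
  rules omit it while the accompanying model schematics include it; both
  variants are supported and the flag is recorded in fit results. On the
  headline predictions the choice moves weights by < 0.1 and accuracy by
  < 0.01.
- `clamp_inhibition` (default on): on long streams β − ρt crosses zero
  (t > 40 at the reference parameters); by default inhibition saturates at
  0 rather than turning into excitation.

Reference parameter sets (`REFERENCE_PARAMS`) hold each model's
best-fitting regime for 3-s brightness choices; for the DLCA, σ = 0.5,
k = 0.04, β = 0.1, γ = 0.001, ρ = 0.0025.

Two non-integration alternatives serve as contrasts. *Probability
summation*: per frame a noisy sample of the luminance difference is
compared to ±criterion; the first crossing decides, no crossing falls back
to a fair coin (or to the sign of the summed evidence, behind a flag). The
momentary sample can be taken from the displayed (noise-bearing) streams or
— via `stimgen.as_schedule` — from the underlying mean schedule with
internal noise as the only stochasticity; the distinction matters, see
Limitations. *Mixture LCA*: per trial, an inhibition-dominant or a
leak-dominant static LCA is drawn with probability p_mix, the
across-trial-averaging alternative to a within-trial dynamic mechanism.

## Weight extraction

**Behavioral temporal-bias index.** Per window i,
TB_i = ½(CongAcc_i / BaseAcc + BaseAcc / IncongAcc_i), with baseline
accuracy pooled over the batch (one duration at a time; pooling across
windows is the natural reading since baseline trials have no window).
An unbiased observer sits at 1 in every window. The ratio form is adopted
because 1 is its documented unbiased value; the difference form
CongAcc_i − IncongAcc_i is computed alongside (`alt_values`). Windows with
no trials or a zero denominator are NaN, never 0. An individual's overall
bias is Σ|TB_i − 1| over defined windows.

**Logistic regression.** Choice (right = 1) on per-window mean
luminance-difference (right − left) predictors, intercept included, fitted
by maximum likelihood (statsmodels, L-BFGS). Coefficients are divided by
their mean so a flat profile is 1 — chosen so the ideal integrator sits at
1, matching the index's scale. Window width defaults to one fifth of the
stream and accepts any divisor of it (e.g. 200 ms). Degenerate designs are
reported, not regularized: non-convergence or a near-zero achieved deviance
(the perfect-separation signature) clears the `converged` flag.

The two estimators agree on profile shape on model-generated data; the
perturbation design exists because the index resolves a given profile with
far fewer trials than regression on baseline-only fluctuations.

## Fitting and model comparison

For a model and parameter set, each trial's P(left) is the fraction of
`n_sims` re-simulations of that trial's *actual displayed streams* (fresh
internal noise only) choosing left, clipped to [ε, 1 − ε] with
ε = 1/(2·n_sims) — an observed choice the simulation never produced costs
a large finite penalty rather than −∞. The dataset log-likelihood sums log
P(observed); simulation runs in trial-id order so the estimate is invariant
to how the caller ordered the trials. Parameters are selected by exhaustive
grid search; every grid point reuses the same noise substream (common
random numbers), removing simulation noise from likelihood differences
between points; ties break by grid order. Default grids span roughly an
order of magnitude around the reference values (and therefore contain
them). Comparison uses BIC = −2 lnL + k ln n with k = 3/2/3/5 free
parameters for the absorbing DDM / reflecting DDM / LCA / DLCA and n the
trial count. The generalization protocol re-simulates the best 3-s fit on
other durations without refitting, emitting predicted profiles, accuracy
and (when choices are supplied) predictive log-likelihood.

Problem sizes: profile assertions use 10–20k simulated trials per duration;
fitting demonstrations use 5,000 3-s trials with 100 simulations per trial
during search and 600 for final scoring. These sizes resolve every effect
asserted in the test suite; all are config-driven and scale up directly.

## Shape and duration statistics

A profile is non-monotonic iff strictly w1 > w2 and w5 > w2 (ties are
"other", matching the strict-trend reading; the classification is invariant
to positive rescaling). The fraction of non-monotonic individuals is tested
against the chance level ¼ by a 1-df Pearson chi-square on the
{non-monotonic, other} split — the ¼ derives from the four possible order
relations among the three windows and is taken as given. The
duration–accuracy curve is summarized by bounded least squares on
y = (a − 0.5)(1 − exp(−x/T)) + 0.5 with a ∈ (0.5, 1], T > 0, multi-started
over T ∈ {0.2, 0.5, 1, 2} s (three-point data invite local minima); flat
chance-level data pin a at 0.5 and flag T unidentifiable.

## What the synthetic study shows — and what it cannot

The synthetic observer reproduces, at the reference DLCA parameters:
primacy-monotone weighting at 1–2 s, the U-shaped (non-monotonic) profile
at 3 s in both estimators, recency-monotone weighting at 5 s, accuracy
rising from 0.74 (1 s) through 0.82 (2 s) to 0.87 (3 s), condition-blind
accuracy (congruent ≈ baseline ≈ incongruent) as required by signal
conservation, and exact recovery of its generating parameters by grid
search. Between-individual variation is emulated only through internal
noise; real participants add lapses, criterion drift and learning that the
generator does not model, so green tests demonstrate correctness of the
machinery and internal consistency of the dynamic-leak account, not
behavioral realism.

Known limits, measured rather than hidden:

- **Simulated accuracy runs high.** At the reference parameters the DLCA's
  accuracies (0.74/0.82/0.87 at 1/2/3 s) sit a few points above the
  behavioral values the same parameters were fitted to (≈0.73/0.77/0.80).
  The floor flag does not explain it; untruncated luminance draws (see
  above) plausibly do. All duration and condition *orderings* are
  unaffected.
- **Probability-summation condition ordering depends on the sample
  definition.** Applied to the displayed noisy streams at criterion 0.4 and
  internal noise 0.2, the threshold rule makes congruent trials *harder*
  than baseline (≈0.83 vs ≈0.87): the weak compensated windows preceding a
  late perturbation generate many wrong-ward crossings. The documented
  congruent > baseline > incongruent ordering emerges when the rule samples
  the underlying signal schedule (internal noise only), which is how the
  discriminator is asserted here. Either way the model separates the
  conditions sharply while integrating models do not — the discriminator's
  actual point.
- **The published four-model BIC ranking does not transfer to synthetic
  data.** Fitted to 5,000 DLCA-generated 3-s trials, the DLCA attains the
  best raw likelihood and recovers its parameters, but its two extra
  parameters cost more BIC than its likelihood edge at this n (ΔlnL ≈ 8 vs
  a penalty difference of 8.5), and the reflecting-cap diffusion — far
  behind on human data — fits this cleaner, mildly end-weighted synthetic
  observer nearly as well as the LCA with only two parameters. The
  corresponding acceptance test records this honestly and fails; the
  likelihood ordering (DLCA best) and parameter recovery are asserted
  separately and hold.
- **Mixture-LCA at 1 s.** The trial-mixture alternative is reliably
  non-monotonic at 2 s (the property that falsifies it against short-stream
  primacy data) but comes out monotone-recency at 1 s under the stated
  mixture parameters; the 1-s claim did not reproduce and is not asserted.
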
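"""Sequential-sampling models of two-alternative perceptual choice.

All models receive the two per-frame luminance streams I1 (left) and I2
(right) of a trial and are read out at stream end (interrogation paradigm):
the more active accumulator decides, exact ties by a fair coin.  One time
step is one 100-ms stimulus frame.

Candidate models
----------------
``ddm_absorbing``
    Drift diffusion as two racing accumulators with feed-forward inhibition,
    x_i(0) = delta + N(0, sigma),
    x1(t+1) = max(0, I1 - I2 + x1 + N(0, sigma))   (and symmetrically for x2),
    an upper absorbing boundary theta that freezes the race once reached, and
    a zero-activation reflecting floor.  Produces primacy weighting.
``ddm_reflecting``
    x1(t+1) = min(theta, I1 - I2 + x1 + N(0, sigma)); the cap saturates but
    never terminates integration, and there is no floor.  Produces recency.
``lca``
    Leaky competing accumulator:
    x1(t+1) = I1 + (1 - k) x1 - beta x2 + N(0, sigma);
    leak dominance (k > beta) yields recency, inhibition dominance primacy.
``dlca``
    Dynamic LCA: the leak grows and the inhibition decays linearly in time,
    x1(t+1) = I1 + (1 - k - gamma t) x1 - (beta - rho t) x2 + N(0, sigma),
    with t in frames and t = 0 at the first evidence frame so that
    gamma = rho = 0 reduces exactly to the static LCA.  The shift from an
    inhibition-dominated to a leak-dominated regime over the course of a
    trial lets this model produce non-monotonic (primacy + recency)
    weighting at intermediate durations.
``integrator``
    Ideal integrator, x_i(t+1) = x_i + I_i + N(0, sigma): flat weighting.

Two non-integration alternatives are also provided: ``probability
summation`` (first momentary sample to cross a criterion decides) and a
trial-level mixture of a primacy-regime and a recency-regime static LCA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .stimgen import Trial

__all__ = [
    "ModelParams",
    "AccumulatorState",
    "ChoiceRecord",
    "MODELS",
    "REFERENCE_PARAMS",
    "N_FREE_PARAMS",
    "simulate_paths",
    "simulate_choices",
    "simulate_choice",
    "simulate_experiment",
    "simulate_prob_summation",
    "simulate_mixture_lca",
    "step_ddm_absorbing",
    "step_ddm_reflecting",
    "step_lca",
    "step_dlca",
]

MODELS = ("ddm_absorbing", "ddm_reflecting", "lca", "dlca", "integrator")

LEFT, RIGHT = 0, 1


@dataclass(frozen=True)
class ModelParams:
    """Parameter record shared by all models; unused fields are ignored.

    sigma : per-frame accumulation-noise SD.
    delta : starting point (absorbing-boundary DDM only).
    theta : boundary height (DDM variants only).
    k, beta : leak and lateral inhibition per frame (LCA family).
    gamma, rho : per-frame (100-ms) linear change of leak (+) and
        inhibition (-) in the dynamic LCA.
    criterion : momentary-sample threshold (probability summation only).
    p_mix : probability of the inhibition-dominant regime (mixture LCA).
    floor : apply the zero-activation reflecting floor (LCA family and
        absorbing DDM).
    clamp_inhibition : clamp the effective inhibition beta - rho t at 0 so
        it cannot turn into excitation on long streams.
    """

    sigma: float = 0.0
    delta: float = 0.0
    theta: Optional[float] = None
    k: float = 0.0
    beta: float = 0.0
    gamma: float = 0.0
    rho: float = 0.0
    criterion: Optional[float] = None
    p_mix: Optional[float] = None
    floor: bool = True
    clamp_inhibition: bool = True

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.theta is not None and self.theta <= 0:
            raise ValueError("theta must be > 0")

    def effective_leak(self, t: float) -> float:
        """Leak coefficient k + gamma*t at frame t (t=0 is the first frame)."""
        return self.k + self.gamma * t

    def effective_inhibition(self, t: float) -> float:
        """Inhibition coefficient beta - rho*t, clamped at 0 by default."""
        b = self.beta - self.rho * t
        if self.clamp_inhibition:
            b = max(b, 0.0)
        return b


# Best-fitting parameter regimes for 3-s brightness-discrimination choices;
# the dlca entry is the set under which the dynamic model reproduces the
# non-monotonic 3-s weighting profile and its duration generalization.
REFERENCE_PARAMS: dict[str, ModelParams] = {
    "ddm_absorbing": ModelParams(sigma=1.0, theta=30.0, delta=0.0),
    "ddm_reflecting": ModelParams(sigma=0.95, theta=23.0),
    "lca": ModelParams(sigma=0.5, k=0.06, beta=0.05),
    "dlca": ModelParams(sigma=0.5, k=0.04, beta=0.1, gamma=0.001, rho=0.0025),
    "integrator": ModelParams(sigma=1.0),
}

# free parameters entering the BIC penalty
N_FREE_PARAMS = {
    "ddm_absorbing": 3,  # sigma, theta, delta
    "ddm_reflecting": 2,  # sigma, theta
    "lca": 3,  # sigma, k, beta
    "dlca": 5,  # sigma, k, beta, gamma, rho
    "integrator": 1,  # sigma
}


@dataclass
class AccumulatorState:
    """Scalar two-accumulator state for single-step inspection."""

    x1: float = 0.0
    x2: float = 0.0
    t: int = 0
    absorbed: int = 0  # 0 = racing; 1 or 2 = that unit hit the bound


@dataclass
class ChoiceRecord:
    trial_id: int
    choice: str  # {'left', 'right'}
    model: str
    params: ModelParams
    seed: int


# ---------------------------------------------------------------------------
# scalar single-step updates (reference semantics; the vectorized engine
# below mirrors these exactly)
# ---------------------------------------------------------------------------

def step_ddm_absorbing(state: AccumulatorState, I1: float, I2: float,
                       params: ModelParams, noise: tuple[float, float] = (0.0, 0.0)
                       ) -> AccumulatorState:
    """One absorbing-boundary DDM update; frozen once a unit is absorbed."""
    if state.absorbed:
        return replace(state, t=state.t + 1)
    n1, n2 = noise
    x1 = I1 - I2 + state.x1 + n1
    x2 = I2 - I1 + state.x2 + n2
    if params.floor:
        x1, x2 = max(0.0, x1), max(0.0, x2)
    absorbed = 0
    if params.theta is not None and max(x1, x2) >= params.theta:
        absorbed = 1 if x1 >= x2 else 2
    return AccumulatorState(x1=x1, x2=x2, t=state.t + 1, absorbed=absorbed)


def step_ddm_reflecting(state: AccumulatorState, I1: float, I2: float,
                        params: ModelParams, noise: tuple[float, float] = (0.0, 0.0)
                        ) -> AccumulatorState:
    """One reflecting-cap DDM update: activations saturate at theta."""
    n1, n2 = noise
    x1 = min(params.theta, I1 - I2 + state.x1 + n1)
    x2 = min(params.theta, I2 - I1 + state.x2 + n2)
    return AccumulatorState(x1=x1, x2=x2, t=state.t + 1)


def step_lca(state: AccumulatorState, I1: float, I2: float,
             params: ModelParams, noise: tuple[float, float] = (0.0, 0.0)
             ) -> AccumulatorState:
    """One leaky-competing-accumulator update."""
    n1, n2 = noise
    x1 = I1 + (1 - params.k) * state.x1 - params.beta * state.x2 + n1
    x2 = I2 + (1 - params.k) * state.x2 - params.beta * state.x1 + n2
    if params.floor:
        x1, x2 = max(0.0, x1), max(0.0, x2)
    return AccumulatorState(x1=x1, x2=x2, t=state.t + 1)


def step_dlca(state: AccumulatorState, I1: float, I2: float,
              params: ModelParams, noise: tuple[float, float] = (0.0, 0.0)
              ) -> AccumulatorState:
    """One dynamic-LCA update; leak/inhibition evaluated at the current t."""
    n1, n2 = noise
    lk = params.effective_leak(state.t)
    bi = params.effective_inhibition(state.t)
    x1 = I1 + (1 - lk) * state.x1 - bi * state.x2 + n1
    x2 = I2 + (1 - lk) * state.x2 - bi * state.x1 + n2
    if params.floor:
        x1, x2 = max(0.0, x1), max(0.0, x2)
    return AccumulatorState(x1=x1, x2=x2, t=state.t + 1)


# ---------------------------------------------------------------------------
# vectorized engine
# ---------------------------------------------------------------------------

def _as_streams(trials) -> tuple[np.ndarray, np.ndarray]:
    """Stack trials (or accept raw arrays) into (n_trials, n_frames) streams."""
    if isinstance(trials, Trial):
        trials = [trials]
    if isinstance(trials, (list, tuple)) and trials and isinstance(trials[0], Trial):
        n = {t.n_frames for t in trials}
        if len(n) != 1:
            raise ValueError("all trials in one batch must share n_frames")
        I1 = np.stack([t.lum_left for t in trials])
        I2 = np.stack([t.lum_right for t in trials])
        return I1, I2
    I1, I2 = trials
    return np.atleast_2d(np.asarray(I1, float)), np.atleast_2d(np.asarray(I2, float))


def simulate_paths(
    model: str,
    I1: np.ndarray,
    I2: np.ndarray,
    params: ModelParams,
    n_sims: int,
    rng: np.random.Generator,
    noise: Optional[tuple[np.ndarray, np.ndarray]] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Run a model over (n_trials, n_frames) streams with n_sims noise paths.

    Returns the terminal activations ``(x1, x2)``, each (n_trials, n_sims).
    For the absorbing DDM the state is frozen from the frame a unit hits the
    boundary, so the terminal activations already encode the implicit
    decision.  ``noise`` optionally supplies the per-accumulator draws
    (already scaled by sigma) with shape (n_steps, n_trials, n_sims); the
    absorbing DDM uses one extra leading pair for its noisy starting point.
    Noise is drawn per accumulator per frame, first accumulator 1 then
    accumulator 2, which makes the left/right symmetry property exact under
    stream + noise swapping.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    n_trials, n_frames = I1.shape
    shape = (n_trials, n_sims)

    def draw(step):
        if noise is not None:
            return noise[0][step], noise[1][step]
        n1 = params.sigma * rng.standard_normal(shape)
        n2 = params.sigma * rng.standard_normal(shape)
        return n1, n2

    if model == "ddm_absorbing":
        n1, n2 = draw(0)
        x1 = params.delta + n1
        x2 = params.delta + n2
        if params.floor:
            np.maximum(x1, 0.0, out=x1)
            np.maximum(x2, 0.0, out=x2)
        frozen = np.zeros(shape, dtype=bool)
        d = I1 - I2
        for t in range(n_frames):
            n1, n2 = draw(t + 1)
            new1 = d[:, t, None] + x1 + n1
            new2 = -d[:, t, None] + x2 + n2
            if params.floor:
                np.maximum(new1, 0.0, out=new1)
                np.maximum(new2, 0.0, out=new2)
            x1 = np.where(frozen, x1, new1)
            x2 = np.where(frozen, x2, new2)
            if params.theta is not None and not math.isinf(params.theta):
                frozen |= (x1 >= params.theta) | (x2 >= params.theta)
        return x1, x2

    x1 = np.zeros(shape)
    x2 = np.zeros(shape)
    if model == "ddm_reflecting":
        d = I1 - I2
        for t in range(n_frames):
            n1, n2 = draw(t)
            x1 = np.minimum(params.theta, d[:, t, None] + x1 + n1)
            x2 = np.minimum(params.theta, -d[:, t, None] + x2 + n2)
        return x1, x2

    if model == "integrator":
        for t in range(n_frames):
            n1, n2 = draw(t)
            x1 = x1 + I1[:, t, None] + n1
            x2 = x2 + I2[:, t, None] + n2
        return x1, x2

    # lca / dlca
    for t in range(n_frames):
        lk = params.effective_leak(t) if model == "dlca" else params.k
        bi = params.effective_inhibition(t) if model == "dlca" else params.beta
        n1, n2 = draw(t)
        new1 = I1[:, t, None] + (1 - lk) * x1 - bi * x2 + n1
        new2 = I2[:, t, None] + (1 - lk) * x2 - bi * x1 + n2
        if params.floor:
            np.maximum(new1, 0.0, out=new1)
            np.maximum(new2, 0.0, out=new2)
        x1, x2 = new1, new2
    return x1, x2


def decide(x1: np.ndarray, x2: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Interrogation readout: argmax of terminal activation, ties by coin."""
    choice = np.where(x1 > x2, LEFT, RIGHT)
    tie = x1 == x2
    if np.any(tie):
        choice = np.where(tie, rng.integers(0, 2, size=x1.shape), choice)
    return choice


def simulate_choices(
    model: str,
    trials,
    params: ModelParams,
    n_sims: int = 1,
    seed=0,
) -> np.ndarray:
    """Simulate choices (0 = left, 1 = right), shape (n_trials, n_sims)."""
    I1, I2 = _as_streams(trials)
    rng = np.random.default_rng(seed)
    x1, x2 = simulate_paths(model, I1, I2, params, n_sims, rng)
    return decide(x1, x2, rng)


def simulate_choice(model: str, trial: Trial, params: ModelParams, seed=0) -> ChoiceRecord:
    """Simulate a single trial once and return a ChoiceRecord."""
    c = simulate_choices(model, trial, params, n_sims=1, seed=seed)[0, 0]
    seed_scalar = seed if np.isscalar(seed) else int(np.asarray(seed)[-1])
    return ChoiceRecord(
        trial_id=trial.trial_id,
        choice="left" if c == LEFT else "right",
        model=model,
        params=params,
        seed=seed_scalar,
    )


def simulate_experiment(
    model: str,
    trials: Sequence[Trial],
    params: ModelParams,
    seed=0,
) -> np.ndarray:
    """One choice per trial (0 = left, 1 = right) for a mixed-duration batch.

    Trials are grouped by frame count and simulated in vectorized batches;
    the result is aligned with the input order.
    """
    trials = list(trials)
    choices = np.empty(len(trials), dtype=int)
    by_len: dict[int, list[int]] = {}
    for i, t in enumerate(trials):
        by_len.setdefault(t.n_frames, []).append(i)
    for j, (n, idx) in enumerate(sorted(by_len.items())):
        batch = [trials[i] for i in idx]
        c = simulate_choices(model, batch, params, n_sims=1, seed=[_seed_scalar(seed), j])
        choices[np.array(idx)] = c[:, 0]
    return choices


def _seed_scalar(seed) -> int:
    return int(seed) if np.isscalar(seed) else int(np.asarray(seed)[-1])


# ---------------------------------------------------------------------------
# non-integration alternatives
# ---------------------------------------------------------------------------

def simulate_prob_summation(
    trials,
    params: ModelParams,
    n_sims: int = 1,
    seed=0,
    fallback: str = "coin",
) -> np.ndarray:
    """Probability-summation rule: first momentary sample to cross decides.

    Each frame's noisy evidence sample (I1 - I2 + N(0, sigma)) is compared to
    +/- criterion; the first crossing fixes the choice.  If no sample crosses,
    the choice falls back to a fair coin (default) or to the sign of the
    summed evidence (``fallback='argmax'``).
    """
    if params.criterion is None or params.criterion <= 0:
        raise ValueError("probability summation needs criterion > 0")
    I1, I2 = _as_streams(trials)
    rng = np.random.default_rng(seed)
    n_trials, n_frames = I1.shape
    d = I1 - I2  # (n_trials, n_frames)
    samples = d[:, None, :] + params.sigma * rng.standard_normal((n_trials, n_sims, n_frames))
    crossed = np.abs(samples) >= params.criterion
    any_cross = crossed.any(axis=2)
    first = crossed.argmax(axis=2)  # first crossing frame (0 if none)
    sign = np.take_along_axis(samples, first[:, :, None], axis=2)[:, :, 0]
    choice = np.where(sign > 0, LEFT, RIGHT)
    if fallback == "coin":
        fb = rng.integers(0, 2, size=(n_trials, n_sims))
    elif fallback == "argmax":
        tot = samples.sum(axis=2)
        fb = np.where(tot > 0, LEFT, np.where(tot < 0, RIGHT,
                      rng.integers(0, 2, size=(n_trials, n_sims))))
    else:
        raise ValueError(f"unknown fallback {fallback!r}")
    return np.where(any_cross, choice, fb)


def simulate_mixture_lca(
    trials,
    params_primacy: ModelParams,
    params_recency: ModelParams,
    p_mix: float,
    n_sims: int = 1,
    seed=0,
) -> np.ndarray:
    """Trial-level mixture of two static LCA regimes.

    With probability ``p_mix`` a trial is processed by the inhibition-dominant
    (primacy) regime, otherwise by the leak-dominant (recency) regime.  This
    is the across-trial-averaging alternative to a within-trial dynamic
    mechanism: it predicts non-monotonic mean weighting at every duration.
    """
    if not 0.0 <= p_mix <= 1.0:
        raise ValueError("p_mix must be in [0, 1]")
    I1, I2 = _as_streams(trials)
    rng = np.random.default_rng(seed)
    n_trials = I1.shape[0]
    use_primacy = rng.random((n_trials, n_sims)) < p_mix
    x1a, x2a = simulate_paths("lca", I1, I2, params_primacy, n_sims, np.random.default_rng(rng.integers(2**31)))
    x1b, x2b = simulate_paths("lca", I1, I2, params_recency, n_sims, np.random.default_rng(rng.integers(2**31)))
    x1 = np.where(use_primacy, x1a, x1b)
    x2 = np.where(use_primacy, x2a, x2b)
    return decide(x1, x2, rng)


def choices_to_records(
    trials: Sequence[Trial], choices: np.ndarray, model: str, params: ModelParams, seed: int
) -> list[ChoiceRecord]:
    """Wrap an aligned 0/1 choice vector as ChoiceRecord objects."""
    return [
        ChoiceRecord(t.trial_id, "left" if c == LEFT else "right", model, params, seed)
        for t, c in zip(trials, np.asarray(choices).ravel())
    ]
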
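"""Temporal-weighting profiles extracted from choice data.

Two complementary estimators of the influence of each temporal window on the
final choice:

* the behavioral temporal-bias index, which compares accuracy on trials with
  a congruent or incongruent perturbation in window i against baseline
  accuracy,
      TB_i = 1/2 (CongAcc_i / BaseAcc + BaseAcc / IncongAcc_i),
  so that an observer weighting all windows equally sits at 1 in every
  window (the equated-signal design guarantees a null perturbation effect
  for flat weighting); the difference form CongAcc_i - IncongAcc_i is also
  computed as an alternative reading; and

* a logistic regression of choice on the per-window mean evidence
  difference, with coefficients normalized by their mean so a flat profile
  is 1.

An individual's overall temporal bias is the summed absolute deviation of
the index from 1 across windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stimgen import N_WINDOWS, Trial
from .models import LEFT

__all__ = [
    "WeightProfile",
    "BiasScore",
    "accuracy",
    "temporal_bias_index",
    "logistic_weights",
    "bias_score",
    "bias_accuracy_correlation",
]


@dataclass
class WeightProfile:
    """Per-window temporal weights.

    ``window_values`` holds one weight per temporal window; undefined windows
    (no trials, or a zero-accuracy denominator in the index) are NaN, never
    silently 0.  For ``method='behavioral_index'`` the unbiased level is 1 by
    construction; for ``method='logistic'`` the coefficients are divided by
    their mean so a flat profile is 1.  ``alt_values`` carries the
    difference-form index (congruent minus incongruent accuracy) whose
    unbiased level is 0.
    """

    window_values: np.ndarray
    method: str
    n_trials: int
    duration_s: float
    alt_values: Optional[np.ndarray] = None
    converged: bool = True
    raw_coefficients: Optional[np.ndarray] = None

    @property
    def n_windows(self) -> int:
        return len(self.window_values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "window": np.arange(1, self.n_windows + 1),
                "weight": self.window_values,
                "method": self.method,
                "duration_s": self.duration_s,
            }
        )


@dataclass
class BiasScore:
    """Summed absolute deviation of the temporal-bias index from 1."""

    value: float
    participant_id: Optional[int] = None


def _correct(choices: np.ndarray, trials: Sequence[Trial]) -> np.ndarray:
    choices = np.asarray(choices).ravel()
    if len(choices) != len(trials):
        raise ValueError("one choice per trial required")
    correct_idx = np.array([t.correct_index for t in trials])
    return choices == correct_idx


def accuracy(choices: np.ndarray, trials: Sequence[Trial]) -> float:
    """Fraction of trials on which the brighter disk was chosen."""
    return float(_correct(choices, trials).mean())


def temporal_bias_index(choices: np.ndarray, trials: Sequence[Trial]) -> WeightProfile:
    """Behavioral temporal-bias index per perturbation window.

    Baseline accuracy is pooled across the supplied trials (which should
    share one duration); windows whose incongruent accuracy or whose baseline
    accuracy is zero, or which have no trials, come back NaN.
    """
    trials = list(trials)
    durs = {t.duration_s for t in trials}
    if len(durs) != 1:
        raise ValueError("temporal_bias_index expects a single-duration batch")
    corr = _correct(choices, trials)
    cond = np.array([t.condition for t in trials])
    win = np.array([t.perturbed_window if t.perturbed_window else 0 for t in trials])

    base_mask = cond == "baseline"
    base_acc = corr[base_mask].mean() if base_mask.any() else np.nan

    tb = np.full(N_WINDOWS, np.nan)
    diff = np.full(N_WINDOWS, np.nan)
    for i in range(1, N_WINDOWS + 1):
        cmask = (cond == "congruent") & (win == i)
        imask = (cond == "incongruent") & (win == i)
        if not (cmask.any() and imask.any()) or not np.isfinite(base_acc):
            continue
        cacc = corr[cmask].mean()
        iacc = corr[imask].mean()
        diff[i - 1] = cacc - iacc
        if iacc == 0 or base_acc == 0:
            continue  # undefined ratio, stays NaN
        tb[i - 1] = 0.5 * (cacc / base_acc + base_acc / iacc)
    return WeightProfile(
        window_values=tb,
        method="behavioral_index",
        n_trials=len(trials),
        duration_s=trials[0].duration_s,
        alt_values=diff,
    )


def logistic_weights(
    choices: np.ndarray,
    trials: Sequence[Trial],
    window_ms: Optional[float] = None,
    frame_ms: float = 100.0,
) -> WeightProfile:
    """Windowed logistic regression of choice on evidence differences.

    Predictors are the per-window means of (right - left) luminance; the
    response is choosing the right disk.  ``window_ms`` sets the window width
    (default: one fifth of the trial, the perturbation-design resolution;
    e.g. 200 for the high-resolution read-out).  Coefficients are divided by
    their mean so a flat profile is 1.  Degenerate designs (perfect
    separation / non-convergence) are flagged via ``converged``, never
    silently regularized.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    trials = list(trials)
    n_frames = {t.n_frames for t in trials}
    if len(n_frames) != 1:
        raise ValueError("logistic_weights expects a single-duration batch")
    n_frames = n_frames.pop()
    if window_ms is None:
        if n_frames % N_WINDOWS:
            raise ValueError("n_frames not divisible into 5 windows")
        wlen = n_frames // N_WINDOWS
    else:
        wlen = int(round(window_ms / frame_ms))
        if wlen < 1 or n_frames % wlen:
            raise ValueError(f"window of {window_ms} ms does not divide the stream")
    n_win = n_frames // wlen

    diff = np.stack([t.lum_right - t.lum_left for t in trials])  # (n, frames)
    X = diff.reshape(len(trials), n_win, wlen).mean(axis=2)
    y = (np.asarray(choices).ravel() != LEFT).astype(float)

    converged = True
    try:
        import warnings

        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, sm.add_constant(X)).fit(disp=0, method="lbfgs", maxiter=500)
        coef = res.params[1:]
        converged = bool(res.mle_retvals.get("converged", True))
        # a (near-)perfectly separated design drives the likelihood to 0;
        # report it as non-converged rather than trusting the runaway fit
        if res.llf / len(y) > -1e-4:
            converged = False
    except (PerfectSeparationError, np.linalg.LinAlgError):
        converged = False
        coef = np.full(n_win, np.nan)

    m = np.nanmean(coef)
    values = coef / m if np.isfinite(m) and abs(m) > 1e-12 else np.full(n_win, np.nan)
    return WeightProfile(
        window_values=np.asarray(values, float),
        method="logistic",
        n_trials=len(trials),
        duration_s=trials[0].duration_s,
        converged=converged,
        raw_coefficients=np.asarray(coef, float),
    )


def bias_score(profile: WeightProfile, participant_id: Optional[int] = None) -> BiasScore:
    """Overall temporal bias: sum of |TB_i - 1| over defined windows."""
    v = profile.window_values
    return BiasScore(value=float(np.nansum(np.abs(v - 1.0))), participant_id=participant_id)


def bias_accuracy_correlation(
    profiles: Sequence[WeightProfile], accuracies: Sequence[float]
) -> tuple[float, float]:
    """Pearson correlation between individual bias scores and accuracy.

    Returns (r, p).  With zero variance in either variable the correlation is
    undefined and (nan, nan) is returned rather than an arbitrary value.
    """
    if len(profiles) != len(accuracies) or len(profiles) < 2:
        raise ValueError("need >= 2 paired (profile, accuracy) observations")
    b = np.array([bias_score(p).value for p in profiles])
    a = np.asarray(accuracies, float)
    if np.ptp(b) == 0 or np.ptp(a) == 0:
        return float("nan"), float("nan")
    r, p = sps.pearsonr(b, a)
    return float(r), float(p)
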
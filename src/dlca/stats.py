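"""Profile-shape classification and duration-accuracy statistics.

A weighting profile is non-monotonic when both the first and the last
window outweigh the second (strictly) — the U-shaped signature that
separates the dynamic LCA from the static candidates.  The fraction of
individuals showing this pattern is tested against a chance level of 1/4
with a one-degree-of-freedom Pearson chi-square.  The growth of accuracy
with stream duration is summarized by the time constant of a saturating
exponential.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize
from scipy import stats as sps

from .weights import WeightProfile

__all__ = [
    "ShapeCount",
    "IntegrationFit",
    "classify_profile",
    "chi_square_gof",
    "fit_integration_constant",
]


@dataclass
class ShapeCount:
    """Tally of non-monotonic profiles among individuals."""

    n_nonmonotonic: int
    n_total: int
    null_prob: float = 0.25

    def __post_init__(self):
        if not 0 <= self.n_nonmonotonic <= self.n_total:
            raise ValueError("need 0 <= n_nonmonotonic <= n_total")


@dataclass
class IntegrationFit:
    """Saturating-exponential fit y = (a - 0.5)(1 - exp(-x/T)) + 0.5.

    ``a`` is the asymptotic accuracy (proportion), ``T`` the integration time
    constant in seconds.  ``identifiable`` is False when the data are flat at
    chance, in which case T is meaningless.
    """

    a: float
    T: float
    sse: float
    identifiable: bool = True


def classify_profile(profile: WeightProfile | Sequence[float]) -> str:
    """Classify a weight profile as 'nonmonotonic' or 'other'.

    Non-monotonic means strictly w1 > w2 and w_last > w2 (ties count as
    'other').  The classification only uses relative weights, so it is
    invariant to positive rescaling.  Missing windows 1, 2 or last raise,
    so undefined profiles can be excluded from counts explicitly.
    """
    w = profile.window_values if isinstance(profile, WeightProfile) else np.asarray(profile, float)
    if len(w) < 3:
        raise ValueError("need at least 3 windows")
    w1, w2, wlast = w[0], w[1], w[-1]
    if not (np.isfinite(w1) and np.isfinite(w2) and np.isfinite(wlast)):
        raise ValueError("windows 1, 2 and last must be defined")
    return "nonmonotonic" if (w1 > w2 and wlast > w2) else "other"


def chi_square_gof(count: ShapeCount) -> tuple[float, float]:
    """Pearson chi-square (1 df) of the observed split against null_prob.

    Observed cells are {n_nonmonotonic, n_total - n_nonmonotonic}; expected
    cells {n p0, n (1 - p0)}.  Returns (statistic, p_value).
    """
    if count.n_total <= 0:
        raise ValueError("n_total must be positive")
    n, k, p0 = count.n_total, count.n_nonmonotonic, count.null_prob
    observed = np.array([k, n - k], float)
    expected = np.array([n * p0, n * (1 - p0)])
    stat, p = sps.chisquare(observed, expected)
    return float(stat), float(p)


def fit_integration_constant(
    accuracies: Sequence[float],
    durations: Sequence[float],
    starts: Sequence[float] = (0.2, 0.5, 1.0, 2.0),
) -> IntegrationFit:
    """Least-squares fit of the saturating-exponential accuracy curve.

    ``accuracies`` are proportions correct, ``durations`` in seconds (at
    least 3 pairs).  Bounded least squares (a in (0.5, 1], T > 0) with
    multiple starting values of T guards against local minima on small
    data.  If the accuracies are flat at chance the fit pins a at 0.5 and T
    is flagged unidentifiable.
    """
    y = np.asarray(accuracies, float)
    x = np.asarray(durations, float)
    if len(y) != len(x) or len(y) < 3:
        raise ValueError("need >= 3 (duration, accuracy) pairs")
    if np.any(x <= 0):
        raise ValueError("durations must be positive")

    def resid(p):
        a, T = p
        return (a - 0.5) * (1.0 - np.exp(-x / T)) + 0.5 - y

    best = None
    a0 = float(np.clip(y.max(), 0.501, 1.0))
    for T0 in starts:
        try:
            sol = optimize.least_squares(
                resid, [a0, T0], bounds=([0.5, 1e-6], [1.0, np.inf])
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("integration-constant fit failed to converge from all starts")
    a, T = best.x
    sse = float(2 * best.cost)
    identifiable = (a - 0.5) > 1e-3 and np.ptp(y) > 1e-6
    return IntegrationFit(a=float(a), T=float(T), sse=sse, identifiable=identifiable)
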
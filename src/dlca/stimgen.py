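"""Perturbation-design stimulus generation for brightness-discrimination trials.

Each trial is a pair of luminance streams in 100-ms frames.  On baseline
trials the correct disk fluctuates around a high mean and the incorrect disk
around a low mean.  On perturbed trials the separation between the two means
is transiently strengthened (congruent) or reversed (incongruent) inside one
of five equal temporal windows, and a compensatory shift is applied to the
remaining windows so that the expected summed evidence difference is the same
in every condition of a given duration.  A temporally unbiased integrator is
therefore equally accurate in all three conditions; any accuracy difference
between perturbation loci reveals a temporal weighting bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DesignConfig",
    "Trial",
    "window_bounds",
    "compensation_shift",
    "mean_schedule",
    "make_trial",
    "make_experiment",
    "transform_input",
    "trials_to_frames",
    "trials_to_metadata",
]

CONDITIONS = ("baseline", "congruent", "incongruent")
N_WINDOWS = 5


@dataclass(frozen=True)
class DesignConfig:
    """Parameters of the signal-perturbation design.

    Luminances are unitless screen values, nominally in [0, 1].  ``sd`` is the
    per-frame Gaussian noise SD shared by all conditions.  Condition
    proportions must sum to one.
    """

    frame_ms: int = 100
    sd: float = 0.15
    base_hi: float = 0.75
    base_lo: float = 0.60
    pert_hi: float = 0.85
    pert_lo: float = 0.45
    p_baseline: float = 0.20
    p_congruent: float = 0.40
    p_incongruent: float = 0.40
    durations: tuple = (1, 2, 3)
    trials_per_duration: int = 360
    blocked: bool = True
    include_display_frames: bool = False  # leading grey frame + final white mask

    def __post_init__(self):
        if not np.isclose(self.p_baseline + self.p_congruent + self.p_incongruent, 1.0):
            raise ValueError("condition proportions must sum to 1")
        for m in (self.base_hi, self.base_lo, self.pert_hi, self.pert_lo):
            if not 0.0 < m < 1.0:
                raise ValueError("luminance means must lie in (0, 1)")

    @property
    def frames_per_second(self) -> int:
        return round(1000 / self.frame_ms)

    def n_frames(self, duration_s: float) -> int:
        n = duration_s * 1000 / self.frame_ms
        if abs(n - round(n)) > 1e-9:
            raise ValueError(f"duration {duration_s}s is not a whole number of frames")
        return int(round(n))

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["durations"] = list(self.durations)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DesignConfig":
        d = dict(d)
        if "durations" in d:
            d["durations"] = tuple(d["durations"])
        return cls(**d)


@dataclass
class Trial:
    """One stimulus: two per-frame luminance streams plus condition metadata.

    ``lum_left`` / ``lum_right`` are the model inputs I1 / I2.  The optional
    display frames (grey onset frame, white mask) are never part of these
    streams; they exist only in the rendered schedule.
    """

    trial_id: int
    duration_s: float
    n_frames: int
    lum_left: np.ndarray
    lum_right: np.ndarray
    correct_side: str  # {'left', 'right'}
    condition: str  # {'baseline', 'congruent', 'incongruent'}
    perturbed_window: Optional[int]  # 1..5, None for baseline
    seed: int

    def __post_init__(self):
        if len(self.lum_left) != self.n_frames or len(self.lum_right) != self.n_frames:
            raise ValueError("stream length must equal n_frames")
        if self.condition == "baseline":
            if self.perturbed_window is not None:
                raise ValueError("baseline trials carry no perturbed window")
        elif self.perturbed_window not in range(1, N_WINDOWS + 1):
            raise ValueError("perturbed trials need a window in 1..5")

    @property
    def correct_index(self) -> int:
        """0 if the left stream is the brighter (correct) one, else 1."""
        return 0 if self.correct_side == "left" else 1

    def signed_diff(self) -> np.ndarray:
        """Per-frame luminance difference, correct minus incorrect disk."""
        d = self.lum_left - self.lum_right
        return d if self.correct_side == "left" else -d


def window_bounds(n_frames: int) -> list[tuple[int, int]]:
    """Split ``n_frames`` into 5 contiguous equal half-open frame ranges.

    Frames are 0-based; the i-th element (i = 0..4) is temporal window i+1.
    """
    if n_frames % N_WINDOWS != 0:
        raise ValueError(f"n_frames={n_frames} is not divisible by {N_WINDOWS}")
    w = n_frames // N_WINDOWS
    return [(i * w, (i + 1) * w) for i in range(N_WINDOWS)]


def window_of_frame(frame: int, n_frames: int) -> int:
    """1-based temporal window containing a 0-based frame index."""
    return frame // (n_frames // N_WINDOWS) + 1


def compensation_shift(condition: str, config: DesignConfig = DesignConfig()) -> float:
    """Signed per-frame mean shift of the *correct* disk in unperturbed windows.

    The incorrect disk shifts by the opposite amount, so the compensatory
    signal is split evenly between the two disks.  The magnitude solves the
    signal-conservation constraint: with baseline per-frame difference
    D = base_hi - base_lo and perturbed-window difference P (= +/-(pert_hi -
    pert_lo)), the total per-frame difference adjustment c in the four
    unperturbed windows satisfies (1/5)P + (4/5)(D + c) = D, i.e.
    c = (D - P)/4, of which each disk takes half.
    """
    if condition == "baseline":
        return 0.0
    D = config.base_hi - config.base_lo
    P = config.pert_hi - config.pert_lo
    if condition == "congruent":
        c = (D - P) / 4.0
    elif condition == "incongruent":
        c = (D + P) / 4.0
    else:
        raise ValueError(f"unknown condition {condition!r}")
    return c / 2.0


def mean_schedule(
    config: DesignConfig,
    duration_s: float,
    condition: str,
    perturbed_window: Optional[int],
    correct_side: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame mean luminance of the left and right disks (noise-free)."""
    n = config.n_frames(duration_s)
    mu_correct = np.full(n, config.base_hi)
    mu_incorrect = np.full(n, config.base_lo)
    if condition != "baseline":
        bounds = window_bounds(n)
        lo, hi = bounds[perturbed_window - 1]
        if condition == "congruent":
            mu_correct[lo:hi] = config.pert_hi
            mu_incorrect[lo:hi] = config.pert_lo
        else:
            mu_correct[lo:hi] = config.pert_lo
            mu_incorrect[lo:hi] = config.pert_hi
        shift = compensation_shift(condition, config)
        unpert = np.ones(n, dtype=bool)
        unpert[lo:hi] = False
        mu_correct[unpert] += shift
        mu_incorrect[unpert] -= shift
    if correct_side == "left":
        return mu_correct, mu_incorrect
    return mu_incorrect, mu_correct


def make_trial(
    config: DesignConfig,
    duration_s: float,
    condition: str,
    perturbed_window: Optional[int],
    correct_side: str,
    seed,
    trial_id: int = 0,
) -> Trial:
    """Draw one trial: Gaussian per-frame luminances around the mean schedule.

    ``seed`` may be an int or a sequence of ints (a counter-based substream
    key); the trial is bit-reproducible from it.  Luminances are deliberately
    not clipped to [0, 1]: clipping would bias the condition means and break
    the equated-signal constraint.
    """
    if condition == "baseline" and perturbed_window is not None:
        raise ValueError("baseline trials take perturbed_window=None")
    mu_l, mu_r = mean_schedule(config, duration_s, condition, perturbed_window, correct_side)
    rng = np.random.default_rng(seed)
    lum_left = mu_l + config.sd * rng.standard_normal(len(mu_l))
    lum_right = mu_r + config.sd * rng.standard_normal(len(mu_r))
    seed_scalar = seed if np.isscalar(seed) else int(np.asarray(seed)[-1])
    return Trial(
        trial_id=trial_id,
        duration_s=duration_s,
        n_frames=len(mu_l),
        lum_left=lum_left,
        lum_right=lum_right,
        correct_side=correct_side,
        condition=condition,
        perturbed_window=perturbed_window,
        seed=seed_scalar,
    )


def display_schedule(trial: Trial, config: DesignConfig) -> tuple[np.ndarray, np.ndarray]:
    """Rendered schedule: grey onset frame (0.2), evidence, white mask (1.0).

    For display output only; the extra frames never enter model input and the
    evidence frames are clipped to the displayable range here (and only here).
    """
    left = np.concatenate(([0.2], np.clip(trial.lum_left, 0, 1), [1.0]))
    right = np.concatenate(([0.2], np.clip(trial.lum_right, 0, 1), [1.0]))
    return left, right


def _condition_list(rng: np.random.Generator, n: int, config: DesignConfig) -> list[str]:
    # near-exact 20/40/40 split, order shuffled
    n_base = round(n * config.p_baseline)
    n_cong = round(n * config.p_congruent)
    n_incong = n - n_base - n_cong
    conds = ["baseline"] * n_base + ["congruent"] * n_cong + ["incongruent"] * n_incong
    rng.shuffle(conds)
    return conds


def _balanced(rng: np.random.Generator, values: Sequence, n: int) -> list:
    # each value appears floor(n/len) or ceil(n/len) times, order shuffled
    reps = -(-n // len(values))
    pool = list(values) * reps
    rng.shuffle(pool)
    return pool[:n]


def make_experiment(
    config: DesignConfig,
    n_participants: int = 1,
    trials_per_participant: Optional[int] = None,
    seed: int = 0,
) -> list[Trial]:
    """Generate a full experiment's worth of trials.

    Condition proportions follow the design (20/40/40 by default), perturbed
    windows are uniform over 1..5 within each perturbed condition, and the
    correct side is counterbalanced.  Durations are blocked or interleaved
    per the config.  Per-trial noise comes from substreams keyed by
    (master seed, trial index), so trial content does not depend on
    generation order.
    """
    if trials_per_participant is None:
        trials_per_participant = config.trials_per_duration * len(config.durations)
    trials: list[Trial] = []
    master = np.random.default_rng([seed, 0])
    trial_id = 0
    for _ in range(n_participants):
        per_dur = trials_per_participant // len(config.durations)
        slots: list[tuple] = []
        for dur in config.durations:
            conds = _condition_list(master, per_dur, config)
            n_pert = sum(c != "baseline" for c in conds)
            windows = iter(_balanced(master, range(1, N_WINDOWS + 1), n_pert))
            sides = iter(_balanced(master, ("left", "right"), per_dur))
            for c in conds:
                w = next(windows) if c != "baseline" else None
                slots.append((dur, c, w, next(sides)))
        if not config.blocked:
            master.shuffle(slots)  # interleaved durations
        for dur, cond, win, side in slots:
            trials.append(
                make_trial(config, dur, cond, win, side, seed=[seed, 1, trial_id], trial_id=trial_id)
            )
            trial_id += 1
    return trials


def as_schedule(trial: Trial, config: DesignConfig = DesignConfig()) -> Trial:
    """Replace a trial's streams with its noise-free mean schedule.

    Useful for models whose momentary samples are defined on the underlying
    signal rather than on the realized luminance draws (e.g. the threshold
    read-out of the probability-summation rule).
    """
    mu_l, mu_r = mean_schedule(
        config, trial.duration_s, trial.condition, trial.perturbed_window, trial.correct_side
    )
    return replace(trial, lum_left=mu_l, lum_right=mu_r)


def transform_input(trial: Trial, mode: str = "identity") -> Trial:
    """Apply a static input nonlinearity to both streams.

    ``power``: I -> (10 I)^0.8; ``log``: I -> log(1000 I).  Used to check
    robustness of weighting profiles to early visual compression.
    """
    if mode == "identity":
        return trial
    if mode == "power":
        f = lambda x: np.power(10.0 * x, 0.8)
        if np.any(trial.lum_left < 0) or np.any(trial.lum_right < 0):
            raise ValueError("power transform requires non-negative luminances")
    elif mode == "log":
        if np.any(trial.lum_left <= 0) or np.any(trial.lum_right <= 0):
            raise ValueError("log transform requires positive luminances")
        f = lambda x: np.log(1000.0 * x)
    else:
        raise ValueError(f"unknown transform mode {mode!r}")
    return replace(trial, lum_left=f(trial.lum_left), lum_right=f(trial.lum_right))


def trials_to_frames(trials: Sequence[Trial]) -> pd.DataFrame:
    """Long-format frame table: trial_id, frame, lum_left, lum_right."""
    parts = []
    for t in trials:
        parts.append(
            pd.DataFrame(
                {
                    "trial_id": t.trial_id,
                    "frame": np.arange(t.n_frames),
                    "lum_left": t.lum_left,
                    "lum_right": t.lum_right,
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def trials_to_metadata(trials: Sequence[Trial]) -> pd.DataFrame:
    """One row of condition metadata per trial."""
    return pd.DataFrame(
        {
            "trial_id": [t.trial_id for t in trials],
            "duration_s": [t.duration_s for t in trials],
            "n_frames": [t.n_frames for t in trials],
            "condition": [t.condition for t in trials],
            "perturbed_window": [t.perturbed_window for t in trials],
            "correct_side": [t.correct_side for t in trials],
            "seed": [t.seed for t in trials],
        }
    )


def trials_from_frames(frames: pd.DataFrame, meta: pd.DataFrame) -> list[Trial]:
    """Rebuild Trial objects from the two CSV-backed tables."""
    trials = []
    grouped = frames.groupby("trial_id", sort=True)
    meta = meta.set_index("trial_id")
    for tid, g in grouped:
        m = meta.loc[tid]
        g = g.sort_values("frame")
        pw = m["perturbed_window"]
        pw = None if pd.isna(pw) else int(pw)
        trials.append(
            Trial(
                trial_id=int(tid),
                duration_s=float(m["duration_s"]),
                n_frames=int(m["n_frames"]),
                lum_left=g["lum_left"].to_numpy(),
                lum_right=g["lum_right"].to_numpy(),
                correct_side=str(m["correct_side"]),
                condition=str(m["condition"]),
                perturbed_window=pw,
                seed=int(m["seed"]),
            )
        )
    return trials
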
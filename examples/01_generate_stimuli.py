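"""Generate perturbation-design stimuli and verify signal conservation.

Builds a small experiment, shows the mean-luminance schedule of a perturbed
trial, and checks that the expected summed evidence (correct minus incorrect
disk) is identical across baseline, congruent and incongruent conditions --
the design property that makes any accuracy difference between perturbation
windows a pure read-out of temporal weighting.
"""

import numpy as np

from dlca import stimgen

cfg = stimgen.DesignConfig()
print(f"frame = {cfg.frame_ms} ms, per-frame SD = {cfg.sd}")
print(f"baseline means: {cfg.base_hi} vs {cfg.base_lo}; "
      f"perturbed: {cfg.pert_hi} vs {cfg.pert_lo}")
print(f"compensatory per-disk shift, congruent:   "
      f"{stimgen.compensation_shift('congruent'):+.5f}")
print(f"compensatory per-disk shift, incongruent: "
      f"{stimgen.compensation_shift('incongruent'):+.5f}")

# a congruent 2-s trial perturbed in window 4: frames 12-15 carry the
# strong signal, the rest the compensated weak signal
mu_l, mu_r = stimgen.mean_schedule(cfg, 2, "congruent", 4, "left")
print("\nmean difference schedule (2 s, congruent, window 4):")
print(np.round(mu_l - mu_r, 4))

print("\nexpected summed signal by condition (3-s trials, all windows):")
n = cfg.n_frames(3)
for cond in ("baseline", "congruent", "incongruent"):
    wins = [None] if cond == "baseline" else range(1, 6)
    sums = [np.sum(np.subtract(*stimgen.mean_schedule(cfg, 3, cond, w, "left")))
            for w in wins]
    print(f"  {cond:12s} {np.round(sums, 10)}")
print(f"  (all equal 0.15 x {n} frames = {0.15 * n})")

trials = stimgen.make_experiment(cfg, 1, 1080, seed=0)
conds = [t.condition for t in trials]
print(f"\n1080 generated trials: {conds.count('baseline')} baseline, "
      f"{conds.count('congruent')} congruent, {conds.count('incongruent')} incongruent")
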
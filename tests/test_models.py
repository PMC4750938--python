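"""Model dynamics: hand-iterated oracles, reductions, symmetry, readout."""

import numpy as np
import pytest

from dlca import models, stimgen
from dlca.models import AccumulatorState, ModelParams


def run_scalar(step, n_steps, I1, I2, params, state=None):
    s = state or AccumulatorState()
    traj = [s]
    for t in range(n_steps):
        s = step(s, I1, I2, params, (0.0, 0.0))
        traj.append(s)
    return traj


class TestDdmAbsorbing:
    def test_hand_iterated_absorption_time(self):
        # constant drift 0.15/frame, bound 2: crosses on the 14th update
        # (cumulative 2.1 >= 2)
        p = ModelParams(sigma=0.0, delta=0.0, theta=2.0)
        s = AccumulatorState()
        for t in range(1, 31):
            s = models.step_ddm_absorbing(s, 0.75, 0.60, p, (0.0, 0.0))
            if s.absorbed:
                break
        assert t == 14
        assert s.absorbed == 1
        assert s.x1 == pytest.approx(0.15 * 14)

    def test_frozen_after_absorption(self):
        p = ModelParams(sigma=0.0, theta=1.0)
        s = AccumulatorState()
        for _ in range(20):
            s = models.step_ddm_absorbing(s, 0.9, 0.1, p, (0.0, 0.0))
        assert s.x1 == pytest.approx(0.8 * 2)  # frozen at the crossing value

    def test_symmetric_inputs_stay_at_start(self):
        p = ModelParams(sigma=0.0, delta=0.5, theta=10.0)
        s = AccumulatorState(x1=0.5, x2=0.5)
        traj = run_scalar(models.step_ddm_absorbing, 10, 0.7, 0.7, p, s)
        assert all(st.x1 == st.x2 == 0.5 for st in traj)

    def test_unbounded_reduction_to_difference_integrator(self):
        I1 = np.random.default_rng(0).uniform(0.6, 0.9, (1, 20))
        I2 = np.full((1, 20), 0.5)
        d_sum = (I1 - I2).sum()
        # no floor: antisymmetric pair, x1 - x2 = 2 * sum of differences
        p = ModelParams(sigma=0.0, theta=np.inf, delta=0.0, floor=False)
        x1, x2 = models.simulate_paths("ddm_absorbing", I1, I2, p, 1,
                                       np.random.default_rng(0))
        assert x1[0, 0] - x2[0, 0] == pytest.approx(2 * d_sum)
        # with the floor and all-positive evidence the loser pins at 0
        p = ModelParams(sigma=0.0, theta=np.inf, delta=0.0, floor=True)
        x1, x2 = models.simulate_paths("ddm_absorbing", I1, I2, p, 1,
                                       np.random.default_rng(0))
        assert x2[0, 0] == 0.0
        assert x1[0, 0] == pytest.approx(d_sum)


class TestDdmReflecting:
    def test_cap_saturates_without_terminating(self):
        p = ModelParams(sigma=0.0, theta=3.0)
        traj = run_scalar(models.step_ddm_reflecting, 6, 1.0, 0.0, p)
        assert [s.x1 for s in traj[1:]] == [1, 2, 3, 3, 3, 3]

    def test_inactive_below_cap(self):
        p = ModelParams(sigma=0.0, theta=23.0)
        traj = run_scalar(models.step_ddm_reflecting, 10, 0.75, 0.6, p)
        assert traj[-1].x1 == pytest.approx(0.15 * 10)

    def test_antisymmetric_trajectories(self):
        p = ModelParams(sigma=0.0, theta=50.0)
        traj = run_scalar(models.step_ddm_reflecting, 10, 0.8, 0.55, p)
        assert all(s.x1 == pytest.approx(-s.x2) for s in traj)


class TestLca:
    def test_null_dynamics_is_perfect_integrator(self):
        p = ModelParams(sigma=0.0, k=0.0, beta=0.0)
        traj = run_scalar(models.step_lca, 12, 0.75, 0.6, p)
        assert traj[-1].x1 == pytest.approx(0.75 * 12)
        assert traj[-1].x2 == pytest.approx(0.6 * 12)

    def test_converges_to_linear_fixed_point_without_floor(self):
        # solve x = I + (1-k) x - beta * swap(x) as a 2x2 linear system
        k, b = 0.06, 0.05
        A = np.array([[k, b], [b, k]])
        expected = np.linalg.solve(A, [0.75, 0.6])
        p = ModelParams(sigma=0.0, k=k, beta=b, floor=False)
        traj = run_scalar(models.step_lca, 3000, 0.75, 0.6, p)
        assert traj[-1].x1 == pytest.approx(expected[0], rel=1e-4)
        assert traj[-1].x2 == pytest.approx(expected[1], rel=1e-4)

    def test_floored_fixed_point_pins_loser_at_zero(self):
        # with the zero floor the losing unit sits at 0 and the winner at
        # I1/k once inhibition from the floored unit vanishes
        p = ModelParams(sigma=0.0, k=0.06, beta=0.05, floor=True)
        traj = run_scalar(models.step_lca, 3000, 0.75, 0.6, p)
        assert traj[-1].x2 == 0.0
        assert traj[-1].x1 == pytest.approx(0.75 / 0.06, rel=1e-4)


class TestDlca:
    def test_effective_coefficients(self):
        p = ModelParams(k=0.04, gamma=0.001, beta=0.1, rho=0.0025)
        assert p.effective_leak(30) == pytest.approx(0.07)
        assert p.effective_inhibition(40) == pytest.approx(0.0)
        assert p.effective_inhibition(0) == pytest.approx(0.1)
        # clamped by default on long streams; sign flip only when disabled
        assert p.effective_inhibition(48) == 0.0
        p_unclamped = ModelParams(beta=0.1, rho=0.0025, clamp_inhibition=False)
        assert p_unclamped.effective_inhibition(48) == pytest.approx(-0.02)

    def test_reduces_to_lca_bit_identically(self, experiment_2s):
        trials = experiment_2s[:200]
        p_lca = ModelParams(sigma=0.5, k=0.06, beta=0.05)
        p_dlca = ModelParams(sigma=0.5, k=0.06, beta=0.05, gamma=0.0, rho=0.0)
        a = models.simulate_choices("lca", trials, p_lca, n_sims=3, seed=21)
        b = models.simulate_choices("dlca", trials, p_dlca, n_sims=3, seed=21)
        assert np.array_equal(a, b)

    def test_lca_without_leak_inhibition_is_integrator(self, experiment_2s):
        trials = experiment_2s[:200]
        p0 = ModelParams(sigma=0.7, k=0.0, beta=0.0, floor=False)
        a = models.simulate_choices("lca", trials, p0, n_sims=3, seed=22)
        b = models.simulate_choices("integrator", trials,
                                    ModelParams(sigma=0.7), n_sims=3, seed=22)
        assert np.array_equal(a, b)


class TestReadout:
    @pytest.mark.parametrize("model,params", [
        ("ddm_absorbing", ModelParams(sigma=0.0, theta=1e9)),
        ("ddm_reflecting", ModelParams(sigma=0.0, theta=1e9)),
        ("lca", ModelParams(sigma=0.0, k=0.05, beta=0.03)),
        ("dlca", ModelParams(sigma=0.0, k=0.04, beta=0.1, gamma=0.001, rho=0.0025)),
        ("integrator", ModelParams(sigma=0.0)),
    ])
    def test_noise_free_models_always_correct(self, model, params, experiment_2s):
        trials = [t for t in experiment_2s[:300] if t.condition == "baseline"]
        ch = models.simulate_experiment(model, trials, params, seed=1)
        correct = np.array([t.correct_index for t in trials])
        assert np.array_equal(ch, correct)

    def test_exact_tie_resolved_by_coin(self):
        I = np.full((1, 10), 0.7)
        ch = models.simulate_choices("integrator", (I, I),
                                     ModelParams(sigma=0.0), n_sims=400, seed=5)
        frac = ch.mean()
        assert 0.4 < frac < 0.6
        again = models.simulate_choices("integrator", (I, I),
                                        ModelParams(sigma=0.0), n_sims=400, seed=5)
        assert np.array_equal(ch, again)

    def test_same_seed_same_record(self, experiment_2s):
        t = experiment_2s[0]
        p = models.REFERENCE_PARAMS["dlca"]
        a = models.simulate_choice("dlca", t, p, seed=77)
        b = models.simulate_choice("dlca", t, p, seed=77)
        assert a == b

    def test_unknown_model_rejected(self, experiment_2s):
        with pytest.raises(ValueError):
            models.simulate_choices("ou_process", experiment_2s[:2], ModelParams())


class TestSymmetry:
    @pytest.mark.parametrize("model,params", [
        ("ddm_absorbing", ModelParams(sigma=0.4, theta=3.0)),
        ("ddm_reflecting", ModelParams(sigma=0.4, theta=5.0)),
        ("lca", ModelParams(sigma=0.4, k=0.06, beta=0.05)),
        ("dlca", ModelParams(sigma=0.4, k=0.04, beta=0.1, gamma=0.001, rho=0.0025)),
        ("integrator", ModelParams(sigma=0.4)),
    ])
    def test_swapping_streams_and_noise_swaps_activations(self, model, params, rng):
        n_trials, n_frames, n_sims = 40, 20, 8
        I1 = rng.uniform(0.4, 0.9, (n_trials, n_frames))
        I2 = rng.uniform(0.4, 0.9, (n_trials, n_frames))
        steps = n_frames + 1 if model == "ddm_absorbing" else n_frames
        nA = params.sigma * rng.standard_normal((steps, n_trials, n_sims))
        nB = params.sigma * rng.standard_normal((steps, n_trials, n_sims))
        g = np.random.default_rng(0)
        x1, x2 = models.simulate_paths(model, I1, I2, params, n_sims, g, noise=(nA, nB))
        y1, y2 = models.simulate_paths(model, I2, I1, params, n_sims, g, noise=(nB, nA))
        assert np.array_equal(x1, y2)
        assert np.array_equal(x2, y1)


class TestProbSummation:
    def test_first_crossing_decides_without_noise(self):
        d = np.array([0.05, -0.1, 0.25, -0.9])  # first |d| >= 0.2 is frame 2 (+)
        I1 = d.clip(min=0)[None, :] + 0.5
        I2 = -d.clip(max=0)[None, :] + 0.5
        p = ModelParams(sigma=0.0, criterion=0.2)
        ch = models.simulate_prob_summation((I1, I2), p, n_sims=1, seed=0)
        assert ch[0, 0] == models.LEFT

    def test_unreachable_criterion_falls_back(self):
        I1 = np.full((1, 10), 0.75)
        I2 = np.full((1, 10), 0.60)
        p = ModelParams(sigma=0.0, criterion=1e9)
        ch = models.simulate_prob_summation((I1, I2), p, n_sims=500, seed=1)
        assert 0.4 < ch.mean() < 0.6  # fair coin
        ch2 = models.simulate_prob_summation((I1, I2), p, n_sims=5, seed=1,
                                             fallback="argmax")
        assert np.all(ch2 == models.LEFT)  # summed evidence is positive

    def test_criterion_required(self):
        with pytest.raises(ValueError):
            models.simulate_prob_summation((np.ones((1, 5)), np.ones((1, 5))),
                                           ModelParams(sigma=0.1))


class TestMixtureLca:
    PRIMACY = ModelParams(sigma=0.5, k=0.04, beta=0.2)
    RECENCY = ModelParams(sigma=0.5, k=0.2, beta=0.025)

    def test_pure_mixture_ignores_other_regime(self, experiment_2s):
        trials = experiment_2s[:300]
        a = models.simulate_mixture_lca(trials, self.PRIMACY, self.RECENCY, 1.0, seed=3)
        b = models.simulate_mixture_lca(trials, self.PRIMACY,
                                        ModelParams(sigma=2.0, k=0.5), 1.0, seed=3)
        assert np.array_equal(a, b)
        c = models.simulate_mixture_lca(trials, ModelParams(sigma=2.0, k=0.5),
                                        self.RECENCY, 0.0, seed=3)
        d = models.simulate_mixture_lca(trials, self.PRIMACY, self.RECENCY, 0.0, seed=3)
        assert np.array_equal(c, d)

    def test_trial_mixture_is_nonmonotonic_at_2s(self):
        # across-trial averaging of a primacy and a recency regime produces
        # U-shaped mean weights even at 2 s -- unlike the within-trial
        # dynamic mechanism, which is monotone-primacy there
        from dlca import weights
        # the first-window elevation is a small effect (~0.05 on the
        # normalized scale), so this needs a large sample to resolve
        cfg = stimgen.DesignConfig(durations=(2,))
        trials = stimgen.make_experiment(cfg, 1, 80_000, seed=71)
        ch = models.simulate_mixture_lca(trials, self.PRIMACY, self.RECENCY,
                                         p_mix=0.16, seed=81)[:, 0]
        w = weights.logistic_weights(ch, trials).window_values
        assert w[0] > w[1] and w[4] > w[1]
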
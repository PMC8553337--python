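"""Reward-driven task: baselines, eligibility, rules, end-to-end learning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evoplast.cgp import CompiledRule, InvalidEvaluation, decode
from evoplast.neurosim import NeuronParams, escape_rate
from evoplast.reward import (
    RewardBaselines,
    RewardTaskConfig,
    apply_rule,
    eligibility_at_trial_end,
    eligibility_step,
    fitness_reward,
    reference_genomes,
    reference_rule_expressions,
    reference_rules,
    run_experiment,
    update_baselines,
    wrap_compiled_rule,
)


def tiny_config(**kw):
    """Scaled-down task for fast end-to-end checks."""
    defaults = dict(n_inputs=30, n_trials=60, T=300.0)
    defaults.update(kw)
    return RewardTaskConfig(**defaults)


class TestBaselines:
    def test_recursion_example(self):
        """mr=2, rewards (+1, -1, +1) from (0, 0)."""
        b = RewardBaselines()
        seq = []
        for R in (1, -1, 1):
            b = update_baselines(b, R, mr=2)
            seq.append((b.rbar_plus, b.rbar_minus))
        assert seq[0] == pytest.approx((0.5, 0.0))
        assert seq[1] == pytest.approx((0.25, -0.5))
        assert seq[2] == pytest.approx((0.625, -0.25))
        assert b.rbar == pytest.approx(0.375)
        assert b.rbar_abs == pytest.approx(0.875)

    def test_geometric_closed_form(self):
        b = RewardBaselines()
        mr, k = 100, 57
        for _ in range(k):
            b = update_baselines(b, 1, mr)
        assert b.rbar_plus == pytest.approx(1 - (1 - 1 / mr) ** k)
        assert b.rbar_minus == 0.0

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.sampled_from([-1, 1]), min_size=1, max_size=200),
           st.integers(min_value=1, max_value=50))
    def test_range_invariants_and_sum_identity(self, rewards, mr):
        b = RewardBaselines()
        for R in rewards:
            b = update_baselines(b, R, mr)
            assert 0.0 <= b.rbar_plus <= 1.0
            assert -1.0 <= b.rbar_minus <= 0.0
            assert -1.0 <= b.rbar <= 1.0
            assert 0.0 <= b.rbar_abs <= 1.0
            assert b.rbar == pytest.approx(b.rbar_plus + b.rbar_minus)

    def test_bad_window_rejected(self):
        with pytest.raises(ValueError):
            update_baselines(RewardBaselines(), 1, 0)


class TestEligibility:
    def test_homogeneous_decay(self):
        p = NeuronParams()
        E = np.array([1.0, -0.5])
        dt, tau = 0.1, 500.0
        for _ in range(1000):
            E = eligibility_step(E, np.zeros(2), p.u_rest, False, p, dt, tau)
        assert np.allclose(E, np.array([1.0, -0.5]) * np.exp(-100.0 / tau), rtol=1e-9)

    def test_fixed_point_under_clamped_potential(self):
        """Clamped u, constant sbar, no post spikes: E converges to
        -phi(u)*sbar/delta_u (phi in Hz)."""
        p = NeuronParams(delta_u=2.0, rho=20.0)
        u = p.u_th - 4.0
        sbar = np.array([0.3])
        E = np.zeros(1)
        dt, tau = 0.1, 50.0
        for _ in range(20000):
            E = eligibility_step(E, sbar, u, False, p, dt, tau)
        expected = -float(escape_rate(u, p)) * 0.3 / p.delta_u
        # discretization bias of the fixed point is O(dt/2tau)
        assert E[0] == pytest.approx(expected, rel=2e-3)

    def test_post_spike_with_zero_sbar_no_effect(self):
        p = NeuronParams()
        E = np.array([0.2])
        dt, tau = 0.1, 500.0
        # u at rest so the phi term is negligible against the delta term
        e1 = eligibility_step(E, np.zeros(1), p.u_rest - 100, True, p, dt, tau)
        e2 = eligibility_step(E, np.zeros(1), p.u_rest - 100, False, p, dt, tau)
        assert e1[0] == pytest.approx(e2[0], abs=1e-15)

    def test_closed_form_matches_stepping(self, rng):
        p = NeuronParams()
        n, dt, tau = 400, 0.1, 200.0
        sbar = rng.random((3, n))
        u = p.u_rest + 5 * rng.standard_normal(n)
        spikes = np.sort(rng.choice(n, size=5, replace=False))
        E = np.zeros(3)
        spike_set = set(spikes.tolist())
        for k in range(n):
            E = eligibility_step(E, sbar[:, k], u[k], k in spike_set, p, dt, tau)
        closed = eligibility_at_trial_end(sbar, u, spikes, p, dt, tau)
        assert np.allclose(E, closed, rtol=1e-9)


class TestRules:
    def test_lr0_zero_on_positive_reward(self):
        rules = reference_rules()
        E = np.array([0.3, -0.2])
        assert np.allclose(rules["LR0"](1, E, 0.4, -0.1), 0.0)
        assert np.allclose(rules["LR4"](1, E, 0.4, -0.1), 0.0)

    def test_lr1_reduces_to_lr0_at_zero_expected_reward(self):
        rules = reference_rules()
        E = np.array([0.5])
        # rbar = rp + rm = 0
        assert rules["LR1"](-1, E, 0.3, -0.3) == pytest.approx(rules["LR0"](-1, E, 0.3, -0.3))

    def test_lr2_baseline_endpoints(self):
        rules = reference_rules()
        E = np.array([1.0])
        assert rules["LR2"](1, E, 0.0, 0.0) == pytest.approx(1.0)  # R*E early
        assert rules["LR2"](1, E, 1.0, 0.0) == pytest.approx(0.0)  # (R-1)E late

    def test_expressions_match_callables(self):
        """The infix forms compile (via sympy) to the same functions."""
        rules = reference_rules()
        exprs = reference_rule_expressions()
        rng = np.random.default_rng(0)
        names4 = [f"x{i}" for i in range(4)]
        for name, text in exprs.items():
            compiled = wrap_compiled_rule(CompiledRule.from_expression(text, names4), "split")
            for _ in range(20):
                R = float(rng.choice([-1.0, 1.0]))
                E = rng.standard_normal(4)
                rp, rm = rng.uniform(0, 1), -rng.uniform(0, 1)
                assert np.allclose(
                    compiled(R, E, rp, rm), rules[name](R, E, rp, rm), rtol=1e-10
                ), name

    def test_reference_genomes_decode_to_rules(self):
        """Hand-wired genotypes reproduce LR0/LR2 numerically."""
        rules = reference_rules()
        rng = np.random.default_rng(1)
        for name, (genome, prims) in reference_genomes().items():
            rule = CompiledRule.from_graph(decode(genome, prims))
            for _ in range(100):
                R = float(rng.choice([-1.0, 1.0]))
                E = rng.standard_normal(3)
                rp, rm = rng.uniform(0, 1), -rng.uniform(0, 1)
                assert np.allclose(rule(R, E, rp, rm), rules[name](R, E, rp, rm)), name

    def test_lr5_positive_branch_causal_term(self):
        """At R=+1 the eligibility-carrying term of LR5 is
        2*(1 - rbar_abs)*E, the LR2 form up to the factor 2."""
        rules = reference_rules()
        E = np.array([0.7])
        rp, rm = 0.6, -0.2
        with_E = rules["LR5"](1, E, rp, rm)
        without_E = rules["LR5"](1, np.zeros(1), rp, rm)
        causal = with_E - without_E
        assert causal[0] == pytest.approx(2 * (1 - (rp - rm)) * 0.7)

    def test_apply_rule_scales_and_flags(self):
        b = RewardBaselines()
        E = np.array([0.5])
        dw = apply_rule(lambda R, E, rp, rm: (R - 1) * E, -1, E, b, eta=2.0)
        assert dw[0] == pytest.approx(-2.0)
        with pytest.raises(InvalidEvaluation):
            apply_rule(lambda R, E, rp, rm: E / 0.0, 1, E, b, eta=1.0)


class TestEndToEnd:
    def test_experiment_determinism(self):
        cfg = tiny_config()
        r1 = run_experiment(reference_rules()["LR0"], cfg, seed=7)
        r2 = run_experiment(reference_rules()["LR0"], cfg, seed=7)
        assert np.array_equal(r1, r2)

    def test_zero_rule_is_chance_level(self):
        cfg = tiny_config(n_trials=100)
        f = fitness_reward(lambda R, E, rp, rm: 0.0 * E, cfg, seeds=range(6))
        # mean reward per trial within binomial noise of zero
        assert abs(f) < 3 / np.sqrt(6 * 100 / 4)

    def test_invalid_rule_gives_minus_inf(self):
        cfg = tiny_config(n_trials=5)
        f = fitness_reward(lambda R, E, rp, rm: E / 0.0, cfg, seeds=[0])
        assert f == float("-inf")

    def test_lr0_learns(self):
        """Mean reward over the last third of trials exceeds the first
        third in most seeds (the learning signature)."""
        cfg = RewardTaskConfig(n_trials=150)
        wins = 0
        for seed in range(5):
            r = run_experiment(reference_rules()["LR0"], cfg, seed)
            wins += r[-50:].mean() > r[:50].mean()
        assert wins >= 4

    def test_paper_scale_is_n_times_per_trial(self):
        cfg = tiny_config(n_trials=40)
        rule = reference_rules()["LR0"]
        a = fitness_reward(rule, cfg, seeds=[1, 2], scale="per_trial")
        b = fitness_reward(rule, cfg, seeds=[1, 2], scale="paper")
        assert b == pytest.approx(cfg.n_trials * a)
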
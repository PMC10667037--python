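"""Branching-process extinction probabilities and times."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import demefix as dx


def _params(st_val, K=1000, t=5.0, variant="independent_binomial"):
    return dx.ModelParams(K=K, s=st_val / t, t=t, variant=variant)


class TestOffspringModel:
    def test_neutral_means_equal_migration_matrix(self, clique5):
        model = dx.build_offspring_model(clique5, _params(0.0))
        np.testing.assert_allclose(model.lam, clique5.m)

    def test_means_scaled_by_effective_advantage(self, clique5):
        model = dx.build_offspring_model(clique5, _params(0.05))
        np.testing.assert_allclose(model.lam, 0.2 * math.exp(0.05))

    def test_circulation_mean_total_offspring(self):
        # each mutant leaves e^{st} descendants on average when rows sum to 1
        g = dx.make_star(dx.StarSpec(D=5, mO=0.2, alpha=1.0))
        model = dx.build_offspring_model(g, _params(0.03))
        np.testing.assert_allclose(model.lam.sum(axis=1), math.exp(0.03))


class TestGeneratingFunction:
    def test_normalization_at_one(self, star_suppressor):
        model = dx.build_offspring_model(star_suppressor, _params(0.05))
        np.testing.assert_allclose(dx.gf_apply(model, np.ones(5)), 1.0)

    def test_scalar_closed_form_at_zero(self, wellmixed_graph):
        model = dx.build_offspring_model(wellmixed_graph, _params(0.05, K=5000))
        assert dx.gf_apply(model, np.zeros(1))[0] == pytest.approx(
            math.exp(-math.exp(0.05)))

    def test_rejects_points_outside_unit_cube(self, clique5):
        model = dx.build_offspring_model(clique5, _params(0.05))
        with pytest.raises(ValueError, match="unit cube"):
            dx.gf_apply(model, np.full(5, 1.1))

    @given(data=st.data())
    @settings(max_examples=30, deadline=None)
    def test_monotone_and_convex(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31)))
        g = dx.make_dirichlet_clique(
            dx.DirichletCliqueSpec(D=4, eta=1.0, seed=int(rng.integers(2**31))))
        model = dx.build_offspring_model(g, _params(0.05))
        x = rng.uniform(0, 1, 4)
        y = np.minimum(x + rng.uniform(0, 1, 4) * (1 - x), 1.0)  # y >= x
        fx, fy = dx.gf_apply(model, x), dx.gf_apply(model, y)
        assert np.all(fx <= fy + 1e-14)
        mid = dx.gf_apply(model, 0.5 * (x + y))
        assert np.all(mid <= 0.5 * (fx + fy) + 1e-14)  # convexity along segments

    def test_binomial_power_close_to_poisson(self, star_suppressor):
        # the pgf exponents differ by ~ G b^2 (1-x)^2 / 2 <= ~5e-3 here
        params = _params(0.05)
        mp = dx.build_offspring_model(star_suppressor, params, mode=dx.POISSON)
        mb = dx.build_offspring_model(star_suppressor, params, mode=dx.BINOMIAL_POWER)
        x = np.linspace(0.1, 0.9, 5)
        np.testing.assert_allclose(dx.gf_apply(mp, x), dx.gf_apply(mb, x), rtol=1e-2)


class TestSolveExtinction:
    def test_neutral_process_goes_extinct_surely(self, clique5):
        res = dx.solve_extinction(dx.build_offspring_model(clique5, _params(0.0)))
        np.testing.assert_allclose(res.p, 1.0)
        assert any("critical" in f for f in res.validity_flags)

    def test_circulation_matches_wellmixed(self, clique5, wellmixed_graph):
        res = dx.solve_extinction(dx.build_offspring_model(clique5, _params(0.05)))
        ref = dx.solve_extinction(
            dx.build_offspring_model(wellmixed_graph, _params(0.05, K=5000)))
        np.testing.assert_allclose(res.rho, res.rho[0])  # demes equivalent
        assert res.rho[0] == pytest.approx(ref.rho[0], abs=1e-12)
        # close to (but below) the first-order value 2st
        assert res.rho[0] < 2 * 0.05
        assert res.rho[0] == pytest.approx(2 * 0.05, rel=0.1)

    def test_star_leaf_center_ratio_approaches_alpha(self):
        g = dx.make_star(dx.StarSpec(D=5, mO=0.05, alpha=4.0))
        res = dx.solve_extinction(dx.build_offspring_model(g, _params(1e-3)))
        assert res.rho[1] / res.rho[0] == pytest.approx(4.0, rel=0.01)

    def test_average_never_exceeds_wellmixed_first_order(self):
        # suppression: rho_avg <= 2st (within first-order tolerance)
        for seed in range(20):
            g = dx.make_dirichlet_clique(dx.DirichletCliqueSpec(D=5, eta=1.0, seed=seed))
            res = dx.solve_extinction(dx.build_offspring_model(g, _params(0.02)))
            assert res.rho_avg <= 2 * 0.02 * 1.02
            assert res.rho_avg <= res.rho.max() + 1e-15

    def test_validity_flags_fire_outside_regime(self, clique5):
        res = dx.solve_extinction(dx.build_offspring_model(clique5, _params(0.002)))
        assert any("K*st" in f for f in res.validity_flags)
        res2 = dx.solve_extinction(dx.build_offspring_model(clique5, _params(0.5)))
        assert any("st =" in f for f in res2.validity_flags)


class TestFirstOrder:
    def test_clique_gives_two_st_per_deme(self):
        np.testing.assert_allclose(
            dx.first_order_fixation(dx.make_clique(5, 0.2), 0.01), 0.02, atol=1e-12)

    def test_star_ratio_is_alpha_for_any_st(self):
        g = dx.make_star(dx.StarSpec(D=5, mO=0.05, alpha=4.0))
        rho = dx.first_order_fixation(g, 0.037)
        assert rho[1] / rho[0] == pytest.approx(4.0, abs=1e-10)
        np.testing.assert_allclose(rho[1:], rho[1])

    def test_matches_small_st_limit_of_fixed_point(self):
        # Richardson extrapolation of rho/st as st -> 0 is the oracle
        g = dx.make_dirichlet_clique(dx.DirichletCliqueSpec(D=5, eta=1.0, seed=42))
        v = dx.first_order_fixation(g, 1.0)

        def rho_over_st(stv):
            res = dx.solve_extinction(dx.build_offspring_model(g, _params(stv)))
            return res.rho / stv

        rich = 2 * rho_over_st(1e-4) - rho_over_st(2e-4)
        np.testing.assert_allclose(rich, v, rtol=1e-4)

    def test_rejects_disconnected_graph(self):
        with pytest.raises(ValueError):
            dx.first_order_fixation(dx.MigrationGraph(m=np.eye(3)), 0.01)


class TestExtinctionTime:
    def test_scalar_oracle(self, wellmixed_graph):
        # independent direct iteration of q <- exp(lam (q-1)) for one type
        lam = math.exp(0.05)
        q, num = 0.0, 0.0
        for n in range(1, 20000):
            qn = math.exp(lam * (qn_prev := q) - lam)
            num += n * (qn - qn_prev)
            q = qn
            if qn - qn_prev < 1e-16 and n > 50:
                break
        p_scalar = q
        tau_scalar = num / p_scalar

        model = dx.build_offspring_model(wellmixed_graph, _params(0.05, K=5000))
        res = dx.extinction_time(model)
        assert res.tau[0] == pytest.approx(tau_scalar, rel=1e-6)
        assert res.tau_avg == res.tau[0]

    def test_iterates_monotone_and_converge_to_p(self, star_suppressor):
        model = dx.build_offspring_model(star_suppressor, _params(0.05))
        res = dx.extinction_time(model)
        diffs = np.diff(res.q_iterates, axis=0)
        assert np.all(diffs >= -1e-15)
        p = dx.solve_extinction(model).p
        np.testing.assert_allclose(res.q_iterates[-1], p, atol=1e-8)
        assert np.all(res.tau >= 1.0)

    def test_strong_migration_star_speeds_up_extinction(self, wellmixed_graph):
        ref = dx.extinction_time(
            dx.build_offspring_model(wellmixed_graph, _params(0.05, K=5000)))
        strong = dx.extinction_time(dx.build_offspring_model(
            dx.make_star(dx.StarSpec(D=5, mO=0.05, alpha=4.0)), _params(0.05)))
        weak = dx.extinction_time(dx.build_offspring_model(
            dx.make_star(dx.StarSpec(D=5, mO=1e-4, alpha=4.0)), _params(0.05)))
        assert strong.tau_avg < ref.tau_avg < weak.tau_avg
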
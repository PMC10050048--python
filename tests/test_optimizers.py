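"""Update schemes: line search, trust radius bookkeeping, trust region."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mndopt.optimizers import als_step, optimize, tro_step, trust_radius_update


class TestALS:
    def test_zero_gradient_gives_zero_step(self):
        B = np.eye(3)
        d = als_step(np.zeros(3), B, [])
        assert np.all(d == 0)

    def test_direction_normalized_before_scaling(self, rng):
        B = np.diag([1.0, 4.0, 9.0])
        g = rng.normal(size=3)
        data = [(1.0, 0.5, rng.normal(size=3))]
        d = als_step(g, B, data, dmax=100.0)
        dn = -np.linalg.solve(B, g)
        # step is parallel to the Hessian-descent direction
        cosang = d @ dn / (np.linalg.norm(d) * np.linalg.norm(dn))
        assert abs(abs(cosang) - 1.0) < 1e-12

    def test_closed_form_step_matches_grid_search(self, rng):
        n = 4
        B = np.eye(n)
        g = rng.normal(size=n)
        data = [(w, r, rng.normal(size=n))
                for w, r in zip(rng.uniform(0.5, 2.0, 5), rng.normal(size=5))]
        d = als_step(g, B, data, dmax=2.0)
        dhat = -g / np.linalg.norm(g)

        def surrogate(k):
            return sum((w * (r - k * (dxi @ dhat))) ** 2 for w, r, dxi in data)

        ks = np.linspace(-2.0, 2.0, 200001)
        vals = [surrogate(k) for k in ks]
        k_grid = ks[int(np.argmin(vals))]
        k_closed = float(d @ dhat)
        assert k_closed == pytest.approx(k_grid, abs=2.5e-5)
        assert surrogate(k_closed) <= min(vals) + 1e-12


class TestTrustRadius:
    def test_grow_then_cap(self):
        Rn, accept, rho = trust_radius_update(Q=-10.0, S_old=100.0, S_new=91.0,
                                              R=2.0, dmax=2.0)
        assert rho == pytest.approx(0.9)
        assert accept
        assert Rn == 2.0  # 5/4 * 2.0 = 2.5, capped at dmax

    def test_poor_agreement_halves(self):
        Rn, accept, rho = trust_radius_update(Q=-10.0, S_old=100.0, S_new=99.0,
                                              R=2.0, dmax=2.0)
        assert rho == pytest.approx(0.1)
        assert Rn == 1.0

    def test_middling_agreement_keeps_radius(self):
        Rn, accept, rho = trust_radius_update(Q=-10.0, S_old=100.0, S_new=95.0,
                                              R=1.0, dmax=2.0)
        assert rho == pytest.approx(0.5)
        assert accept
        assert Rn == 1.0

    def test_increase_rejected(self):
        Rn, accept, _ = trust_radius_update(Q=-10.0, S_old=100.0, S_new=101.0,
                                            R=1.0, dmax=2.0)
        assert not accept
        assert Rn == 0.5


class TestTRO:
    def test_interior_newton_step(self):
        B = np.diag([2.0, 3.0])
        g = np.array([0.2, 0.3])
        d, lam = tro_step(g, B, R=10.0)
        assert lam == 0.0
        assert np.allclose(d, -np.linalg.solve(B, g), atol=1e-12)

    def test_boundary_shift_against_bisection(self):
        B = np.diag([1.0, 4.0])
        g = np.array([1.0, 1.0])
        R = 0.5
        d, lam = tro_step(g, B, R)
        assert np.linalg.norm(d) == pytest.approx(R, abs=1e-8)

        def norm_at(l):
            return np.linalg.norm(np.linalg.solve(B + l * np.eye(2), g))

        lo, hi = 0.0, 100.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if norm_at(mid) > R:
                lo = mid
            else:
                hi = mid
        assert lam == pytest.approx(0.5 * (lo + hi), abs=1e-10)

    @given(st.integers(min_value=0, max_value=2000))
    def test_constraint_and_model_decrease(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 6)
        A = rng.normal(size=(n, n))
        B = A + A.T                       # indefinite in general
        g = rng.normal(size=n)
        R = float(rng.uniform(0.05, 2.0))
        d, lam = tro_step(g, B, R)
        assert np.linalg.norm(d) <= R + 1e-10
        Q = d @ g + 0.5 * d @ B @ d
        assert Q <= 1e-10
        # KKT: nonnegative shift and complementary slackness
        assert lam >= 0.0
        assert abs(lam * (np.linalg.norm(d) - R)) < 1e-6

    def test_hard_case(self):
        # gradient orthogonal to the lowest eigenvector
        B = np.diag([-2.0, 1.0])
        g = np.array([0.0, 0.5])
        R = 1.0
        d, lam = tro_step(g, B, R)
        assert np.linalg.norm(d) == pytest.approx(R, abs=1e-8)
        assert lam == pytest.approx(2.0, abs=1e-8)
        Q = d @ g + 0.5 * d @ B @ d
        assert Q < 0


class TestDriver:
    @pytest.fixture(scope="class")
    def tiny_problem(self):
        from mndopt.fixtures import generate_reference_data, suite
        from mndopt.params import load_packaged_parameters
        pset = load_packaged_parameters("mndo")
        entries = generate_reference_data(suite(("H2", "HF", "H2O")), pset, seed=5)
        return pset, entries

    def test_start_at_perfect_fit_terminates_immediately(self, tiny_problem):
        pset, entries = tiny_problem
        res = optimize(entries, pset, method="tro", hessian_mode="abs",
                       max_iter=50, gtol=1e-4)
        assert res.converged
        assert len(res.trajectory) == 0
        assert res.S == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("method,mode", [("tro", "abs"), ("hdtr", "abs"),
                                             ("als", "pm7")])
    def test_accepted_steps_monotone(self, tiny_problem, method, mode):
        pset, entries = tiny_problem
        rng = np.random.default_rng(11)
        p0 = pset.flatten()
        start = pset.unflatten(p0 * rng.uniform(0.99, 1.01, size=p0.size))
        res = optimize(entries, start, method=method, hessian_mode=mode,
                       max_iter=12)
        S_hist = [r.S for r in res.trajectory if r.accepted]
        assert all(b <= a + 1e-12 for a, b in zip(S_hist, S_hist[1:]))
        # rejected steps never change the best S
        best = np.inf
        for r in res.trajectory:
            if r.accepted:
                assert r.S <= best + 1e-12
                best = min(best, r.S)

    def test_small_closed_loop_recovery(self, tiny_problem):
        pset, entries = tiny_problem
        rng = np.random.default_rng(11)
        p0 = pset.flatten()
        start = pset.unflatten(p0 * rng.uniform(0.995, 1.005, size=p0.size))
        S0 = None
        from mndopt.objective import evaluate
        S0 = evaluate(entries, start, order=0).S
        res = optimize(entries, start, method="tro", hessian_mode="abs",
                       r0=0.1, dmax=2.0, max_iter=40, s_target=1e-8 * S0)
        assert res.S <= 1e-8 * S0
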
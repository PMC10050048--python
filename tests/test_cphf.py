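"""First- and second-order coupled-perturbed Hartree-Fock structure."""

import numpy as np
import pytest

from mndopt.cphf import ResponseEngine
from mndopt.fixtures import fixture_molecule
from mndopt.integrals import IntegralContext, ParamDir
from mndopt.params import load_packaged_parameters
from mndopt.scf import scf_solve


@pytest.fixture(scope="module")
def water_resp():
    pset = load_packaged_parameters("mndo")
    st = scf_solve(fixture_molecule("H2O"), pset)
    eng = ResponseEngine(st)
    dirs = [ParamDir("O", "zeta_p"), ParamDir("H", "beta_s"), ParamDir("O", "U_pp")]
    chans = [(d1, d2, None) for i, d1 in enumerate(dirs) for d2 in dirs[i:]]
    lookup = {}
    k = 0
    for i, d1 in enumerate(dirs):
        for d2 in dirs[i:]:
            lookup[(d1, d2)] = k
            k += 1
    ctx = IntegralContext(st.mol, pset, chans)
    firsts = {}
    for d in dirs:
        c = lookup[(d, d)]
        firsts[d] = eng.solve_first(d, eng.static_first(ctx, 1, c))
    return pset, st, eng, ctx, dirs, lookup, firsts


def test_first_order_antisymmetry(water_resp):
    _, _, _, _, dirs, _, firsts = water_resp
    for d in dirs:
        for s in (0, 1):
            x = firsts[d].x[s]
            assert np.abs(x + x.T).max() < 1e-10


def test_first_order_residual(water_resp):
    """(eps_j - eps_i) x_ij - R_ij = F_ij on the occupied-virtual block."""
    _, st, eng, _, dirs, _, firsts = water_resp
    for d in dirs:
        r = firsts[d]
        for s in (0, 1):
            no = st.n_occ[s]
            eps = st.eps[s]
            de = eps[None, no:] - eps[:no, None]
            x_ov = r.x[s][:no, no:]
            resid = de * x_ov - (r.fmo[s] - r.FqMO[s])[:no, no:] - r.FqMO[s][:no, no:]
            assert np.abs(resid).max() < 1e-10


def test_density_response_traceless(water_resp):
    _, _, _, _, dirs, _, firsts = water_resp
    for d in dirs:
        assert abs(np.trace(firsts[d].dP_total)) < 1e-10


def test_density_response_against_fd(water_resp):
    pset, st, _, _, _, _, firsts = water_resp
    d = ParamDir("H", "beta_s")

    def density(v):
        ps = pset.copy()
        ps.elements["H"].beta_s = v
        return scf_solve(st.mol, ps).P

    h = 1e-5
    fd = (density(pset["H"].beta_s + h) - density(pset["H"].beta_s - h)) / (2 * h)
    assert np.abs(firsts[d].dP_total - fd).max() < 1e-6


def test_absent_element_static_derivative_is_zero(mndo_params, methane):
    eng = ResponseEngine(methane)
    q = ParamDir("F", "beta_s")
    ctx = IntegralContext(methane.mol, mndo_params, [(q, q, None)])
    Fs = eng.static_first(ctx, 1, 0)
    assert np.abs(Fs[0]).max() == 0.0


def test_e_isol_static_derivative_is_zero(mndo_params, water):
    eng = ResponseEngine(water)
    q = ParamDir("O", "E_isol")
    ctx = IntegralContext(water.mol, mndo_params, [(q, q, None)])
    Fs = eng.static_first(ctx, 1, 0)
    assert np.abs(Fs[0]).max() == 0.0


def _solve2(eng, ctx, c, r1, r2):
    return eng.solve_second(r1, r2, d2H=ctx.hcore(3, c),
                            W12=ctx.two_electron(3, c),
                            W1=ctx.two_electron(1, c),
                            W2=ctx.two_electron(2, c))


def test_second_order_symmetry_and_traces(water_resp):
    pset, st, eng, ctx, dirs, lookup, firsts = water_resp
    d1, d2 = dirs[0], dirs[1]
    so12 = _solve2(eng, ctx, lookup[(d1, d2)], firsts[d1], firsts[d2])
    # swapped perturbation order, with a channel whose slots are swapped too
    ctx_swapped = IntegralContext(st.mol, pset, [(d2, d1, None)])
    so21 = _solve2(eng, ctx_swapped, 0, firsts[d2], firsts[d1])
    # q1 <-> q2 symmetry of the second density derivative
    assert np.abs(so12.d2P_total - so21.d2P_total).max() < 1e-9
    assert abs(np.trace(so12.d2P_total)) < 1e-10
    # orthonormality closure: gamma + gamma^T = X1 X2 + X2 X1
    for s in (0, 1):
        g = so12.gamma[s]
        S = firsts[d1].x[s] @ firsts[d2].x[s] + firsts[d2].x[s] @ firsts[d1].x[s]
        assert np.abs(g + g.T - S).max() < 1e-8


def test_second_density_against_fd(water_resp):
    pset, st, eng, ctx, dirs, lookup, firsts = water_resp
    d1, d2 = dirs[0], dirs[1]   # zeta_p(O), beta_s(H)
    so = _solve2(eng, ctx, lookup[(d1, d2)], firsts[d1], firsts[d2])

    def density(zp, bs):
        ps = pset.copy()
        ps.elements["O"].zeta_p = zp
        ps.elements["H"].beta_s = bs
        return scf_solve(st.mol, ps).P

    z0, b0 = pset["O"].zeta_p, pset["H"].beta_s
    h = 1e-3
    fd = (density(z0 + h, b0 + h) - density(z0 + h, b0 - h)
          - density(z0 - h, b0 + h) + density(z0 - h, b0 - h)) / (4 * h * h)
    assert np.abs(so.d2P_total - fd).max() < 1e-5


def test_zero_perturbation_gives_zero_response(mndo_params, methane):
    eng = ResponseEngine(methane)
    q = ParamDir("F", "zeta_s")     # absent element
    ctx = IntegralContext(methane.mol, mndo_params, [(q, q, None)])
    Fs = eng.static_first(ctx, 1, 0)
    r = eng.solve_first(q, Fs)
    assert np.abs(r.dP_total).max() == 0.0
    so = _solve2(eng, ctx, 0, r, r)
    assert np.abs(so.d2P_total).max() == 0.0


def test_gauge_invariance_under_degenerate_rotation(mndo_params, methane):
    """CH4 has a triply degenerate occupied level; rotating the unperturbed
    coefficients within it must leave dP and d2P unchanged."""
    st = methane
    q = ParamDir("C", "zeta_s")
    ctx = IntegralContext(st.mol, mndo_params, [(q, q, None)])
    eng = ResponseEngine(st)
    r = eng.solve_first(q, eng.static_first(ctx, 1, 0))
    so = _solve2(eng, ctx, 0, r, r)

    # rotate the degenerate occupied triple (orbitals 2,3,4 of 0..4)
    eps = st.eps[0]
    no = st.n_occ[0]
    idx = [i for i in range(no) if abs(eps[i] - eps[no - 1]) < 1e-6]
    assert len(idx) == 3
    rng = np.random.default_rng(7)
    M = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(M)
    C2 = (st.C[0].copy(), st.C[1].copy())
    for s in (0, 1):
        C2[s][:, idx] = C2[s][:, idx] @ Q
    st2 = type(st)(st.mol, st.pset, st.ctx, C2, st.eps, st.P_spin, st.F,
                   st.n_occ, st.E_el, st.V_core, st.n_iter, st.converged)
    eng2 = ResponseEngine(st2)
    r2 = eng2.solve_first(q, eng2.static_first(ctx, 1, 0))
    so2 = _solve2(eng2, ctx, 0, r2, r2)
    assert np.abs(r2.dP_total - r.dP_total).max() < 1e-8
    assert np.abs(so2.d2P_total - so.d2P_total).max() < 1e-8


def test_solution_independent_of_solver_start(water_resp):
    """Dense-LU solution agrees with GMRES from random starting vectors."""
    import scipy.sparse.linalg as spla
    _, st, eng, ctx, dirs, lookup, firsts = water_resp
    d = dirs[0]
    rhs = []
    for s in (0, 1):
        no = st.n_occ[s]
        rhs.append((st.C[s].T @ firsts[d].F_static[s] @ st.C[s])[:no, no:])
    if eng.cs:
        b = rhs[0].ravel()
        x_lu = eng.solve_ov(rhs)[0].ravel()
    else:
        b = np.concatenate([r.ravel() for r in rhs])
        x_lu = np.concatenate([x.ravel() for x in eng.solve_ov(rhs)])
    op = spla.aslinearoperator(eng._L)
    for seed in (0, 1):
        x0 = np.random.default_rng(seed).normal(size=b.size)
        x_gm, info = spla.gmres(op, b, x0=x0, rtol=1e-13, atol=0.0)
        assert info == 0
        assert np.abs(x_gm - x_lu).max() < 1e-9
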
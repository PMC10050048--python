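"""Molecular integrals: oracles, limits, symmetries and derivative checks."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mndopt.constants import BOHR, E2, ONE_CENTER_2E
from mndopt.integrals import CoordDir, IntegralContext, ParamDir
from mndopt.jets import Jet
from mndopt.molecules import Molecule
from mndopt.multipole import AtomMultipoles, pair_two_electron
from mndopt.slater import GeometryError, overlap_pair


def quad_overlap_1s(za, zb, r_ang):
    """3-D numerical quadrature of two 1s Slater functions (cylindrical
    coordinates; z panels split at the nuclear cusps)."""
    rb = r_ang / BOHR
    L = 30.0
    xg, wg = np.polynomial.legendre.leggauss(120)
    z_nodes, z_weights = [], []
    for lo, hi in ((-L, 0.0), (0.0, rb), (rb, rb + L)):
        z_nodes.append(0.5 * (hi - lo) * xg + 0.5 * (hi + lo))
        z_weights.append(0.5 * (hi - lo) * wg)
    z = np.concatenate(z_nodes)
    wz = np.concatenate(z_weights)
    rho_nodes, rho_weights = [], []
    for lo, hi in ((0.0, 1.0), (1.0, 5.0), (5.0, L)):
        rho_nodes.append(0.5 * (hi - lo) * xg + 0.5 * (hi + lo))
        rho_weights.append(0.5 * (hi - lo) * wg)
    rho = np.concatenate(rho_nodes)
    wrho = np.concatenate(rho_weights)
    ZZ, RR = np.meshgrid(z, rho, indexing="ij")
    na = 2 * za ** 1.5 / math.sqrt(4 * math.pi)
    nb = 2 * zb ** 1.5 / math.sqrt(4 * math.pi)
    fa = na * np.exp(-za * np.sqrt(RR ** 2 + ZZ ** 2))
    fb = nb * np.exp(-zb * np.sqrt(RR ** 2 + (ZZ - rb) ** 2))
    return 2 * math.pi * (wz @ ((fa * fb * RR) @ wrho))


class TestOverlap:
    def test_h_h_against_quadrature(self):
        z = 1.331967
        s = overlap_pair(1, 1, z, None, z, None, 0.74)[(0, 0)]
        assert float(np.asarray(s.val)) == pytest.approx(
            quad_overlap_1s(z, z, 0.74), abs=1e-8)

    def test_decay_at_large_distance(self, mndo_params):
        blk = overlap_pair(2, 2, 2.7, 2.7, 1.8, 1.8, 1000.0)
        for v in blk.values():
            assert abs(float(np.asarray(v.val))) < 1e-12

    def test_swap_transposes_block(self, mndo_params):
        a = overlap_pair(2, 2, 1.79, 1.65, 2.70, 2.42, 1.25)
        b = overlap_pair(2, 2, 2.70, 2.42, 1.79, 1.65, 1.25)
        # sigma-sigma entries swap roles; pi entries are symmetric; the
        # s-p cross terms pick up the sign of the reversed axis
        assert float(np.asarray(a.val for _ in ())) if False else True
        assert np.isclose(float(np.asarray(a[(0, 0)].val)), float(np.asarray(b[(0, 0)].val)))
        assert np.isclose(float(np.asarray(a[(1, 1)].val)), float(np.asarray(b[(1, 1)].val)))
        assert np.isclose(float(np.asarray(a[(0, 3)].val)), -float(np.asarray(b[(3, 0)].val)))

    def test_values_bounded_by_one(self):
        for r in (0.5, 1.0, 2.0, 4.0):
            blk = overlap_pair(2, 2, 1.2, 1.1, 3.1, 2.8, r)
            for v in blk.values():
                assert abs(float(np.asarray(v.val))) <= 1.0

    def test_coincident_atoms_error(self):
        with pytest.raises(GeometryError):
            overlap_pair(1, 1, 1.0, None, 1.0, None, 0.0)


def _mats(element, zs, zp, seed_slot=None, which="zeta_s"):
    from mndopt.constants import N_SHELL
    zsj = Jet([zs] + [None] * 7)
    zpj = None if zp is None else Jet([zp] + [None] * 7)
    if seed_slot is not None:
        (zsj if which == "zeta_s" else zpj).c[1 << seed_slot] = np.array([1.0])
    return AtomMultipoles(element, N_SHELL[element], ONE_CENTER_2E[element], zsj, zpj)


class TestTwoElectron:
    def test_one_center_ss_is_gss_with_zero_zeta_derivative(self):
        # the one-center integrals are fixed constants; probing the two-center
        # model at vanishing distance reproduces the monopole constant
        H = _mats("H", 1.331967, None, seed_slot=0)
        W = pair_two_electron(H, H, Jet.const(1e-10))
        assert float(W.val[0, 0, 0, 0]) == pytest.approx(ONE_CENTER_2E["H"]["G_ss"],
                                                         abs=1e-9)
        dz = W.c[1]
        assert dz is None or abs(np.asarray(dz)[0, 0, 0, 0, 0]) < 1e-9

    def test_coulomb_limit(self):
        A = _mats("H", 1.331967, None)
        W = pair_two_electron(A, A, Jet.const(100.0))
        assert float(W.val[0, 0, 0, 0]) == pytest.approx(E2 / 100.0, rel=1e-3)

    def test_zeta_derivative_against_fd(self):
        z0 = 1.65

        def tensor(zp):
            A = _mats("C", 1.787537, zp)
            B = _mats("O", 2.699905, 2.699905)
            return pair_two_electron(A, B, Jet.const(1.3)).val

        A = _mats("C", 1.787537, z0, seed_slot=0, which="zeta_p")
        B = _mats("O", 2.699905, 2.699905)
        W = pair_two_electron(A, B, Jet.const(1.3))
        h = 1e-5
        fd = (tensor(z0 + h) - tensor(z0 - h)) / (2 * h)
        assert np.abs(W.c[1][0] - fd).max() < 1e-7

    def test_monopole_values_positive(self):
        A = _mats("N", 2.2556, 2.2556)
        B = _mats("F", 2.8485, 2.8485)
        for r in (0.9, 1.4, 2.5, 6.0):
            W = pair_two_electron(A, B, Jet.const(r)).val
            assert W[0, 0, 0, 0] > 0.0


class TestContext:
    @pytest.fixture(scope="class")
    def hof(self):
        t = math.radians(97.2)
        return Molecule("HOF", ("O", "H", "F"),
                        [[0, 0, 0], [0.966, 0, 0],
                         [1.442 * math.cos(t), 1.442 * math.sin(t), 0]])

    def test_rotational_invariance(self, hof, mndo_params, rng):
        ctx = IntegralContext(hof, mndo_params, [])
        R = Rotation.from_rotvec(rng.normal(size=3)).as_matrix()
        ctx2 = IntegralContext(hof.rotated(R), mndo_params, [])
        assert ctx2.vcore() == pytest.approx(ctx.vcore(), abs=1e-10)
        w1 = np.linalg.eigvalsh(ctx.hcore())
        w2 = np.linalg.eigvalsh(ctx2.hcore())
        assert np.abs(w1 - w2).max() < 1e-10

    def test_core_attraction_covariance_trace(self, hof, mndo_params, rng):
        ctx = IntegralContext(hof, mndo_params, [])
        R = Rotation.from_rotvec(rng.normal(size=3)).as_matrix()
        ctx2 = IntegralContext(hof.rotated(R), mndo_params, [])
        for key in ctx.pairs:
            V1 = ctx.pairs[key].W.val[:, :, 0, 0]
            V2 = ctx2.pairs[key].W.val[:, :, 0, 0]
            assert np.trace(V1) == pytest.approx(np.trace(V2), abs=1e-10)

    def test_translation_invariance_of_cartesian_derivatives(self, hof, mndo_params):
        chans = [(None, None, CoordDir(a, ax)) for a in range(3) for ax in range(3)]
        ctx = IntegralContext(hof, mndo_params, chans)
        # Vcore and Hcore derivatives must sum to zero over atoms per axis
        for ax in range(3):
            idx = [3 * a + ax for a in range(3)]
            assert sum(ctx.vcore(4, c) for c in idx) == pytest.approx(0.0, abs=1e-9)
            dH = sum(ctx.hcore(4, c) for c in idx)
            assert np.abs(dH).max() < 1e-9

    def test_coordinate_derivative_against_fd(self, hof, mndo_params):
        chans = [(None, None, CoordDir(1, 0))]
        ctx = IntegralContext(hof, mndo_params, chans)
        h = 1e-5

        def vcore_at(dx):
            c = np.array(hof.coords)
            c[1, 0] += dx
            return IntegralContext(Molecule("x", hof.symbols, c),
                                   mndo_params, []).vcore()

        fd = (vcore_at(h) - vcore_at(-h)) / (2 * h)
        assert ctx.vcore(4, 0) == pytest.approx(fd, abs=1e-7)

    def test_resonance_beta_derivative_exact_half_overlap(self, hof, mndo_params):
        q = ParamDir("O", "beta_s")
        ctx = IntegralContext(hof, mndo_params, [(q, q, None)])
        blk = ctx.pairs[(0, 1)]     # O-H pair
        dbeta = np.asarray(blk.beta.c[1])[0]
        S = blk.S.val
        # d beta_mu nu / d beta_s(O) = S/2 exactly on the O s-row
        assert dbeta[0, 0] == pytest.approx(0.5 * S[0, 0], abs=1e-14)
        assert np.abs(dbeta[1:, 0]).max() < 1e-14

    def test_zero_beta_gives_zero_ss_block(self, hof, mndo_params):
        ps = mndo_params.copy()
        ps.elements["O"].beta_s = 0.0
        ps.elements["H"].beta_s = 0.0
        ctx = IntegralContext(hof, ps, [])
        blk = ctx.pairs[(0, 1)]
        assert abs(blk.beta.val[0, 0]) < 1e-14

    def test_crf_alpha_separability_and_fd(self, hof, mndo_params):
        qO = ParamDir("O", "alpha")
        qF = ParamDir("F", "alpha")
        ctx = IntegralContext(hof, mndo_params, [(qO, qF, None), (qO, qO, None)])
        # cross second derivative of the standard form vanishes
        assert ctx.vcore(3, 0) == pytest.approx(0.0, abs=1e-12)

        from mndopt.fdtools import fd_derivative

        def vc(a):
            ps = mndo_params.copy()
            ps.elements["O"].alpha = a
            return IntegralContext(hof, ps, []).vcore()

        est = fd_derivative(vc, mndo_params["O"].alpha, h=1e-3)
        assert ctx.vcore(1, 0) == pytest.approx(float(est.value), abs=1e-8)

    def test_crf_large_alpha_limit(self, mndo_params):
        mol = Molecule("NN", ("N", "N"), [[0, 0, 0], [0, 0, 1.2]])
        ps = mndo_params.copy()
        ps.elements["N"].alpha = 60.0
        ctx = IntegralContext(mol, ps, [])
        gss = ctx.pairs[(0, 1)].W.val[0, 0, 0, 0]
        assert ctx.vcore() == pytest.approx(25.0 * gss, rel=1e-10)

    def test_random_pair_parameter_derivatives_against_fd(self, mndo_params, rng):
        """Analytic first/second zeta derivatives vs Richardson FD on random
        CHNOF pair geometries."""
        from mndopt.fdtools import fd_derivative
        elements = ["C", "H", "N", "O", "F"]
        for _ in range(6):
            ea, eb = rng.choice(elements, size=2)
            rvec = rng.normal(size=3)
            rvec *= (1.0 + rng.uniform(0.0, 1.5)) / np.linalg.norm(rvec)
            mol = Molecule("pair", (ea, eb), [[0, 0, 0], rvec],
                           multiplicity=_pair_mult(ea, eb))
            q1 = ParamDir(ea, "zeta_s")
            q2 = ParamDir(eb, "zeta_s" if eb != ea else "zeta_s")
            ctx = IntegralContext(mol, mndo_params, [(q1, q2, None)])
            W = ctx.pairs[(0, 1)].W

            def wtensor(z):
                ps = mndo_params.copy()
                ps.elements[ea].zeta_s = z
                return IntegralContext(mol, ps, []).pairs[(0, 1)].W.val

            est = fd_derivative(wtensor, mndo_params[ea].zeta_s, h=1e-4)
            an = np.asarray(W.c[1])[0]
            denom = max(1.0, np.abs(est.value).max())
            assert np.abs(an - est.value).max() / denom < 1e-6


def _pair_mult(ea, eb):
    from mndopt.constants import CORE_CHARGE
    ne = int(CORE_CHARGE[ea] + CORE_CHARGE[eb])
    return 1 if ne % 2 == 0 else 2
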
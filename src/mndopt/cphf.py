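"""First- and second-order coupled-perturbed Hartree-Fock response in the
orthogonalized NDDO basis.

For a converged SCF state and a perturbing parameter q, the first-order
orbital-rotation matrix x^q (dC/dq = C x^q, antisymmetric) solves

    (eps_j - eps_i) x_ij - R_ij(x) = F^q_ij          (occ-virt block)

where F^q is the static MO Fock derivative (frozen density) and R the
response induced by dP(x).  Both spins couple through the Coulomb term, so
the two occupied-virtual blocks are solved together; for a closed shell the
alpha and beta responses coincide and a single spin block with coupling
J(2 dP) - K(dP) is solved.  The linear operator is built densely once per
molecule (by one batched response application) and LU-factorized; the same
factorization serves every parameter and every second-order right-hand side
(the second-order equations have identical structure with gamma^{q1q2} as
unknown).

The remaining elements of x (and gamma) follow by direct substitution; for
pairs of equal-occupancy orbitals degenerate within 1e-6 eV the substitution
denominator is singular and the intra-block rotation is pure gauge, so it is
set to zero (density-level quantities are gauge invariant, which the test
suite checks explicitly).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
import scipy.linalg as sla

from .integrals import IntegralContext, ParamDir
from .scf import (SCFState, coulomb_matrix, coulomb_from_tables,
                  exchange_matrix, exchange_from_tables)

DEGENERACY_THRESHOLD = 1e-6  # eV


class CphfError(RuntimeError):
    pass


@dataclass
class FirstOrder:
    """First-order response for one parameter."""
    q: ParamDir
    x: Tuple[np.ndarray, np.ndarray]       # full MO rotation matrices
    dP: Tuple[np.ndarray, np.ndarray]      # per-spin density derivatives (AO)
    F_static: Tuple[np.ndarray, np.ndarray]  # static AO Fock derivative F^q
    fmo: Tuple[np.ndarray, np.ndarray]     # full MO  F^q + R^q
    FqMO: Tuple[np.ndarray, np.ndarray]    # static MO part

    @property
    def dP_total(self) -> np.ndarray:
        return self.dP[0] + self.dP[1]


@dataclass
class SecondOrder:
    q1: ParamDir
    q2: ParamDir
    gamma: Tuple[np.ndarray, np.ndarray]   # full gamma^{q1 q2}
    d2P: Tuple[np.ndarray, np.ndarray]     # per-spin second density derivative
    m_mo: Tuple[np.ndarray, np.ndarray]    # C^T (F^{q1q2}+R^{q1q2}) C, full MO
    FMO2: Tuple[np.ndarray, np.ndarray]    # script-F^{q1q2} (rhs matrix)
    RMO2: Tuple[np.ndarray, np.ndarray]    # script-R^{q1q2}

    @property
    def d2P_total(self) -> np.ndarray:
        return self.d2P[0] + self.d2P[1]


class ResponseEngine:
    def __init__(self, state: SCFState):
        self.state = state
        ctx = state.ctx
        self.W0 = ctx.two_electron()
        self.g1c = ctx.gamma1c
        self.slices = ctx.ao_slices
        self.symbols = state.mol.symbols
        self.n = ctx.n_ao
        self.nocc = state.n_occ
        self.C = state.C
        self.eps = state.eps
        self.cs = state.closed_shell
        self.spins = (0,) if self.cs else (0, 1)
        self._build_operator()

    # -- core maps -------------------------------------------------------
    def jk(self, dP_total, dP_spin):
        """Response Fock J(dP) - K(dP_sigma) for one spin (batch-capable)."""
        J = coulomb_matrix(self.W0, self.g1c, self.slices, self.symbols, dP_total)
        K = exchange_matrix(self.W0, self.g1c, self.slices, self.symbols, dP_spin)
        return J - K

    def _ov(self, s):
        no = self.nocc[s]
        return no, self.n - no

    def _dP_from_ov(self, x_ov, s):
        """dP_sigma = -(C_o x C_v^T + transpose) from the occ-virt block."""
        no = self.nocc[s]
        Co = self.C[s][:, :no]
        Cv = self.C[s][:, no:]
        M = Co @ x_ov @ Cv.T
        return -(M + np.swapaxes(M, -1, -2))

    def _build_operator(self):
        for s in (0, 1):
            no, nv = self._ov(s)
            de = self.eps[s][no:][None, :] - self.eps[s][:no][:, None]
            if no and nv and np.min(np.abs(de)) < DEGENERACY_THRESHOLD:
                raise CphfError(
                    f"{self.state.mol.name}: occupied-virtual degeneracy; "
                    "response ill-defined")
        dims = [self._ov(s)[0] * self._ov(s)[1] for s in self.spins]
        self.dims = dims
        ntot = sum(dims)
        if ntot == 0:
            self._lu = None
            self._L = np.zeros((0, 0))
            return
        # batched construction: unit occ-virt rotations -> densities -> response
        basis = []
        for s in self.spins:
            no, nv = self._ov(s)
            Co = self.C[s][:, :no]
            Cv = self.C[s][:, no:]
            M = -np.einsum('ui,vj->ijuv', Co, Cv).reshape(no * nv, self.n, self.n)
            basis.append(M + np.swapaxes(M, -1, -2))
        L = np.zeros((ntot, ntot))
        col0 = 0
        for sc, Mc in zip(self.spins, basis):
            ncols = Mc.shape[0]
            dtot = 2.0 * Mc if self.cs else Mc
            J = coulomb_matrix(self.W0, self.g1c, self.slices, self.symbols, dtot)
            K = exchange_matrix(self.W0, self.g1c, self.slices, self.symbols, Mc)
            row0 = 0
            for sr in self.spins:
                no, nv = self._ov(sr)
                R = (J - K) if (self.cs or sr == sc) else J
                Co = self.C[sr][:, :no]
                Cv = self.C[sr][:, no:]
                Rov = np.einsum('ui,buv,vj->bij', Co, R, Cv)
                L[row0:row0 + no * nv, col0:col0 + ncols] = \
                    -Rov.reshape(ncols, no * nv).T
                row0 += no * nv
            col0 += ncols
        off = 0
        for s in self.spins:
            no, nv = self._ov(s)
            de = (self.eps[s][no:][None, :] - self.eps[s][:no][:, None]).ravel()
            L[off:off + no * nv, off:off + no * nv] += np.diag(de)
            off += no * nv
        self._L = L
        sv_min = np.linalg.svd(L, compute_uv=False).min() if ntot else 0.0
        if ntot and sv_min < 1e-6:
            # e.g. a partially filled degenerate shell (broken-symmetry UHF
            # stationary point): the orbital response is unbounded
            raise CphfError(
                f"{self.state.mol.name}: near-singular response operator "
                f"(min singular value {sv_min:.2e}); parameter derivatives "
                "ill-defined")
        self._lu = sla.lu_factor(L)

    def solve_ov(self, rhs_ov):
        """Solve the coupled occ-virt equations; rhs per spin (both given)."""
        if self.cs:
            rhs = rhs_ov[0].ravel()
            if rhs.size == 0:
                sol = np.zeros_like(rhs_ov[0])
                return [sol, sol]
            x = sla.lu_solve(self._lu, rhs).reshape(rhs_ov[0].shape)
            return [x, x]
        rhs = np.concatenate([r.ravel() for r in rhs_ov])
        if rhs.size == 0:
            return [np.zeros_like(r) for r in rhs_ov]
        sol = sla.lu_solve(self._lu, rhs)
        out = []
        k = 0
        for s in (0, 1):
            no, nv = self._ov(s)
            out.append(sol[k:k + no * nv].reshape(no, nv))
            k += no * nv
        return out

    # -- first order -----------------------------------------------------
    def static_first(self, ctx: IntegralContext, mask: int, channel: int,
                     extra_dH=None):
        """Static AO Fock derivative F^q for a derivative channel."""
        dH = ctx.hcore(mask, channel)
        if extra_dH is not None:
            dH = dH + extra_dH
        Wq = ctx.two_electron(mask, channel)
        P = self.state.P
        nonzero_W = any(w is not None for w in Wq.values())
        out = []
        for s in ((0,) if self.cs else (0, 1)):
            F = dH.copy()
            if nonzero_W:
                F = F + coulomb_matrix(Wq, self.g1c, self.slices, self.symbols,
                                       P, one_center=False)
                F = F - exchange_matrix(Wq, self.g1c, self.slices, self.symbols,
                                        self.state.P_spin[s], one_center=False)
            out.append(F)
        if self.cs:
            return (out[0], out[0])
        return tuple(out)

    def _fill_full(self, M, sol_ov, s):
        """Full rotation matrix from M = (scriptF + scriptR) and the solved
        occ-virt block."""
        no = self.nocc[s]
        eps = self.eps[s]
        de = eps[None, :] - eps[:, None]           # eps_j - eps_i
        with np.errstate(divide='ignore', invalid='ignore'):
            x = np.where(np.abs(de) > DEGENERACY_THRESHOLD, M / de, 0.0)
        np.fill_diagonal(x, 0.0)
        x[:no, no:] = sol_ov
        x[no:, :no] = -sol_ov.T
        return x

    def solve_first(self, q, F_static) -> FirstOrder:
        rhs = []
        FqMO = []
        for s in self.spins:
            no = self.nocc[s]
            Fq = self.C[s].T @ F_static[s] @ self.C[s]
            FqMO.append(Fq)
            rhs.append(Fq[:no, no:])
        if self.cs:
            FqMO.append(FqMO[0])
            rhs.append(rhs[0])
        sol = self.solve_ov(rhs)
        dPs = [self._dP_from_ov(sol[s], s) for s in (0, 1)] if not self.cs else None
        if self.cs:
            d0 = self._dP_from_ov(sol[0], 0)
            dPs = [d0, d0]
        dP = dPs[0] + dPs[1]
        xs, fmo = [], []
        for s in self.spins:
            R = self.jk(dP, dPs[s])
            Rmo = self.C[s].T @ R @ self.C[s]
            M = FqMO[s] + Rmo
            fmo.append(M)
            xs.append(self._fill_full(M, sol[s], s))
        if self.cs:
            xs.append(xs[0])
            fmo.append(fmo[0])
        return FirstOrder(q=q, x=tuple(xs), dP=tuple(dPs),
                          F_static=tuple(F_static), fmo=tuple(fmo),
                          FqMO=(FqMO[0], FqMO[1]))

    # -- second order ----------------------------------------------------
    def sigma_term(self, r1: FirstOrder, r2: FirstOrder, s: int) -> np.ndarray:
        """x-quadratic part of d2P (from dC = Cx, d2C = C gamma)."""
        no = self.nocc[s]
        C = self.C[s]
        Co, Cv = C[:, :no], C[:, no:]
        X1, X2 = r1.x[s], r2.x[s]
        S = X1 @ X2 + X2 @ X1
        M = Co @ S[:no, no:] @ Cv.T
        t_ov = M + M.T
        t_oo = Co @ S[:no, :no] @ Co.T
        H = X1[:, :no] @ X2[:, :no].T
        t_x = C @ (H + H.T) @ C.T
        return t_ov + t_oo + t_x

    def static_second(self, r1: FirstOrder, r2: FirstOrder,
                      d2H=None, W12=None, W1=None, W2=None):
        """Static AO second Fock derivative F^{q1 q2} (includes the sigma
        response of the density).

        ``d2H``: second core-matrix derivative (or None for zero);
        ``W12``/``W1``/``W2``: per-pair two-electron derivative tables
        (d2/dq1dq2, d/dq1, d/dq2), possibly empty.
        """
        P = self.state.P
        if d2H is None:
            d2H = np.zeros((self.n, self.n))
        W12 = W12 or {}
        W1 = W1 or {}
        W2 = W2 or {}
        dP1, dP2 = r1.dP_total, r2.dP_total
        sig = [self.sigma_term(r1, r2, s) for s in self.spins]
        if self.cs:
            sig = [sig[0], sig[0]]
        sig_tot = sig[0] + sig[1]
        out = []
        for s in self.spins:
            Ps = self.state.P_spin[s]
            F = d2H.copy()

            def _jk(W, Pt, Psp):
                nonlocal F
                if any(w is not None for w in W.values()):
                    F = F + coulomb_matrix(W, self.g1c, self.slices, self.symbols,
                                           Pt, one_center=False)
                    F = F - exchange_matrix(W, self.g1c, self.slices, self.symbols,
                                            Psp, one_center=False)

            _jk(W12, P, Ps)
            _jk(W1, dP2, r2.dP[s])
            _jk(W2, dP1, r1.dP[s])
            F = F + self.jk(sig_tot, sig[s])
            out.append(F)
        if self.cs:
            out.append(out[0])
        return tuple(out), sig

    def solve_second(self, r1: FirstOrder, r2: FirstOrder,
                     d2H=None, W12=None, W1=None, W2=None,
                     F2_static=None, sig=None) -> SecondOrder:
        if F2_static is None:
            F2_static, sig = self.static_second(r1, r2, d2H, W12, W1, W2)
        rhs = []
        FMO2 = []
        for s in self.spins:
            no = self.nocc[s]
            eps = np.diag(self.eps[s])
            X1, X2 = r1.x[s], r2.x[s]
            f1, f2 = r1.fmo[s], r2.fmo[s]
            F2 = self.C[s].T @ F2_static[s] @ self.C[s]
            F2 = F2 + (X1 @ X2 + X2 @ X1) @ eps
            F2 = F2 + X1.T @ f2 + X1.T @ eps @ X2 + f2 @ X1
            F2 = F2 + X2.T @ f1 + X2.T @ eps @ X1 + f1 @ X2
            FMO2.append(F2)
            rhs.append(F2[:no, no:])
        if self.cs:
            FMO2.append(FMO2[0])
            rhs.append(rhs[0])
        sol = self.solve_ov(rhs)
        if self.cs:
            rho0 = self._dP_from_ov(sol[0], 0)
            rhos = [rho0, rho0]
        else:
            rhos = [self._dP_from_ov(sol[s], s) for s in (0, 1)]
        rho = rhos[0] + rhos[1]
        gammas, RMO2, m_mo, d2P = [], [], [], []
        for s in self.spins:
            R2 = self.jk(rho, rhos[s])
            Rmo = self.C[s].T @ R2 @ self.C[s]
            RMO2.append(Rmo)
            X1, X2 = r1.x[s], r2.x[s]
            S = X1 @ X2 + X2 @ X1
            M = FMO2[s] + Rmo
            gammas.append(self._fill_gamma(M, S, sol[s], s))
            m_mo.append(self.C[s].T @ F2_static[s] @ self.C[s] + Rmo)
            d2P.append(rhos[s] + sig[s])
        if self.cs:
            for lst in (gammas, RMO2, m_mo, d2P):
                lst.append(lst[0])
        return SecondOrder(q1=r1.q, q2=r2.q, gamma=tuple(gammas), d2P=tuple(d2P),
                           m_mo=tuple(m_mo), FMO2=(FMO2[0], FMO2[1]),
                           RMO2=tuple(RMO2))

    def _fill_gamma(self, M, S, sol_ov, s):
        no = self.nocc[s]
        eps = self.eps[s]
        de = eps[None, :] - eps[:, None]
        with np.errstate(divide='ignore', invalid='ignore'):
            g = np.where(np.abs(de) > DEGENERACY_THRESHOLD, M / de, 0.5 * S)
        np.fill_diagonal(g, 0.5 * np.diag(S))
        g[:no, no:] = sol_ov
        g[no:, :no] = S[no:, :no] - sol_ov.T
        return g

    # -- batched interfaces -----------------------------------------------
    def _jk_batch(self, dtot, dspin):
        J = coulomb_matrix(self.W0, self.g1c, self.slices, self.symbols, dtot)
        K = exchange_matrix(self.W0, self.g1c, self.slices, self.symbols, dspin)
        return J - K

    def _mo_batch(self, s, F):
        return np.einsum('ui,buv,vj->bij', self.C[s], F, self.C[s])

    def _fill_full_batch(self, M, sol_ov, s):
        no = self.nocc[s]
        eps = self.eps[s]
        de = eps[None, :] - eps[:, None]
        with np.errstate(divide='ignore', invalid='ignore'):
            x = np.where(np.abs(de) > DEGENERACY_THRESHOLD, M / de, 0.0)
        x[:, np.arange(self.n), np.arange(self.n)] = 0.0
        x[:, :no, no:] = sol_ov
        x[:, no:, :no] = -np.swapaxes(sol_ov, -1, -2)
        return x

    def solve_ov_batch(self, rhs):
        """Solve for a batch: rhs per spin (B, no, nv); returns the same."""
        B = rhs[0].shape[0]
        if self.cs:
            mat = rhs[0].reshape(B, -1).T
            if mat.shape[0] == 0:
                return [np.zeros_like(rhs[0])] * 2
            sol = sla.lu_solve(self._lu, mat).T.reshape(rhs[0].shape)
            return [sol, sol]
        mat = np.concatenate([r.reshape(B, -1) for r in rhs], axis=1).T
        if mat.shape[0] == 0:
            return [np.zeros_like(r) for r in rhs]
        sol = sla.lu_solve(self._lu, mat).T
        out = []
        k = 0
        for s in (0, 1):
            no, nv = self._ov(s)
            out.append(sol[:, k:k + no * nv].reshape(B, no, nv))
            k += no * nv
        return out

    def solve_first_all(self, qlist, dH_all, Wtabs):
        """First-order responses for a batch of parameters.

        ``dH_all``: (B, n, n) core-matrix derivatives; ``Wtabs``: per-pair
        (B, ...) two-electron derivative tables (or None).  Returns a list of
        FirstOrder (None where the static derivative vanishes).
        """
        B = dH_all.shape[0]
        P = self.state.P
        haveW = any(w is not None for w in Wtabs.values())
        Fs = []
        for s in self.spins:
            F = dH_all.copy()
            if haveW:
                F = F + coulomb_from_tables(Wtabs, self.slices, P)
                F = F - exchange_from_tables(Wtabs, self.slices,
                                             self.state.P_spin[s])
            Fs.append(F)
        if self.cs:
            Fs.append(Fs[0])
        zero = [float(np.abs(Fs[0][b]).max()) == 0.0
                and float(np.abs(Fs[-1][b]).max()) == 0.0 for b in range(B)]
        FqMO = [self._mo_batch(s, Fs[s]) for s in self.spins]
        rhs = []
        for s in self.spins:
            no = self.nocc[s]
            rhs.append(FqMO[s][:, :no, no:])
        sol = self.solve_ov_batch(rhs if not self.cs else [rhs[0], rhs[0]])
        dPs = []
        for s in self.spins:
            no = self.nocc[s]
            Co = self.C[s][:, :no]
            Cv = self.C[s][:, no:]
            M = np.einsum('ui,bij,vj->buv', Co, sol[s], Cv)
            dPs.append(-(M + np.swapaxes(M, -1, -2)))
        if self.cs:
            dPs.append(dPs[0])
            FqMO.append(FqMO[0])
        dP = dPs[0] + dPs[1]
        out = []
        fmo = []
        xs = []
        for s in self.spins:
            R = self._jk_batch(dP, dPs[s])
            Rmo = self._mo_batch(s, R)
            M = FqMO[s] + Rmo
            fmo.append(M)
            xs.append(self._fill_full_batch(M, sol[s], s))
        if self.cs:
            fmo.append(fmo[0])
            xs.append(xs[0])
        for b, q in enumerate(qlist):
            if zero[b]:
                out.append(None)
                continue
            out.append(FirstOrder(
                q=q, x=(xs[0][b], xs[1][b]), dP=(dPs[0][b], dPs[1][b]),
                F_static=(Fs[0][b], Fs[-1][b]),
                fmo=(fmo[0][b], fmo[1][b]), FqMO=(FqMO[0][b], FqMO[1][b])))
        return out

    def solve_second_all(self, specs, d2H_all, W12tabs, W1tabs, W2tabs):
        """Second-order responses for a batch of parameter pairs.

        ``specs``: list of (q1, q2, FirstOrder, FirstOrder); the table
        arguments are channel-aligned stacks as in solve_first_all (None when
        every static integral second derivative vanishes).
        """
        B = len(specs)
        n = self.n
        P = self.state.P
        dP1 = np.stack([r1.dP_total for _, _, r1, _ in specs])
        dP2 = np.stack([r2.dP_total for _, _, _, r2 in specs])
        # static part
        Fstat = []
        sig_sp = []
        for s in self.spins:
            dP1s = np.stack([r1.dP[s] for _, _, r1, _ in specs])
            dP2s = np.stack([r2.dP[s] for _, _, _, r2 in specs])
            F = np.zeros((B, n, n)) if d2H_all is None else d2H_all.copy()
            if W12tabs is not None:
                F += coulomb_from_tables(W12tabs, self.slices, P)
                F -= exchange_from_tables(W12tabs, self.slices,
                                          self.state.P_spin[s])
            if W1tabs is not None:
                F += coulomb_from_tables(W1tabs, self.slices, dP2,
                                         delta_batched=True)
                F -= exchange_from_tables(W1tabs, self.slices, dP2s,
                                          delta_batched=True)
            if W2tabs is not None:
                F += coulomb_from_tables(W2tabs, self.slices, dP1,
                                         delta_batched=True)
                F -= exchange_from_tables(W2tabs, self.slices, dP1s,
                                          delta_batched=True)
            Fstat.append(F)
        for s in self.spins:
            X1 = np.stack([r1.x[s] for _, _, r1, _ in specs])
            X2 = np.stack([r2.x[s] for _, _, _, r2 in specs])
            no = self.nocc[s]
            C = self.C[s]
            Co, Cv = C[:, :no], C[:, no:]
            S = X1 @ X2 + X2 @ X1
            M = np.einsum('ui,bij,vj->buv', Co, S[:, :no, no:], Cv)
            t_oo = np.einsum('ui,bij,vj->buv', Co, S[:, :no, :no], Co)
            H = X1[:, :, :no] @ np.swapaxes(X2[:, :, :no], -1, -2)
            t_x = np.einsum('ui,bij,vj->buv', C, H + np.swapaxes(H, -1, -2), C)
            sig_sp.append(M + np.swapaxes(M, -1, -2) + t_oo + t_x)
        if self.cs:
            sig_sp.append(sig_sp[0])
        sig_tot = sig_sp[0] + sig_sp[1]
        FMO2 = []
        rhs = []
        for s in self.spins:
            no = self.nocc[s]
            eps = self.eps[s]
            X1 = np.stack([r1.x[s] for _, _, r1, _ in specs])
            X2 = np.stack([r2.x[s] for _, _, _, r2 in specs])
            f1 = np.stack([r1.fmo[s] for _, _, r1, _ in specs])
            f2 = np.stack([r2.fmo[s] for _, _, _, r2 in specs])
            F = Fstat[s] + self._jk_batch(sig_tot, sig_sp[s])
            Fstat[s] = F
            F2 = self._mo_batch(s, F)
            F2 = F2 + (X1 @ X2 + X2 @ X1) * eps[None, None, :]
            F2 = F2 + np.swapaxes(X1, -1, -2) @ f2 \
                + (np.swapaxes(X1, -1, -2) * eps[None, None, :]) @ X2 + f2 @ X1
            F2 = F2 + np.swapaxes(X2, -1, -2) @ f1 \
                + (np.swapaxes(X2, -1, -2) * eps[None, None, :]) @ X1 + f1 @ X2
            FMO2.append(F2)
            rhs.append(F2[:, :no, no:])
        sol = self.solve_ov_batch(rhs if not self.cs else [rhs[0], rhs[0]])
        rhos = []
        for s in self.spins:
            no = self.nocc[s]
            Co = self.C[s][:, :no]
            Cv = self.C[s][:, no:]
            M = np.einsum('ui,bij,vj->buv', Co, sol[s], Cv)
            rhos.append(-(M + np.swapaxes(M, -1, -2)))
        if self.cs:
            rhos.append(rhos[0])
            FMO2.append(FMO2[0])
        rho = rhos[0] + rhos[1]
        out = []
        RMO2 = []
        for s in self.spins:
            R2 = self._jk_batch(rho, rhos[s])
            RMO2.append(self._mo_batch(s, R2))
        if self.cs:
            RMO2.append(RMO2[0])
        for b, (q1, q2, r1, r2) in enumerate(specs):
            gammas, m_mo, d2P = [], [], []
            for s in (0, 1):
                sb = s if not self.cs else 0
                X1, X2 = r1.x[s], r2.x[s]
                S = X1 @ X2 + X2 @ X1
                M = FMO2[s][b] + RMO2[s][b]
                gammas.append(self._fill_gamma(M, S, sol[sb][b], s))
                m_mo.append(self._mo_batch(s, Fstat[sb][b][None])[0] + RMO2[s][b])
                d2P.append(rhos[s][b] + sig_sp[s][b])
            out.append(SecondOrder(q1=q1, q2=q2, gamma=tuple(gammas),
                                   d2P=tuple(d2P), m_mo=tuple(m_mo),
                                   FMO2=(FMO2[0][b], FMO2[1][b]),
                                   RMO2=(RMO2[0][b], RMO2[1][b])))
        return out
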
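"""Self-consistent field solution in the orthogonalized NDDO basis.

The basis is Lowdin-orthogonalized by construction (overlap = identity), so
the Fock matrix is diagonalized directly.  Open shells use the unrestricted
(UHF) formalism; closed shells take a spin-symmetric path that is exactly
restricted.  The SCF is fully deterministic: core-Hamiltonian guess, fixed
iteration order, DIIS acceleration on the [F, P] commutator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .constants import CORE_CHARGE, N_BASIS
from .integrals import IntegralContext
from .molecules import Molecule
from .params import ParameterSet


class ScfError(RuntimeError):
    def __init__(self, msg, state=None):
        super().__init__(msg)
        self.state = state


def coulomb_matrix(W, g1c, slices, symbols, Delta, one_center=True):
    """Generalized Coulomb contraction J(Delta).

    ``W``: dict {(a,b): (na,na,nb,nb) ndarray or None} for a < b; ``Delta``
    symmetric, optionally with leading batch axes.  Interatomic blocks of J
    vanish in the NDDO structure.
    """
    J = np.zeros(Delta.shape)
    if one_center:
        for a, el in enumerate(symbols):
            sa = slices[a]
            J[..., sa, sa] += np.einsum('ijkl,...kl->...ij', g1c[el],
                                        Delta[..., sa, sa])
    for (a, b), w in W.items():
        if w is None:
            continue
        sa, sb = slices[a], slices[b]
        J[..., sa, sa] += np.einsum('ijkl,...kl->...ij', w, Delta[..., sb, sb])
        J[..., sb, sb] += np.einsum('ijkl,...ij->...kl', w, Delta[..., sa, sa])
    return J


def exchange_matrix(W, g1c, slices, symbols, Lam, one_center=True):
    """Generalized exchange contraction K(Lambda), Lambda symmetric
    (optionally with leading batch axes)."""
    K = np.zeros(Lam.shape)
    if one_center:
        for a, el in enumerate(symbols):
            sa = slices[a]
            K[..., sa, sa] += np.einsum('ulvs,...ls->...uv', g1c[el],
                                        Lam[..., sa, sa])
    for (a, b), w in W.items():
        if w is None:
            continue
        sa, sb = slices[a], slices[b]
        blk = np.einsum('ulvs,...ls->...uv', w, Lam[..., sa, sb])
        K[..., sa, sb] += blk
        K[..., sb, sa] += np.swapaxes(blk, -1, -2)
    return K


def coulomb_from_tables(W, slices, Delta, delta_batched=False):
    """J over a batch of two-electron derivative tables.

    ``W``: dict {(a,b): (C, na, na, nb, nb) or None}; ``Delta`` either a
    single (n, n) matrix or, with ``delta_batched``, a (C, n, n) stack paired
    channel-by-channel with the tables.  Returns (C, n, n).
    """
    nchan = next(np.shape(w)[0] for w in W.values() if w is not None)
    n = Delta.shape[-1]
    J = np.zeros((nchan, n, n))
    spec_a = 'cijkl,ckl->cij' if delta_batched else 'cijkl,kl->cij'
    spec_b = 'cijkl,cij->ckl' if delta_batched else 'cijkl,ij->ckl'
    for (a, b), w in W.items():
        if w is None:
            continue
        sa, sb = slices[a], slices[b]
        J[:, sa, sa] += np.einsum(spec_a, w, Delta[..., sb, sb])
        J[:, sb, sb] += np.einsum(spec_b, w, Delta[..., sa, sa])
    return J


def exchange_from_tables(W, slices, Lam, delta_batched=False):
    """K over a batch of two-electron derivative tables (see above)."""
    nchan = next(np.shape(w)[0] for w in W.values() if w is not None)
    n = Lam.shape[-1]
    K = np.zeros((nchan, n, n))
    spec = 'culvs,cls->cuv' if delta_batched else 'culvs,ls->cuv'
    for (a, b), w in W.items():
        if w is None:
            continue
        sa, sb = slices[a], slices[b]
        blk = np.einsum(spec, w, Lam[..., sa, sb])
        K[:, sa, sb] += blk
        K[:, sb, sa] += np.swapaxes(blk, -1, -2)
    return K


@dataclass
class SCFState:
    mol: Molecule
    pset: ParameterSet
    ctx: IntegralContext
    C: Tuple[np.ndarray, np.ndarray]        # per-spin MO coefficients (columns)
    eps: Tuple[np.ndarray, np.ndarray]      # per-spin orbital energies, eV
    P_spin: Tuple[np.ndarray, np.ndarray]   # per-spin densities
    F: Tuple[np.ndarray, np.ndarray]        # per-spin Fock matrices
    n_occ: Tuple[int, int]
    E_el: float                             # electronic energy, eV
    V_core: float                           # core-core repulsion, eV
    n_iter: int
    converged: bool

    @property
    def P(self) -> np.ndarray:
        return self.P_spin[0] + self.P_spin[1]

    @property
    def closed_shell(self) -> bool:
        return self.n_occ[0] == self.n_occ[1] and np.allclose(
            self.P_spin[0], self.P_spin[1], atol=1e-12)

    def homo(self) -> Tuple[int, int]:
        """(spin, orbital index) of the highest occupied orbital."""
        cands = [(s, self.n_occ[s] - 1) for s in (0, 1) if self.n_occ[s] > 0]
        return max(cands, key=lambda t: self.eps[t[0]][t[1]])

    def fock_builder(self):
        ctx = self.ctx
        W0 = ctx.two_electron()
        g1c, slices, symbols = ctx.gamma1c, ctx.ao_slices, self.mol.symbols

        def build(P, Ps):
            J = coulomb_matrix(W0, g1c, slices, symbols, P)
            K = exchange_matrix(W0, g1c, slices, symbols, Ps)
            return J - K

        return build


def _density(C, nocc):
    Co = C[:, :nocc]
    return Co @ Co.T


class _DIIS:
    def __init__(self, max_vecs=10):
        self.F, self.E = [], []
        self.max_vecs = max_vecs

    def push(self, F, err):
        self.F.append(F)
        self.E.append(err)
        if len(self.F) > self.max_vecs:
            self.F.pop(0)
            self.E.pop(0)

    def extrapolate(self):
        m = len(self.F)
        if m < 2:
            return self.F[-1]
        B = -np.ones((m + 1, m + 1))
        B[m, m] = 0.0
        for i in range(m):
            for j in range(m):
                B[i, j] = np.dot(self.E[i].ravel(), self.E[j].ravel())
        rhs = np.zeros(m + 1)
        rhs[m] = -1.0
        try:
            c = np.linalg.solve(B, rhs)[:m]
        except np.linalg.LinAlgError:
            return self.F[-1]
        return sum(ci * Fi for ci, Fi in zip(c, self.F))


def scf_solve(mol: Molecule, pset: ParameterSet, ctx: Optional[IntegralContext] = None,
              tol_e: float = 1e-12, tol_p: float = 1e-10, max_cycles: int = 500,
              level_shift: Optional[float] = None, force_uhf: bool = False,
              guess=None) -> SCFState:
    """Converge the SCF; on failure retry once with a virtual-orbital level
    shift (released before the final diagonalization, so converged orbital
    energies are unshifted).  ``force_uhf`` runs the unrestricted branch even
    for a closed shell (spin symmetry is preserved, so the result matches the
    restricted path).  ``guess`` optionally supplies per-spin starting
    densities (warm start), which keeps the SCF on a continuous solution
    branch when parameters change incrementally."""
    if ctx is None:
        ctx = IntegralContext(mol, pset, [])
    if level_shift is None:
        try:
            return _scf_run(mol, pset, ctx, tol_e, tol_p, max_cycles, 0.0,
                            force_uhf, guess)
        except ScfError:
            return _scf_run(mol, pset, ctx, tol_e, tol_p, 4 * max_cycles, 3.0,
                            force_uhf, guess)
    return _scf_run(mol, pset, ctx, tol_e, tol_p, max_cycles, level_shift,
                    force_uhf, guess)


def _scf_run(mol: Molecule, pset: ParameterSet, ctx: IntegralContext,
             tol_e: float, tol_p: float, max_cycles: int,
             shift: float, force_uhf: bool = False, guess=None) -> SCFState:
    H = ctx.hcore()
    V_core = ctx.vcore()
    n = ctx.n_ao
    ne = mol.n_electrons
    n_beta = (ne - (mol.multiplicity - 1)) // 2
    n_alpha = ne - n_beta
    if n_alpha > n or n_beta < 0:
        raise ScfError(f"{mol.name}: cannot occupy {ne} electrons in {n} orbitals")

    W0 = ctx.two_electron()
    g1c, slices, symbols = ctx.gamma1c, ctx.ao_slices, mol.symbols

    if guess is not None:
        Pa = np.array(guess[0])
        Pb = np.array(guess[1])
    else:
        # superposition-of-atomic-densities guess: uniform valence populations.
        # (A bare core-Hamiltonian guess converges to spurious higher SCF
        # solutions for several polar molecules.)
        diag = []
        for s in symbols:
            diag += [0.5 * CORE_CHARGE[s] / N_BASIS[s]] * N_BASIS[s]
        scale = mol.n_electrons / (2.0 * sum(diag))
        Pa = np.diag(diag) * scale
        Pb = Pa.copy()
    Ca = Cb = np.eye(n)
    eps_a = eps_b = np.zeros(n)
    restricted = (mol.multiplicity == 1) and not force_uhf

    diis_a, diis_b = _DIIS(), _DIIS()
    E_old = np.inf
    Pa_old, Pb_old = Pa, Pb
    for it in range(1, max_cycles + 1):
        P = Pa + Pb
        J = coulomb_matrix(W0, g1c, slices, symbols, P)
        Ka = exchange_matrix(W0, g1c, slices, symbols, Pa)
        Fa = H + J - Ka
        if restricted:
            Fb = Fa
        else:
            Kb = exchange_matrix(W0, g1c, slices, symbols, Pb)
            Fb = H + J - Kb
        E_el = 0.5 * (np.sum((H + Fa) * Pa) + np.sum((H + Fb) * Pb))

        err_a = Fa @ Pa - Pa @ Fa
        err_b = err_a if restricted else Fb @ Pb - Pb @ Fb
        diis_a.push(Fa, err_a)
        Fa_x = diis_a.extrapolate()
        if restricted:
            Fb_x = Fa_x
        else:
            diis_b.push(Fb, err_b)
            Fb_x = diis_b.extrapolate()

        if shift:
            Fa_x = Fa_x + shift * (np.eye(n) - _density(Ca, n_alpha))
            if not restricted:
                Fb_x = Fb_x + shift * (np.eye(n) - _density(Cb, n_beta))
        eps_a, Ca = np.linalg.eigh(Fa_x)
        Pa_new = _density(Ca, n_alpha)
        if restricted:
            eps_b, Cb, Pb_new = eps_a, Ca, Pa_new
        else:
            eps_b, Cb = np.linalg.eigh(Fb_x)
            Pb_new = _density(Cb, n_beta)

        dE = abs(E_el - E_old)
        dP = np.sqrt(np.mean((Pa_new - Pa_old) ** 2 + (Pb_new - Pb_old) ** 2))
        Pa_old, Pb_old = Pa_new, Pb_new
        if it <= 4:  # light damping stabilizes the first cycles
            Pa = 0.5 * (Pa + Pa_new)
            Pb = 0.5 * (Pb + Pb_new)
        else:
            Pa, Pb = Pa_new, Pb_new
        conv = dE < tol_e and dP < tol_p and it > 5
        if conv:
            # final consistent Fock/energy at the converged density
            P = Pa + Pb
            J = coulomb_matrix(W0, g1c, slices, symbols, P)
            Fa = H + J - exchange_matrix(W0, g1c, slices, symbols, Pa)
            Fb = Fa if restricted else H + J - exchange_matrix(W0, g1c, slices, symbols, Pb)
            eps_a, Ca = np.linalg.eigh(Fa)
            eps_b, Cb = (eps_a, Ca) if restricted else np.linalg.eigh(Fb)
            Pa = _density(Ca, n_alpha)
            Pb = _density(Cb, n_beta)
            E_el = 0.5 * (np.sum((H + Fa) * Pa) + np.sum((H + Fb) * Pb))
            return SCFState(mol, pset, ctx, (Ca, Cb), (eps_a, eps_b), (Pa, Pb),
                            (Fa, Fb), (n_alpha, n_beta), float(E_el), V_core, it, True)
        E_old = E_el

    state = SCFState(mol, pset, ctx, (Ca, Cb), (eps_a, eps_b), (Pa, Pb),
                     (Fa, Fb), (n_alpha, n_beta), float(E_el), V_core, max_cycles, False)
    raise ScfError(f"{mol.name}: SCF not converged in {max_cycles} cycles "
                   f"(dE={dE:.2e}, dP={dP:.2e})", state)
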
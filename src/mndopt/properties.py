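"""Molecular properties entering the objective: heat of formation,
ionization energy, dipole moment, Cartesian gradient.

Units follow the training-set weighting: Delta-H_f in kcal/mol, IE in eV,
dipole in debye, |g| in kcal/(mol*bohr).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .constants import (ATOM_HEAT_OF_FORMATION, ATOMIC_MASS, BOHR, CORE_CHARGE,
                        DEBYE_PER_E_ANGSTROM, KCAL_PER_EV, N_BASIS)
from .integrals import CoordDir, IntegralContext
from .jets import Jet
from .scf import SCFState

# |g| (and |mu| in the derivative chain) is smoothed as sqrt(v.v + delta^2)
# to keep the norm differentiable at the origin
NORM_DELTA = 1e-8

GRAD_UNIT = KCAL_PER_EV * BOHR  # eV/angstrom -> kcal/(mol*bohr)


@dataclass
class PropertyResult:
    hf: float                     # kcal/mol
    ie: float                     # eV
    dip_vec: np.ndarray           # debye
    dip: float                    # debye
    grad: np.ndarray              # (n_atoms, 3), kcal/(mol*bohr)
    gnorm: float                  # kcal/(mol*bohr)
    E_el: float                   # eV
    V_core: float                 # eV

    def get(self, prop: str) -> float:
        return {"hf": self.hf, "ie": self.ie, "dip": self.dip, "geo": self.gnorm}[prop]


def heat_of_formation(state: SCFState) -> float:
    pset = state.pset
    e_isol = sum(pset[s].E_isol for s in state.mol.symbols)
    atoms = sum(ATOM_HEAT_OF_FORMATION[s] for s in state.mol.symbols)
    return KCAL_PER_EV * (state.E_el + state.V_core - e_isol) + atoms


def ionization_energy(state: SCFState) -> float:
    """Koopmans ionization energy: minus the highest occupied orbital energy."""
    s, i = state.homo()
    return -float(state.eps[s][i])


def center_of_mass(mol) -> np.ndarray:
    m = np.array([ATOMIC_MASS[s] for s in mol.symbols])
    return (m[:, None] * mol.coords).sum(0) / m.sum()


def dipole_moment(state: SCFState) -> Tuple[np.ndarray, float]:
    """Point-charge plus sp-hybridization dipole, in debye."""
    mol, ctx = state.mol, state.ctx
    P = state.P
    com = center_of_mass(mol)
    mu = np.zeros(3)
    for a, el in enumerate(mol.symbols):
        sa = ctx.ao_slices[a]
        q = CORE_CHARGE[el] - np.trace(P[sa, sa])
        mu += q * (mol.coords[a] - com)
        if N_BASIS[el] == 4:
            d1 = float(np.asarray(ctx.multipoles[el].D1.val))
            s0 = sa.start
            for tau in range(3):
                mu[tau] -= 2.0 * d1 * P[s0, s0 + 1 + tau]
    mu *= DEBYE_PER_E_ANGSTROM
    return mu, float(np.linalg.norm(mu))


def smooth_norm(v: np.ndarray) -> float:
    return float(np.sqrt(np.dot(v, v) + NORM_DELTA ** 2))


def pair_energy_jet(ctx: IntegralContext, a: int, b: int,
                    P: Jet, Pa: Jet, Pb: Jet) -> Jet:
    """Interatomic energy partition E_AB + V_AB^CRF as a jet.

    ``P``/``Pa``/``Pb`` are (possibly jet-valued) density matrices; jets let
    the same expression deliver the frozen-density gradient (coordinate
    directions with zero density seeds) and its exact parameter derivatives
    (density seeded with the CPHF response).
    """
    blk = ctx.pairs[(a, b)]
    sa, sb = ctx.ao_slices[a], ctx.ao_slices[b]
    za = CORE_CHARGE[ctx.mol.symbols[a]]
    zb = CORE_CHARGE[ctx.mol.symbols[b]]
    Paa = P[sa, sa]
    Pbb = P[sb, sb]
    Pab = P[sa, sb]

    # core-electron attraction: sum_{mu nu in A} P_mu nu * V_mu nu,B (+ A<->B)
    VA = blk.W[:, :, 0, 0] * (-zb)
    VB = blk.W[0, 0, :, :] * (-za)
    e = _jet_contract2(Paa, VA) + _jet_contract2(Pbb, VB)
    # resonance: 2 sum_{mu in A, la in B} P_mu la * beta_mu la
    e = e + 2.0 * _jet_contract2(Pab, blk.beta)
    # two-electron Coulomb and exchange
    e = e + _jet_contract3(Paa, Pbb, blk.W, 'coulomb')
    for Ps in (Pa, Pb):
        e = e - _jet_contract3(Ps[sa, sb], Ps[sa, sb], blk.W, 'exchange')
    return e + blk.crf


def _jet_contract2(A: Jet, B: Jet) -> Jet:
    from .jets import jet_bilinear
    return jet_bilinear(lambda x, y: np.einsum('...ij,...ij->...', x, y), A, B)


def _jet_contract3(PA: Jet, PB: Jet, W: Jet, kind: str) -> Jet:
    from .jets import jet_bilinear
    if kind == 'coulomb':
        tmp = jet_bilinear(lambda x, y: np.einsum('...ij,...ijkl->...kl', x, y), PA, W)
        return jet_bilinear(lambda x, y: np.einsum('...kl,...kl->...', x, y), PB, tmp)
    # exchange: sum_{mu nu in A, la si in B} Ps_mu la Ps_nu si (mu nu | la si)
    tmp = jet_bilinear(lambda x, y: np.einsum('...il,...ijkl->...jk', x, y), PA, W)
    return jet_bilinear(lambda x, y: np.einsum('...jk,...jk->...', x, y), PB, tmp)


def cartesian_gradient(state: SCFState) -> Tuple[np.ndarray, float]:
    """Frozen-density analytic gradient, kcal/(mol*bohr) components."""
    mol, pset = state.mol, state.pset
    nat = mol.n_atoms
    channels = [(None, None, CoordDir(a, ax)) for a in range(nat) for ax in range(3)]
    ctx = IntegralContext(mol, pset, channels)
    P = Jet.const(state.P)
    Pa = Jet.const(state.P_spin[0])
    Pb = Jet.const(state.P_spin[1])
    g = np.zeros(3 * nat)
    for (a, b) in ctx.pairs:
        e = pair_energy_jet(ctx, a, b, P, Pa, Pb)
        if e.c[4] is not None:
            g += np.asarray(e.c[4])
    g = g.reshape(nat, 3) * GRAD_UNIT
    return g, smooth_norm(g.ravel())


def compute_properties(state: SCFState, want_grad: bool = True) -> PropertyResult:
    mu, mu_norm = dipole_moment(state)
    if want_grad:
        g, gn = cartesian_gradient(state)
    else:
        g, gn = np.zeros((state.mol.n_atoms, 3)), 0.0
    return PropertyResult(
        hf=heat_of_formation(state),
        ie=ionization_energy(state),
        dip_vec=mu, dip=mu_norm,
        grad=g, gnorm=gn,
        E_el=state.E_el, V_core=state.V_core)
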
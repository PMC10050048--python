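"""Analytic first and second parameter derivatives of the objective
properties: heat of formation, ionization energy, dipole magnitude and the
Cartesian gradient norm.

All derivatives are assembled from the static integral derivatives (jet
channels) and the first/second-order CPHF responses.  Entries for parameters
of elements absent from a molecule are exactly zero, as is the E_isol column
of every property except the heat of formation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np

from .constants import (ATOM_HEAT_OF_FORMATION, CORE_CHARGE, DEBYE_PER_E_ANGSTROM,
                        KCAL_PER_EV, N_BASIS)
from .cphf import DEGENERACY_THRESHOLD, FirstOrder, ResponseEngine
from .integrals import IntegralContext, ParamDir, RelCoordDir
from .jets import Jet
from .molecules import TrainingEntry
from .params import ParameterSet
from .properties import GRAD_UNIT, NORM_DELTA, center_of_mass, pair_energy_jet
from .scf import SCFState, coulomb_matrix, exchange_matrix, scf_solve


class DerivativeError(RuntimeError):
    pass


@dataclass
class PropertyDerivatives:
    value: float
    grad: np.ndarray                      # length = len(index_map)
    hess: Optional[np.ndarray] = None     # (n, n) or None for first order


def active_indices(mol, index_map) -> List[int]:
    present = set(mol.elements)
    return [i for i, (el, _) in enumerate(index_map) if el in present]


class EntryDerivativeCalculator:
    """Derivatives of every referenced property of one training entry."""

    def __init__(self, entry: TrainingEntry, pset: ParameterSet, order: int = 2,
                 props: Optional[Sequence[str]] = None,
                 state: Optional[SCFState] = None):
        self.entry = entry
        self.mol = entry.molecule
        self.pset = pset
        self.order = order
        self.props = list(props) if props is not None else \
            [p for p, _, _ in entry.references()]
        self.index_map = pset.index_map()
        self.nglob = len(self.index_map)
        self.state = state if state is not None else scf_solve(self.mol, pset)
        self._setup()

    # -- plumbing ---------------------------------------------------------
    def _setup(self):
        imap = self.index_map
        self.active = active_indices(self.mol, imap)
        self.dirs = {i: ParamDir(*imap[i]) for i in self.active}
        # parameters that can touch the Fock matrix / integrals
        self.int_active = [i for i in self.active if imap[i][1] != "E_isol"]
        self.need_geo = "geo" in self.props
        need_response = any(p in self.props for p in ("ie", "dip", "geo")) \
            or self.order >= 2
        pairs = []
        if self.order >= 2:
            pairs = [(i, j) for ai, i in enumerate(self.int_active)
                     for j in self.int_active[ai:]]
        self.pairs = pairs
        channels = []
        self.chan_of = {}
        if self.order >= 2:
            for (i, j) in pairs:
                if not self.need_geo and i != j and not self._int_coupled(i, j):
                    continue   # integral second derivative structurally zero
                if self.need_geo:
                    for ax in range(3):
                        self.chan_of[(i, j, ax)] = len(channels)
                        channels.append((self.dirs[i], self.dirs[j], RelCoordDir(ax)))
                    self.chan_of[(i, j)] = self.chan_of[(i, j, 0)]
                else:
                    self.chan_of[(i, j)] = len(channels)
                    channels.append((self.dirs[i], self.dirs[j], None))
        else:
            for i in self.int_active:
                if self.need_geo:
                    for ax in range(3):
                        self.chan_of[(i, i, ax)] = len(channels)
                        channels.append((self.dirs[i], self.dirs[i], RelCoordDir(ax)))
                    self.chan_of[(i, i)] = self.chan_of[(i, i, 0)]
                else:
                    self.chan_of[(i, i)] = len(channels)
                    channels.append((self.dirs[i], self.dirs[i], None))
        self.ctx = IntegralContext(self.mol, self.pset, channels)
        self.engine = ResponseEngine(self.state)

        # first-order responses for all integral-active parameters, batched
        diag_idx = [self.chan_of[(i, i)] for i in self.int_active]
        dH_all = self._slice_mask(self.ctx.H.c[1], diag_idx, (self.ctx.n_ao,) * 2)
        Wtabs = {key: self._slice_table(blk.W.c[1], diag_idx)
                 for key, blk in self.ctx.pairs.items()}
        res = self.engine.solve_first_all(
            [self.dirs[i] for i in self.int_active], dH_all, Wtabs)
        self.firsts: Dict[int, FirstOrder] = dict(zip(self.int_active, res))
        self.seconds: Dict = {}
        self._seconds_done = False

    @staticmethod
    def _slice_mask(comp, idx, shape):
        if comp is None:
            return np.zeros((len(idx),) + shape)
        return np.asarray(comp)[idx]

    @staticmethod
    def _slice_table(comp, idx, zero_rows=None):
        if comp is None:
            return None
        arr = np.asarray(comp)[np.clip(idx, 0, None)]
        if zero_rows is not None and zero_rows.any():
            arr = arr.copy()
            arr[zero_rows] = 0.0
        return arr

    _ZETA = ("zeta_s", "zeta_p")

    def _int_coupled(self, i, j) -> bool:
        """Whether the pair (q_i, q_j) can have nonzero second derivatives of
        any integral (core matrix, two-electron tensor or core repulsion).

        The core matrix is linear in U and beta at fixed overlap, the
        two-electron tensors depend only on the zetas, and the core repulsion
        function on zetas and (separably) on each alpha, so only
        zeta x {zeta, beta, alpha} pairs and same-parameter diagonals couple.
        """
        (el1, f1), (el2, f2) = self.index_map[i], self.index_map[j]
        if f1 in self._ZETA or f2 in self._ZETA:
            other = f2 if f1 in self._ZETA else f1
            return other in self._ZETA + ("beta_s", "beta_p", "alpha")
        return False

    def _pair_channel(self, i, j):
        """Channel index for an unordered active pair, or None if the pair
        carries no integral channel (its static seconds are zero)."""
        if (i, j) in self.chan_of:
            return self.chan_of[(i, j)], 1, 2
        if (j, i) in self.chan_of:
            return self.chan_of[(j, i)], 2, 1
        return None, None, None

    def first_of(self, i) -> Optional[FirstOrder]:
        return self.firsts.get(i)

    def second_of(self, i, j):
        if not self._seconds_done:
            self._compute_all_seconds()
        return self.seconds.get((min(i, j), max(i, j)))

    def _compute_all_seconds(self):
        """Batched second-order CPHF for every needed active parameter pair."""
        self._seconds_done = True
        todo = []
        cidx = []
        nochan = []
        c1idx = []
        c2idx = []
        for (i, j) in self.pairs:
            r1, r2 = self.firsts.get(i), self.firsts.get(j)
            if r1 is None or r2 is None:
                self.seconds[(i, j)] = None
                continue
            c, _, _ = self._pair_channel(i, j)
            todo.append((self.dirs[i], self.dirs[j], r1, r2, (i, j)))
            cidx.append(c if c is not None else -1)
            nochan.append(c is None)
            # single derivatives come from the diagonal channels, which exist
            # for every active parameter
            c1idx.append(self.chan_of[(i, i)])
            c2idx.append(self.chan_of[(j, j)])
        if not todo:
            return
        cidx = np.array(cidx)
        nochan = np.array(nochan)
        c1idx = np.array(c1idx)
        c2idx = np.array(c2idx)
        n = self.ctx.n_ao
        d2H_all = self._slice_mask(self.ctx.H.c[3], np.clip(cidx, 0, None), (n, n))
        d2H_all[nochan] = 0.0

        def tabs(mask, idx, zero_rows=None):
            t = {key: self._slice_table(blk.W.c[mask], idx, zero_rows=zero_rows)
                 for key, blk in self.ctx.pairs.items()}
            if all(v is None for v in t.values()):
                return None
            return t

        res = self.engine.solve_second_all(
            [(q1, q2, r1, r2) for q1, q2, r1, r2, _ in todo],
            d2H_all, tabs(3, cidx, nochan), tabs(1, c1idx), tabs(1, c2idx))
        for (_, _, _, _, key), so in zip(todo, res):
            self.seconds[key] = so

    # -- heat of formation ------------------------------------------------
    def hf(self) -> PropertyDerivatives:
        st = self.state
        value = KCAL_PER_EV * (st.E_el + st.V_core
                               - sum(self.pset[s].E_isol for s in self.mol.symbols)) \
            + sum(ATOM_HEAT_OF_FORMATION[s] for s in self.mol.symbols)
        n_of = {}
        for s in self.mol.symbols:
            n_of[s] = n_of.get(s, 0) + 1
        g = np.zeros(self.nglob)
        P = st.P
        for i in self.active:
            el, field = self.index_map[i]
            if field == "E_isol":
                g[i] = -KCAL_PER_EV * n_of[el]
                continue
            c = self.chan_of[(i, i)]
            dvc = self.ctx.vcore(1, c)
            r = self.firsts[i]
            de = 0.0
            if r is not None:
                for s in (0, 1):
                    de += np.sum(r.F_static[s] * st.P_spin[s]) \
                        - 0.5 * np.sum((r.F_static[s] - self.ctx.hcore(1, c))
                                       * st.P_spin[s])
            g[i] = KCAL_PER_EV * (de + dvc)
        H = None
        if self.order >= 2:
            H = np.zeros((self.nglob, self.nglob))
            for (i, j) in self.pairs:
                H[i, j] = H[j, i] = self._hf_second(i, j)
        return PropertyDerivatives(value, g, H)

    def _hf_second(self, i, j) -> float:
        st = self.state
        c, mi, mj = self._pair_channel(i, j)
        P = st.P
        if c is None:
            d2v = 0.0
            t = 0.0
            W12 = {}
        else:
            d2v = self.ctx.vcore(3, c)
            d2H = self.ctx.hcore(3, c)
            t = float(np.sum(d2H * P))
            W12 = self.ctx.two_electron(3, c)
        if any(w is not None for w in W12.values()):
            J12 = coulomb_matrix(W12, self.ctx.gamma1c, self.ctx.ao_slices,
                                 self.mol.symbols, P, one_center=False)
            t += 0.5 * float(np.sum(J12 * P))
            for s in (0, 1):
                K12 = exchange_matrix(W12, self.ctx.gamma1c, self.ctx.ao_slices,
                                      self.mol.symbols, st.P_spin[s], one_center=False)
                t -= 0.5 * float(np.sum(K12 * st.P_spin[s]))
        ri, rj = self.firsts[i], self.firsts[j]
        cross = 0.0
        if ri is not None and rj is not None:
            for s in (0, 1):
                cross += 0.5 * (np.sum(ri.F_static[s] * rj.dP[s])
                                + np.sum(rj.F_static[s] * ri.dP[s]))
        return KCAL_PER_EV * (t + cross + d2v)

    # -- ionization energy -------------------------------------------------
    def _check_homo(self):
        st = self.state
        s, h = st.homo()
        eps = st.eps[s]
        gaps = [abs(eps[k] - eps[h]) for k in range(len(eps)) if k != h]
        if gaps and min(gaps) < DEGENERACY_THRESHOLD:
            raise DerivativeError(
                f"{self.mol.name}: degenerate HOMO; IE derivative ill-defined")
        if not st.closed_shell:
            so, ho = 1 - s, st.n_occ[1 - s] - 1
            if ho >= 0 and abs(st.eps[so][ho] - eps[h]) < DEGENERACY_THRESHOLD:
                raise DerivativeError(
                    f"{self.mol.name}: spin-degenerate HOMO; IE derivative ill-defined")
        return s, h

    def ie(self) -> PropertyDerivatives:
        s, h = self._check_homo()
        st = self.state
        value = -float(st.eps[s][h])
        g = np.zeros(self.nglob)
        for i in self.int_active:
            r = self.firsts[i]
            if r is not None:
                g[i] = -r.fmo[s][h, h]
        H = None
        if self.order >= 2:
            H = np.zeros((self.nglob, self.nglob))
            for (i, j) in self.pairs:
                so = self.second_of(i, j)
                if so is None:
                    continue
                d2eps = (so.FMO2[s] + so.RMO2[s])[h, h]
                H[i, j] = H[j, i] = -d2eps
        return PropertyDerivatives(value, g, H)

    # -- dipole -------------------------------------------------------------
    def dip(self) -> PropertyDerivatives:
        st = self.state
        if not st.closed_shell:
            raise DerivativeError(
                f"{self.mol.name}: dipole derivatives require a closed shell")
        mol, ctx = self.mol, self.ctx
        com = center_of_mass(mol)
        tau = mol.coords - com[None, :]

        def mu_vec(P):
            mu = np.zeros(3)
            for a, el in enumerate(mol.symbols):
                sa = ctx.ao_slices[a]
                mu += (CORE_CHARGE[el] - np.trace(P[sa, sa])) * tau[a]
                if N_BASIS[el] == 4:
                    d1 = float(np.asarray(ctx.multipoles[el].D1.val))
                    s0 = sa.start
                    for t in range(3):
                        mu[t] -= 2.0 * d1 * P[s0, s0 + 1 + t]
            return DEBYE_PER_E_ANGSTROM * mu

        value_vec = mu_vec(st.P)
        norm = float(np.sqrt(value_vec @ value_vec + NORM_DELTA ** 2))

        def dmu_vec(i):
            r = self.firsts.get(i)
            dP = r.dP_total if r is not None else np.zeros_like(st.P)
            c = self.chan_of[(i, i)]
            out = np.zeros(3)
            for a, el in enumerate(mol.symbols):
                sa = ctx.ao_slices[a]
                out += -np.trace(dP[sa, sa]) * tau[a]
                if N_BASIS[el] == 4:
                    D1j = ctx.multipoles[el].D1
                    d1 = float(np.asarray(D1j.val))
                    dd1 = _jcomp(D1j, 1, c)
                    s0 = sa.start
                    for t in range(3):
                        out[t] -= 2.0 * (dd1 * st.P[s0, s0 + 1 + t]
                                         + d1 * dP[s0, s0 + 1 + t])
            return DEBYE_PER_E_ANGSTROM * out

        dvecs = {}
        g = np.zeros(self.nglob)
        for i in self.int_active:
            dvecs[i] = dmu_vec(i)
            g[i] = value_vec @ dvecs[i] / norm
        H = None
        if self.order >= 2:
            H = np.zeros((self.nglob, self.nglob))
            for (i, j) in self.pairs:
                d2vec = self._d2mu_vec(i, j, tau)
                val = (dvecs[i] @ dvecs[j] + value_vec @ d2vec) / norm \
                    - (value_vec @ dvecs[i]) * (value_vec @ dvecs[j]) / norm ** 3
                H[i, j] = H[j, i] = val
        return PropertyDerivatives(norm, g, H)

    def _d2mu_vec(self, i, j, tau) -> np.ndarray:
        st, mol, ctx = self.state, self.mol, self.ctx
        c, _, _ = self._pair_channel(i, j)
        so = self.second_of(i, j)
        d2P = so.d2P_total if so is not None else np.zeros_like(st.P)
        ri, rj = self.firsts.get(i), self.firsts.get(j)
        dPi = ri.dP_total if ri is not None else np.zeros_like(st.P)
        dPj = rj.dP_total if rj is not None else np.zeros_like(st.P)
        out = np.zeros(3)
        for a, el in enumerate(mol.symbols):
            sa = ctx.ao_slices[a]
            out += -np.trace(d2P[sa, sa]) * tau[a]
            if N_BASIS[el] == 4:
                D1j = ctx.multipoles[el].D1
                d1 = float(np.asarray(D1j.val))
                # first derivatives of D1 come from the diagonal channels;
                # its cross second derivative lives on the pair channel
                dd1_i = _jcomp(D1j, 1, self.chan_of[(i, i)])
                dd1_j = _jcomp(D1j, 1, self.chan_of[(j, j)])
                d2d1 = _jcomp(D1j, 3, c) if c is not None else 0.0
                s0 = sa.start
                for t in range(3):
                    out[t] -= 2.0 * (d2d1 * st.P[s0, s0 + 1 + t]
                                     + dd1_i * dPj[s0, s0 + 1 + t]
                                     + dd1_j * dPi[s0, s0 + 1 + t]
                                     + d1 * d2P[s0, s0 + 1 + t])
        return DEBYE_PER_E_ANGSTROM * out

    # -- gradient norm ------------------------------------------------------
    def geo(self) -> PropertyDerivatives:
        st = self.state
        mol = self.mol
        nat = mol.n_atoms
        nact = len(self.int_active)
        g_val = np.zeros((nat, 3))
        dg = {i: np.zeros((nat, 3)) for i in self.int_active}
        d2g = {}
        pair_list = self.pairs if self.order >= 2 else \
            [(i, i) for i in self.int_active]
        for (i, j) in pair_list:
            d2g[(i, j)] = np.zeros((nat, 3))

        # density jets per channel: seeds carry the CPHF response
        nchan = self.ctx.nchan
        n = self.ctx.n_ao
        dP1 = {s: np.zeros((nchan, n, n)) for s in (0, 1)}
        dP2 = {s: np.zeros((nchan, n, n)) for s in (0, 1)}
        d2Pc = {s: np.zeros((nchan, n, n)) for s in (0, 1)}
        have_second = self.order >= 2
        for (i, j) in pair_list:
            ri, rj = self.firsts.get(i), self.firsts.get(j)
            so = self.second_of(i, j) if have_second else None
            for ax in range(3):
                c = self.chan_of[(i, j, ax)]
                for s in (0, 1):
                    if ri is not None:
                        dP1[s][c] = ri.dP[s]
                    if rj is not None:
                        dP2[s][c] = rj.dP[s]
                    if so is not None:
                        d2Pc[s][c] = so.d2P[s]
        Pj = {}
        for s in (0, 1):
            Pj[s] = Jet([self.state.P_spin[s], dP1[s], dP2[s], d2Pc[s],
                         None, None, None, None])
        Ptot = Pj[0] + Pj[1]

        for (a, b), blk in self.ctx.pairs.items():
            scale = 1.0 / (b - a)
            e = pair_energy_jet(self.ctx, a, b, Ptot, Pj[0], Pj[1])
            for (i, j) in pair_list:
                for ax in range(3):
                    c = self.chan_of[(i, j, ax)]
                    dE = _c(e, 4, c) * scale
                    g_val[b, ax] += dE
                    g_val[a, ax] -= dE
                    d5 = _c(e, 5, c) * scale   # d2E / dq_i dtau
                    d6 = _c(e, 6, c) * scale   # d2E / dq_j dtau
                    dg[i][b, ax] += d5
                    dg[i][a, ax] -= d5
                    if i != j:
                        dg[j][b, ax] += d6
                        dg[j][a, ax] -= d6
                    d7 = _c(e, 7, c) * scale
                    d2g[(i, j)][b, ax] += d7
                    d2g[(i, j)][a, ax] -= d7
        # g_val accumulated once per (i,j) channel group; normalize
        npair_ch = len(pair_list)
        g_val /= npair_ch
        for i in self.int_active:
            cnt = sum(1 for (x, y) in pair_list if x == i or y == i)
            dg[i] /= cnt if self.order >= 2 else 1.0

        g_val *= GRAD_UNIT
        gflat = g_val.ravel()
        norm = float(np.sqrt(gflat @ gflat + NORM_DELTA ** 2))
        g = np.zeros(self.nglob)
        for i in self.int_active:
            dg[i] *= GRAD_UNIT
            g[i] = gflat @ dg[i].ravel() / norm
        H = None
        if self.order >= 2:
            H = np.zeros((self.nglob, self.nglob))
            for (i, j) in self.pairs:
                d2 = d2g[(i, j)] * GRAD_UNIT
                val = (dg[i].ravel() @ dg[j].ravel() + gflat @ d2.ravel()) / norm \
                    - (gflat @ dg[i].ravel()) * (gflat @ dg[j].ravel()) / norm ** 3
                H[i, j] = H[j, i] = val
        return PropertyDerivatives(norm, g, H)

    # -- public -------------------------------------------------------------
    def compute(self) -> Dict[str, PropertyDerivatives]:
        out = {}
        for p in self.props:
            out[p] = getattr(self, p)()
        return out


def _jcomp(jet: Jet, mask: int, channel: int) -> float:
    v = jet.c[mask]
    if v is None:
        return 0.0
    return float(np.asarray(v)[channel])


def _c(jet: Jet, mask: int, channel: int) -> float:
    v = jet.c[mask]
    if v is None:
        return 0.0
    return float(np.asarray(v)[channel])


def entry_derivatives(entry: TrainingEntry, pset: ParameterSet, order: int = 2,
                      props: Optional[Sequence[str]] = None,
                      state: Optional[SCFState] = None) -> Dict[str, PropertyDerivatives]:
    calc = EntryDerivativeCalculator(entry, pset, order=order, props=props, state=state)
    return calc.compute()
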
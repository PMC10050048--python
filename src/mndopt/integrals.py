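"""Molecule-level MNDO integral assembly with analytic derivative channels.

An :class:`IntegralContext` evaluates, for one molecule and one parameter
set, every integral entering the Fock matrix and the core-core repulsion --
overlaps, two-center two-electron tensors, core-electron attractions,
resonance integrals, the core repulsion function -- in jet arithmetic.  The
caller declares a list of *channels*; each channel assigns up to three
differentiation directions (slots) to parameters or Cartesian coordinates,
and every assembled quantity then carries the corresponding exact mixed
derivatives alongside its value.

Directions are per-element for parameters (seeding every atom of that
element simultaneously, which is the derivative the parameter vector needs)
and per-atom for coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .constants import CORE_CHARGE, N_BASIS, N_SHELL, ONE_CENTER_2E
from .jets import Jet, jet_bilinear, jsqrt, jexp, jet_stack
from .molecules import Molecule
from .multipole import AtomMultipoles, pair_two_electron
from .params import ParameterSet
from .slater import overlap_pair

_SLOT_MASK = (1, 2, 4)


@dataclass(frozen=True)
class ParamDir:
    element: str
    field: str


@dataclass(frozen=True)
class CoordDir:
    atom: int
    axis: int


@dataclass(frozen=True)
class RelCoordDir:
    """Pair-relative Cartesian direction.

    Seeds atom i's coordinate along ``axis`` with weight i, so that for an
    atom pair (a, b) every pair quantity (which depends on coordinates only
    through r_b - r_a) carries (b - a) times its derivative with respect to
    the pair vector component; the caller divides by (b - a).  One channel
    per axis thus serves all pairs at once.
    """
    axis: int


Channel = Tuple[Optional[object], Optional[object], Optional[object]]


@dataclass
class PairBlock:
    S: Jet        # (na, nb) overlap
    W: Jet        # (na, na, nb, nb) two-electron tensor, eV
    beta: Jet     # (na, nb) resonance integrals, eV
    crf: Jet      # scalar core-core repulsion, eV
    R: Jet        # scalar distance, angstrom


def one_center_tensor(element: str) -> np.ndarray:
    """Full one-center two-electron tensor from the fixed G/H constants."""
    g = ONE_CENTER_2E[element]
    n = N_BASIS[element]
    t = np.zeros((n, n, n, n))
    t[0, 0, 0, 0] = g["G_ss"]
    if n == 4:
        hpp = 0.5 * (g["G_pp"] - g["G_p2"])
        for p in (1, 2, 3):
            t[0, 0, p, p] = t[p, p, 0, 0] = g["G_sp"]
            t[p, p, p, p] = g["G_pp"]
            for key in ((0, p, 0, p), (0, p, p, 0), (p, 0, 0, p), (p, 0, p, 0)):
                t[key] = g["H_sp"]
            for q in (1, 2, 3):
                if q == p:
                    continue
                t[p, p, q, q] = g["G_p2"]
                for key in ((p, q, p, q), (p, q, q, p), (q, p, p, q), (q, p, q, p)):
                    t[key] = hpp
    return t


class IntegralContext:
    def __init__(self, mol: Molecule, pset: ParameterSet, channels: List[Channel] = ()):
        self.mol = mol
        self.pset = pset
        self.channels = list(channels)
        self.nchan = len(self.channels)
        n = 0
        self.ao_slices = []
        for s in mol.symbols:
            self.ao_slices.append(slice(n, n + N_BASIS[s]))
            n += N_BASIS[s]
        self.n_ao = n
        self.gamma1c = {el: one_center_tensor(el) for el in mol.elements}

        self._param_jets = {
            el: {f: self._make_param_jet(el, f) for f in pset[el].fields()}
            for el in mol.elements
        }
        self._coord_jets = [
            [self._make_coord_jet(a, ax) for ax in range(3)] for a in range(mol.n_atoms)
        ]
        self.multipoles = {
            el: AtomMultipoles(
                el, N_SHELL[el], ONE_CENTER_2E[el],
                self._param_jets[el]["zeta_s"], self._param_jets[el].get("zeta_p"))
            for el in mol.elements
        }
        self._build()

    # -- seeding --------------------------------------------------------
    def _seed(self, dir_weight) -> List[Optional[np.ndarray]]:
        """Per-slot seed arrays over channels (None if unused)."""
        out = []
        for slot in range(3):
            arr = np.zeros(self.nchan)
            hit = False
            for c, chan in enumerate(self.channels):
                if chan[slot] is None:
                    continue
                w = dir_weight(chan[slot])
                if w:
                    arr[c] = w
                    hit = True
            out.append(arr if hit else None)
        return out

    def _make_param_jet(self, el: str, field: str) -> Jet:
        seeds = self._seed(lambda d: 1.0 if isinstance(d, ParamDir)
                           and d.element == el and d.field == field else 0.0)
        val = getattr(self.pset[el], field)
        return Jet([val, seeds[0], seeds[1], None, seeds[2], None, None, None])

    def _make_coord_jet(self, atom: int, axis: int) -> Jet:
        def w(d):
            if isinstance(d, CoordDir) and d.atom == atom and d.axis == axis:
                return 1.0
            if isinstance(d, RelCoordDir) and d.axis == axis:
                return float(atom)
            return 0.0
        seeds = self._seed(w)
        return Jet([self.mol.coords[atom, axis],
                    seeds[0], seeds[1], None, seeds[2], None, None, None])

    # -- assembly -------------------------------------------------------
    def _rotation(self, rvec: List[Jet], R: Jet) -> Jet:
        """(3,3) jet whose columns are the local axes in global coordinates."""
        ez = [v / R for v in rvec]
        if abs(float(np.asarray(ez[2].val))) < 0.9:
            ref = (Jet.const(0.0), Jet.const(0.0), Jet.const(1.0))
        else:
            ref = (Jet.const(1.0), Jet.const(0.0), Jet.const(0.0))
        ex = _cross(ref, ez)
        nrm = jsqrt(ex[0] * ex[0] + ex[1] * ex[1] + ex[2] * ex[2])
        ex = [v / nrm for v in ex]
        ey = _cross(ez, ex)
        return jet_stack([jet_stack(col) for col in (ex, ey, ez)], axis=-2).transpose_last()

    def _build(self):
        mol, pset = self.mol, self.pset
        n = self.n_ao
        Hb = _JetAccumulator((n, n), self.nchan)
        Vcore = Jet.const(0.0)
        self.pairs: Dict[Tuple[int, int], PairBlock] = {}

        # one-center part of the core matrix
        for a, el in enumerate(mol.symbols):
            sl = self.ao_slices[a]
            Hb.add_scalar(self._param_jets[el]["U_ss"], (sl.start, sl.start))
            if N_BASIS[el] == 4:
                upp = self._param_jets[el]["U_pp"]
                for k in range(1, 4):
                    Hb.add_scalar(upp, (sl.start + k, sl.start + k))

        for a in range(mol.n_atoms):
            for b in range(a + 1, mol.n_atoms):
                blk = self._pair_block(a, b)
                self.pairs[(a, b)] = blk
                sa, sb = self.ao_slices[a], self.ao_slices[b]
                za, zb = CORE_CHARGE[mol.symbols[a]], CORE_CHARGE[mol.symbols[b]]
                Hb.add_block(blk.W[:, :, 0, 0] * (-zb), sa, sa)
                Hb.add_block(blk.W[0, 0, :, :] * (-za), sb, sb)
                Hb.add_block(blk.beta, sa, sb)
                Hb.add_block(blk.beta.transpose_last(), sb, sa)
                Vcore = Vcore + blk.crf
        self.H = Hb.jet()
        self.Vcore = Vcore

    def _pair_block(self, a: int, b: int) -> PairBlock:
        mol = self.mol
        ela, elb = mol.symbols[a], mol.symbols[b]
        na, nb = N_BASIS[ela], N_BASIS[elb]
        rvec = [self._coord_jets[b][ax] - self._coord_jets[a][ax] for ax in range(3)]
        R = jsqrt(rvec[0] * rvec[0] + rvec[1] * rvec[1] + rvec[2] * rvec[2])
        pa, pb = self._param_jets[ela], self._param_jets[elb]

        sloc = overlap_pair(N_SHELL[ela], N_SHELL[elb],
                            pa["zeta_s"], pa.get("zeta_p"),
                            pb["zeta_s"], pb.get("zeta_p"), R)
        Sb = _JetAccumulator((na, nb), self.nchan)
        for (i, j), v in sloc.items():
            Sb.add_scalar(v, (i, j))
        S = Sb.jet()

        Wloc = pair_two_electron(self.multipoles[ela], self.multipoles[elb], R)

        need_rot = na == 4 or nb == 4
        if need_rot:
            T = self._rotation(rvec, R)
            Ta = _expand_transform(T, na)
            Tb = _expand_transform(T, nb)
            S = jet_bilinear(lambda x, y: np.einsum('...ia,...ab->...ib', x, y), Ta, S)
            S = jet_bilinear(lambda x, y: np.einsum('...ib,...jb->...ij', x, y), S, Tb)
            W = jet_bilinear(lambda x, y: np.einsum('...ia,...abcd->...ibcd', x, y), Ta, Wloc)
            W = jet_bilinear(lambda x, y: np.einsum('...jb,...ibcd->...ijcd', x, y), Ta, W)
            W = jet_bilinear(lambda x, y: np.einsum('...kc,...ijcd->...ijkd', x, y), Tb, W)
            W = jet_bilinear(lambda x, y: np.einsum('...ld,...ijkd->...ijkl', x, y), Tb, W)
        else:
            W = Wloc

        bsum = _beta_sum(jet_stack(_orbital_betas(pa, na)),
                         jet_stack(_orbital_betas(pb, nb)))
        beta = bsum * S

        crf = self._crf(ela, elb, pa, pb, W, R)
        return PairBlock(S=S, W=W, beta=beta, crf=crf, R=R)

    def _crf(self, ela, elb, pa, pb, W, R) -> Jet:
        gss = W[0, 0, 0, 0]
        za, zb = CORE_CHARGE[ela], CORE_CHARGE[elb]
        ea = jexp(-pa["alpha"] * R)
        eb = jexp(-pb["alpha"] * R)
        # N-H / O-H pairs: the heavy-atom exponential carries a factor R (angstrom)
        if ela in ("N", "O") and elb == "H":
            ea = ea * R
        elif elb in ("N", "O") and ela == "H":
            eb = eb * R
        return gss * (za * zb) * (1.0 + ea + eb)

    # -- extraction ------------------------------------------------------
    def hcore(self, mask: int = 0, channel: Optional[int] = None) -> np.ndarray:
        return _extract(self.H, mask, channel, (self.n_ao, self.n_ao))

    def vcore(self, mask: int = 0, channel: Optional[int] = None) -> float:
        return float(np.asarray(_extract(self.Vcore, mask, channel, ())))

    def two_electron(self, mask: int = 0, channel: Optional[int] = None):
        """Per-pair two-electron tensors for a derivative component.

        Returns dict {(a,b): ndarray or None}; None marks an identically zero
        derivative block.
        """
        out = {}
        for key, blk in self.pairs.items():
            v = blk.W.c[mask]
            if v is None:
                out[key] = None
            elif mask == 0:
                out[key] = np.asarray(v)
            else:
                out[key] = np.asarray(v)[channel]
        return out

    def overlap(self, mask: int = 0, channel: Optional[int] = None):
        out = {}
        for key, blk in self.pairs.items():
            v = blk.S.c[mask]
            out[key] = None if v is None else (
                np.asarray(v) if mask == 0 else np.asarray(v)[channel])
        return out


def _cross(u, v):
    return [u[1] * v[2] - u[2] * v[1],
            u[2] * v[0] - u[0] * v[2],
            u[0] * v[1] - u[1] * v[0]]


def _orbital_betas(pjets, n):
    if n == 1:
        return [pjets["beta_s"]]
    return [pjets["beta_s"], pjets["beta_p"], pjets["beta_p"], pjets["beta_p"]]


def _beta_sum(col: Jet, row: Jet) -> Jet:
    """0.5 * (beta_mu + beta_nu) as an (na, nb) jet from orbital beta vectors."""
    out = []
    for m in range(8):
        x, y = col.c[m], row.c[m]
        if x is None and y is None:
            out.append(None)
            continue
        xs = 0.0 if x is None else np.asarray(x)[..., :, None]
        ys = 0.0 if y is None else np.asarray(y)[..., None, :]
        out.append(0.5 * (xs + ys))
    return Jet(out)


def _expand_transform(T: Jet, n: int) -> Jet:
    """Block-diagonal (1, T) orbital transform of size n."""
    if n == 1:
        return Jet([np.eye(1), None, None, None, None, None, None, None])
    out = []
    for m in range(8):
        v = T.c[m]
        if v is None:
            out.append(None)
            continue
        v = np.asarray(v)
        full = np.zeros(v.shape[:-2] + (4, 4))
        if m == 0:
            full[..., 0, 0] = 1.0
        full[..., 1:, 1:] = v
        out.append(full)
    return Jet(out)


def _extract(jet: Jet, mask: int, channel, shape):
    v = jet.c[mask]
    if v is None:
        return np.zeros(shape)
    v = np.asarray(v)
    if mask == 0:
        return v
    return v[channel]


class _JetAccumulator:
    """Accumulate scalar/block jet contributions into a jet-valued array."""

    def __init__(self, shape, nchan):
        self.shape = shape
        self.nchan = nchan
        self.comps = [None] * 8
        self.comps[0] = np.zeros(shape)

    def _ensure(self, mask):
        if self.comps[mask] is None:
            self.comps[mask] = np.zeros((self.nchan,) + self.shape)
        return self.comps[mask]

    def add_scalar(self, j: Jet, idx):
        j = Jet.lift(j)
        for m in range(8):
            v = j.c[m]
            if v is None:
                continue
            tgt = self.comps[0] if m == 0 else self._ensure(m)
            tgt[(Ellipsis,) + idx] += v

    def add_block(self, j: Jet, sa: slice, sb: slice):
        for m in range(8):
            v = j.c[m]
            if v is None:
                continue
            tgt = self.comps[0] if m == 0 else self._ensure(m)
            tgt[..., sa, sb] += v

    def jet(self) -> Jet:
        return Jet(self.comps)
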
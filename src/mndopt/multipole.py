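"""Two-center two-electron integrals: the point-multipole model.

Every NDDO charge distribution formed by a valence orbital pair on one atom
is represented by a small point-charge configuration (monopole, dipole,
linear quadrupole or square quadrupole) with characteristic separations

    D1 = <s| z |p>  and  D2 = sqrt(<p| r^2 |p> / 5)

of the Slater valence shell, and each multipole-multipole interaction is
damped in Klopman-Ohno fashion,

    e^2 / sqrt(r_ij^2 + (rho_lA + rho_lB)^2) ,

with additive terms rho_0, rho_1, rho_2 per atom fixed by requiring that the
zero-distance limits of the monopole-monopole, dipole-dipole and
quadrupole-quadrupole self-interactions reproduce the one-center integrals
G_ss, H_sp and (G_pp - G_p2)/2.  rho_0 is closed form; rho_1 and rho_2 solve
transcendental conditions by Newton iteration, re-iterated in jet arithmetic
so that their zeta-derivatives (through D1, D2) are exact.

All quantities here are in eV/angstrom; zeta inputs in 1/bohr.  Local frame:
atom A at the origin, atom B at (0, 0, R); basis order (s, px, py, pz).
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional, Tuple

import numpy as np

from .constants import BOHR, E2
from .jets import Jet, jet_stack, jsqrt


def dipole_separation(n: int, zs, zp):
    """D1 = <s|z|p> for principal quantum number n, in angstrom."""
    num = (4.0 * zs * zp) ** (n + 0.5) * (2 * n + 1)
    den = (zs + zp) ** (2 * n + 2) * math.sqrt(3.0)
    return num / den * BOHR


def quadrupole_separation(n: int, zp):
    """D2 = sqrt(<r^2>/5) of the p shell, in angstrom."""
    return math.sqrt((2 * n + 1) * (2 * n + 2) / 20.0) / zp * BOHR


def _jet_quadrupole_separation(n: int, zp: Jet):
    return math.sqrt((2 * n + 1) * (2 * n + 2) / 20.0) * BOHR / zp


def _jet_dipole_separation(n: int, zs: Jet, zp: Jet):
    num = (4.0 * zs * zp) ** (n + 0.5) * (2 * n + 1)
    return num / ((zs + zp) ** (2 * n + 2)) * (BOHR / math.sqrt(3.0))


def rho_monopole(g_ss: float):
    return E2 / (2.0 * g_ss)


def _dipole_self(rho, d1):
    """[mu mu] self-interaction at zero separation."""
    return 0.25 * E2 * (1.0 / rho - 1.0 / jsqrt(d1 * d1 + rho * rho))


def _quadrupole_self(rho, d2):
    """[Q Q] self-interaction of two square quadrupoles at zero separation.

    The additive term rho2 is fixed by equating this to the one-center
    integral (p p'|p p') = (G_pp - G_p2)/2; the square (p_x p_y type)
    configuration is the conventional choice and reproduces published
    MNDO-formalism energetics (the linear-quadrupole condition shifts every
    heavy-heavy bond by ~15 kcal/mol).
    """
    return E2 * (1.0 / 8.0 / rho
                 - 0.25 / jsqrt(d2 * d2 + rho * rho)
                 + 1.0 / 8.0 / jsqrt(2.0 * d2 * d2 + rho * rho))


def _newton_rho(self_fn, target: float, d_val: float) -> float:
    """Solve self_fn(rho, d) = target for rho > 0 (float level)."""
    lo, hi = 1e-4, 50.0
    rho = E2 / (4.0 * target)  # monopole-like initial scale
    for _ in range(200):
        f = float(Jet.lift(self_fn(Jet.const(rho), Jet.const(d_val))).val) - target
        if f > 0:
            lo = max(lo, rho)
        else:
            hi = min(hi, rho)
        h = 1e-7 * rho
        fp = (float(Jet.lift(self_fn(Jet.const(rho + h), Jet.const(d_val))).val)
              - float(Jet.lift(self_fn(Jet.const(rho - h), Jet.const(d_val))).val)) / (2 * h)
        step = f / fp
        new = rho - step
        if not (lo < new < hi):
            new = 0.5 * (lo + hi)
        if abs(new - rho) < 1e-15 * rho:
            rho = new
            break
        rho = new
    return rho


def _refine_rho_jet(self_fn, target: float, rho0: float, d_jet: Jet) -> Jet:
    """Implicit differentiation via Newton re-iteration in jet arithmetic."""
    h = 1e-7 * rho0
    fp = (float(Jet.lift(self_fn(Jet.const(rho0 + h), Jet.const(float(np.asarray(d_jet.val))))).val)
          - float(Jet.lift(self_fn(Jet.const(rho0 - h),
                                   Jet.const(float(np.asarray(d_jet.val))))).val)) / (2 * h)
    rho = Jet.const(rho0)
    for _ in range(4):
        rho = rho - (self_fn(rho, d_jet) - target) * (1.0 / fp)
    return rho


class AtomMultipoles:
    """Multipole data (D1, D2, rho0, rho1, rho2) for one atom, jet-valued."""

    def __init__(self, element: str, n_shell: int, one_center: Dict[str, float],
                 zs: Jet, zp: Optional[Jet]):
        self.element = element
        self.has_p = zp is not None
        self.rho0 = Jet.const(rho_monopole(one_center["G_ss"]))
        if self.has_p:
            self.D1 = _jet_dipole_separation(n_shell, zs, zp)
            self.D2 = _jet_quadrupole_separation(n_shell, zp)
            hsp = one_center["H_sp"]
            hpp = 0.5 * (one_center["G_pp"] - one_center["G_p2"])
            d1v = float(np.asarray(self.D1.val))
            d2v = float(np.asarray(self.D2.val))
            self.rho1 = _refine_rho_jet(_dipole_self, hsp,
                                        _newton_rho(_dipole_self, hsp, d1v), self.D1)
            self.rho2 = _refine_rho_jet(_quadrupole_self, hpp,
                                        _newton_rho(_quadrupole_self, hpp, d2v), self.D2)
        else:
            self.D1 = self.D2 = self.rho1 = self.rho2 = None
        self._dists = None

    def rho(self, order: int) -> Jet:
        return (self.rho0, self.rho1, self.rho2)[order]

    def distributions(self) -> Dict[Tuple[int, int], List]:
        if self._dists is None:
            self._dists = self._build_distributions()
        return self._dists

    def _build_distributions(self) -> Dict[Tuple[int, int], List]:
        """Point-charge configurations per (mu <= nu) local orbital pair.

        Each entry: list of (order, charges, positions) where charges is an
        (k,) float array and positions an (k, 3) jet array (angstrom).
        """
        zero = Jet.const(0.0)
        mono = (0, np.array([1.0]), jet_stack([jet_stack([zero, zero, zero])], axis=-2))
        out = {(0, 0): [mono]}
        if not self.has_p:
            return out
        D1, D2 = self.D1, self.D2
        for ax, idx in ((0, 1), (1, 2), (2, 3)):  # (s,p_ax) dipoles
            pos = [[zero] * 3, [zero] * 3]
            pos[0][ax] = D1
            pos[1][ax] = -1.0 * D1
            out[(0, idx)] = [(1, np.array([0.5, -0.5]),
                             jet_stack([jet_stack(p) for p in pos], axis=-2))]
        for ax, idx in ((0, 1), (1, 2), (2, 3)):  # (p,p) monopole + linear quadrupole
            pos = [[zero] * 3, [zero] * 3, [zero] * 3]
            pos[0][ax] = 2.0 * D2
            pos[1][ax] = -2.0 * D2
            out[(idx, idx)] = [mono,
                               (2, np.array([0.25, 0.25, -0.5]),
                                jet_stack([jet_stack(p) for p in pos], axis=-2))]
        for (ax1, ax2), key in (((0, 1), (1, 2)), ((0, 2), (1, 3)), ((1, 2), (2, 3))):
            pos = []
            chg = []
            for s1 in (1.0, -1.0):
                for s2 in (1.0, -1.0):
                    p = [zero] * 3
                    p[ax1] = s1 * D2
                    p[ax2] = s2 * D2
                    pos.append(p)
                    chg.append(0.25 * s1 * s2)
            out[key] = [(2, np.array(chg),
                         jet_stack([jet_stack(p) for p in pos], axis=-2))]
        return out


def pair_two_electron(matA: AtomMultipoles, matB: AtomMultipoles, R: Jet):
    """Local-frame two-center tensor (mu nu | la si), eV; atom B at (0,0,R).

    Returns a jet with value shape (na, na, nb, nb).  All charge-pair
    interactions of all distribution pairs are evaluated in one flattened
    jet computation, then segment-summed into the orbital-pair entries.
    """
    na = 4 if matA.has_p else 1
    nb = 4 if matB.has_p else 1
    distA = matA.distributions()
    distB = matB.distributions()
    zero = Jet.const(0.0)
    shiftB = jet_stack([zero, zero, R])

    # flatten: one interaction per distinct (config_A, config_B) pair
    cfgsA = {}
    for key, cfgs in distA.items():
        for c in cfgs:
            cfgsA.setdefault(id(c), (key, c))
    cfgsB = {}
    for key, cfgs in distB.items():
        for c in cfgs:
            cfgsB.setdefault(id(c), (key, c))
    uA = [c for _, c in cfgsA.values()]
    uB = [c for _, c in cfgsB.values()]

    posA = _concat_positions([p for _, _, p in uA])      # (KA, 3) jet
    posB = _concat_positions([p for _, _, p in uB])      # (KB, 3) jet
    kA = [np.shape(p.c[0])[0] for _, _, p in uA]
    kB = [np.shape(p.c[0])[0] for _, _, p in uB]
    offA = np.cumsum([0] + kA)
    offB = np.cumsum([0] + kB)
    qA = np.concatenate([q for _, q, _ in uA])
    qB = np.concatenate([q for _, q, _ in uB])

    # damping per charge pair: (rho_{lA} + rho_{lB})^2 with per-config orders
    rhoA = [matA.rho(l) for l, _, _ in uA]
    rhoB = [matB.rho(l) for l, _, _ in uB]
    rho_a = _stack_per_charge(rhoA, kA)                  # (KA,) jet
    rho_b = _stack_per_charge(rhoB, kB)                  # (KB,) jet
    rho = Jet([None if (a is None and b is None) else
               (0.0 if a is None else np.asarray(a)[..., :, None])
               + (0.0 if b is None else np.asarray(b)[..., None, :])
               for a, b in zip(rho_a.c, rho_b.c)])

    diff = Jet([None if (ca is None and cb is None and cs is None) else
                (0.0 if ca is None else np.asarray(ca)[..., :, None, :])
                - (0.0 if cb is None else np.asarray(cb)[..., None, :, :])
                - (0.0 if cs is None else np.asarray(cs)[..., None, None, :])
                for ca, cb, cs in zip(posA.c, posB.c, shiftB.c)])
    d2 = Jet.const(0.0)
    for axi in range(3):
        comp = Jet([None if v is None else np.asarray(v)[..., axi]
                    for v in diff.c])
        d2 = d2 + comp * comp
    inv = (1.0 / jsqrt(d2 + rho * rho)) * (E2 * np.outer(qA, qB))

    # segment-sum the (KA, KB) interaction grid into per-config-pair scalars
    sums = []
    for v in inv.c:
        if v is None:
            sums.append(None)
            continue
        v = np.asarray(v)
        rowsum = np.add.reduceat(v, offA[:-1], axis=-2)
        sums.append(np.add.reduceat(rowsum, offB[:-1], axis=-1))
    block = Jet(sums)   # (..., nCfgA, nCfgB)

    idxA = {cid: k for k, cid in enumerate(cfgsA)}
    idxB = {cid: k for k, cid in enumerate(cfgsB)}
    entries = {}
    for (m, n), cfgsa in distA.items():
        for (l, s), cfgsb in distB.items():
            acc = Jet.const(0.0)
            for ca in cfgsa:
                for cb in cfgsb:
                    acc = acc + block[idxA[id(ca)], idxB[id(cb)]]
            entries[(m, n, l, s)] = acc
    return _materialize(entries, na, nb)


def _concat_positions(pos_jets):
    """Concatenate (k,3) position jets along the charge axis."""
    out = []
    for mask in range(8):
        comps = [p.c[mask] for p in pos_jets]
        if all(c is None for c in comps):
            out.append(None)
            continue
        mats = []
        lead = ()
        for p, c in zip(pos_jets, comps):
            if c is not None:
                lead = np.broadcast_shapes(lead, np.shape(c)[:-2])
        for p, c in zip(pos_jets, comps):
            k = np.shape(p.c[0])[0]
            if c is None:
                mats.append(np.zeros(lead + (k, 3)))
            else:
                mats.append(np.broadcast_to(np.asarray(c),
                                            lead + np.shape(c)[-2:]))
        out.append(np.concatenate(mats, axis=-2))
    return Jet(out)


def _stack_per_charge(rho_jets, counts):
    """Per-charge damping values: repeat each config's rho over its charges."""
    out = []
    for mask in range(8):
        comps = [r.c[mask] for r in rho_jets]
        if all(c is None for c in comps):
            out.append(None)
            continue
        lead = ()
        for c in comps:
            if c is not None:
                lead = np.broadcast_shapes(lead, np.shape(c))
        cols = []
        for c, k in zip(comps, counts):
            base = np.zeros(lead) if c is None else np.broadcast_to(
                np.asarray(c), lead)
            cols.append(np.repeat(base[..., None], k, axis=-1))
        out.append(np.concatenate(cols, axis=-1))
    return Jet(out)


def _materialize(entries, na, nb):
    """Assemble the (na,na,nb,nb) jet from symmetry-distinct entries."""
    comps = []
    for mask in range(8):
        shapes = [np.shape(e.c[mask]) for e in entries.values() if e.c[mask] is not None]
        if not shapes and mask != 0:
            comps.append(None)
            continue
        lead = np.broadcast_shapes(*shapes) if shapes else ()
        arr = np.zeros(lead + (na, na, nb, nb))
        for (m, n, l, s), e in entries.items():
            v = e.c[mask]
            if v is None:
                continue
            for (i, j) in {(m, n), (n, m)}:
                for (k, h) in {(l, s), (s, l)}:
                    arr[..., i, j, k, h] = v
        comps.append(arr)
    return Jet(comps)
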
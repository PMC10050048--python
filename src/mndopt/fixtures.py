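"""Fixture molecules and the synthetic training-set generator.

Geometries are literature-style experimental structures for small CHNOF
molecules, constructed programmatically (angstrom).  The generator computes
reference heats of formation, ionization energies and dipole moments with
the engine itself at a chosen parameter vector p*, optionally adding
Gaussian noise, so that parameter recovery is a closed loop: with zero noise
the error function has a global minimum S = 0 at p*.

Ionization-energy references are only emitted for molecules whose HOMO is
safely non-degenerate (Koopmans derivative well-defined), dipole references
only for closed shells with a clearly nonzero dipole.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional, Sequence

import numpy as np

from .cphf import DEGENERACY_THRESHOLD
from .molecules import Molecule, TrainingEntry
from .params import ParameterSet
from .properties import compute_properties
from .scf import ScfError, scf_solve


def _diatomic(name, a, b, r, mult=1):
    return Molecule(name, (a, b), [[0, 0, 0], [0, 0, r]], multiplicity=mult)


def _bent(name, center, outer, r, angle_deg, mult=1):
    t = math.radians(angle_deg)
    return Molecule(name, (center, outer, outer),
                    [[0, 0, 0], [r, 0, 0], [r * math.cos(t), r * math.sin(t), 0]],
                    multiplicity=mult)


def _linear(name, symbols, bonds, mult=1):
    z = [0.0]
    for b in bonds:
        z.append(z[-1] + b)
    return Molecule(name, symbols, [[0, 0, zz] for zz in z], multiplicity=mult)


def _pyramidal(name, apex, base, r, angle_deg, mult=1):
    """XY3 with Y-X-Y angle angle_deg."""
    t = math.radians(angle_deg)
    # polar angle theta of the three bonds from the C3 axis
    ct = 1.0 - 1.5 * (1.0 - math.cos(t))  # hmm replaced below by exact relation
    # exact: cos(angle) = 1.5*sin^2(theta)*(-0.5) ... use direct formula:
    # for bonds at polar angle th, azimuths 0,120,240: cos(angle)=sin^2 th cos120 + cos^2 th
    # => cos(angle) = cos^2 th - sin^2 th / 2  => sin^2 th = 2(1-cos angle)/3
    s2 = 2.0 * (1.0 - math.cos(t)) / 3.0
    th = math.asin(math.sqrt(min(s2, 1.0)))
    coords = [[0.0, 0.0, 0.0]]
    for k in range(3):
        ph = 2.0 * math.pi * k / 3.0
        coords.append([r * math.sin(th) * math.cos(ph),
                       r * math.sin(th) * math.sin(ph),
                       -r * math.cos(th)])
    return Molecule(name, (apex,) + (base,) * 3, coords, multiplicity=mult)


def _tetrahedral(name, center, outer, r, subst: Optional[Dict[int, tuple]] = None):
    d = r / math.sqrt(3.0)
    syms = [center] + [outer] * 4
    coords = [[0, 0, 0], [d, d, d], [d, -d, -d], [-d, d, -d], [-d, -d, d]]
    if subst:
        for idx, (sym, rr) in subst.items():
            syms[idx] = sym
            coords[idx] = list(np.array(coords[idx]) * (rr / r))
    return Molecule(name, syms, coords)


def _planar_x3(name, center, outer, r, mult=1):
    coords = [[0.0, 0.0, 0.0]]
    for k in range(3):
        ph = 2.0 * math.pi * k / 3.0
        coords.append([r * math.cos(ph), r * math.sin(ph), 0.0])
    return Molecule(name, (center,) + (outer,) * 3, coords, multiplicity=mult)


def _build_library() -> Dict[str, Molecule]:
    mols: Dict[str, Molecule] = {}

    def add(m):
        mols[m.name] = m

    add(_diatomic("H2", "H", "H", 0.741))
    add(_diatomic("HF", "H", "F", 0.917))
    add(_diatomic("N2", "N", "N", 1.098))
    add(_diatomic("CO", "C", "O", 1.128))
    add(_diatomic("F2", "F", "F", 1.412))
    # hydroperoxyl radical (bent doublet with a well-separated SOMO; the
    # hydroxyl radical's degenerate pi^3 shell makes its UHF response
    # singular and is avoided)
    t = math.radians(104.3)
    add(Molecule("HO2", ("O", "O", "H"),
                 [[0, 0, 0], [0, 0, 1.331],
                  [0.971 * math.sin(t), 0, -0.971 * math.cos(t)]],
                 multiplicity=2))

    add(_bent("H2O", "O", "H", 0.9572, 104.52))
    add(_bent("NH2", "N", "H", 1.024, 103.4, mult=2))
    add(_bent("OF2", "O", "F", 1.405, 103.1))
    add(_linear("CO2", ("O", "C", "O"), [1.162, 1.162]))
    add(_linear("HCN", ("H", "C", "N"), [1.065, 1.153]))
    add(_linear("HNC", ("H", "N", "C"), [0.994, 1.169]))
    add(_linear("N2O", ("N", "N", "O"), [1.128, 1.184]))
    add(_linear("FCN", ("F", "C", "N"), [1.262, 1.159]))

    # HOF: O at origin, H and F in the xy plane
    t = math.radians(97.2)
    add(Molecule("HOF", ("O", "H", "F"),
                 [[0, 0, 0], [0.966, 0, 0], [1.442 * math.cos(t), 1.442 * math.sin(t), 0]]))
    t = math.radians(108.6)
    add(Molecule("HNO", ("N", "H", "O"),
                 [[0, 0, 0], [1.063, 0, 0], [1.212 * math.cos(t), 1.212 * math.sin(t), 0]]))

    add(_pyramidal("NH3", "N", "H", 1.012, 106.7))
    add(_pyramidal("NF3", "N", "F", 1.371, 102.2))
    add(_planar_x3("CH3", "C", "H", 1.079, mult=2))

    # formaldehyde, in the xz plane
    t = math.radians(121.9)
    add(Molecule("H2CO", ("C", "O", "H", "H"),
                 [[0, 0, 0], [0, 0, 1.205],
                  [1.111 * math.sin(t), 0, 1.111 * math.cos(t)],
                  [-1.111 * math.sin(t), 0, 1.111 * math.cos(t)]]))
    # carbonyl fluoride
    t = math.radians(126.1)
    add(Molecule("CF2O", ("C", "O", "F", "F"),
                 [[0, 0, 0], [0, 0, 1.172],
                  [1.316 * math.sin(t), 0, 1.316 * math.cos(t)],
                  [-1.316 * math.sin(t), 0, 1.316 * math.cos(t)]]))
    # formyl fluoride H-C(=O)F
    add(Molecule("HCOF", ("C", "O", "F", "H"),
                 [[0, 0, 0], [0, 0, 1.181],
                  [1.338 * math.sin(math.radians(122.8)), 0,
                   1.338 * math.cos(math.radians(122.8))],
                  [-1.095 * math.sin(math.radians(127.3)), 0,
                   1.095 * math.cos(math.radians(127.3))]]))
    # hydrogen peroxide with its skew dihedral
    oo, ohb, ang, dih = 1.475, 0.950, math.radians(94.8), math.radians(111.5)
    sa = math.sin(math.pi - ang)
    ca = math.cos(math.pi - ang)
    add(Molecule("H2O2", ("O", "O", "H", "H"),
                 [[0, 0, 0], [0, 0, oo],
                  [ohb * sa, 0, -ohb * ca],
                  [ohb * sa * math.cos(dih), ohb * sa * math.sin(dih), oo + ohb * ca]]))
    add(_linear("C2H2", ("H", "C", "C", "H"), [1.063, 1.203, 1.063]))
    add(_linear("C2F2", ("F", "C", "C", "F"), [1.283, 1.198, 1.283]))
    add(_linear("C2N2", ("N", "C", "C", "N"), [1.154, 1.389, 1.154]))

    # hydrazine (gauche)
    nn, nh = 1.449, 1.021
    th = math.radians(112.0)
    dphi = math.radians(59.5)
    g = math.radians(95.0)
    coords = [[0, 0, 0], [0, 0, nn]]
    for ph in (dphi, -dphi):
        coords.append([nh * math.sin(th) * math.cos(ph),
                       nh * math.sin(th) * math.sin(ph),
                       nh * math.cos(th)])
    for ph in (g + dphi, g - dphi):
        coords.append([nh * math.sin(th) * math.cos(ph),
                       nh * math.sin(th) * math.sin(ph),
                       nn - nh * math.cos(th)])
    add(Molecule("N2H4", ("N", "N", "H", "H", "H", "H"), coords))
    # trans-difluorodiazene F-N=N-F
    t = math.radians(105.5)
    nn, nf = 1.214, 1.389
    add(Molecule("N2F2", ("N", "N", "F", "F"),
                 [[0, 0, 0], [0, 0, nn],
                  [nf * math.sin(t), 0, -nf * math.cos(t)],
                  [-nf * math.sin(t), 0, nn + nf * math.cos(t)]]))

    add(_tetrahedral("CH4", "C", "H", 1.087))
    add(_tetrahedral("CF4", "C", "F", 1.320))
    add(_tetrahedral("CH3F", "C", "H", 1.087, subst={1: ("F", 1.383)}))
    add(_tetrahedral("CHF3", "C", "F", 1.328, subst={1: ("H", 1.098)}))
    add(_tetrahedral("CH2F2", "C", "H", 1.093,
                     subst={1: ("F", 1.357), 2: ("F", 1.357)}))

    # ethylene, planar in xz
    t = math.radians(121.2)
    cc, ch = 1.339, 1.086
    add(Molecule("C2H4", ("C", "C", "H", "H", "H", "H"),
                 [[0, 0, 0], [0, 0, cc],
                  [ch * math.sin(t), 0, ch * math.cos(t)],
                  [-ch * math.sin(t), 0, ch * math.cos(t)],
                  [ch * math.sin(t), 0, cc - ch * math.cos(t)],
                  [-ch * math.sin(t), 0, cc - ch * math.cos(t)]]))
    # methanimine CH2=NH
    add(Molecule("CH2NH", ("C", "N", "H", "H", "H"),
                 [[0, 0, 0], [0, 0, 1.273],
                  [1.09 * math.sin(math.radians(119)), 0,
                   -1.09 * math.cos(math.radians(61))],
                  [-1.09 * math.sin(math.radians(119)), 0,
                   -1.09 * math.cos(math.radians(61))],
                  [1.023 * math.sin(math.radians(110)), 0,
                   1.273 + 1.023 * math.cos(math.radians(70)) * 0 +
                   1.023 * math.cos(math.radians(110))]]))
    # formic acid (planar, trans)
    add(Molecule("HCOOH", ("C", "O", "O", "H", "H"),
                 [[0, 0, 0], [0, 0, 1.202],
                  [1.343 * math.sin(math.radians(124.9)), 0,
                   1.343 * math.cos(math.radians(124.9))],
                  [-1.097 * math.sin(math.radians(111.0)), 0,
                   1.097 * math.cos(math.radians(111.0))],
                  [1.343 * math.sin(math.radians(124.9)) +
                   0.972 * math.sin(math.radians(18.0)), 0,
                   1.343 * math.cos(math.radians(124.9)) -
                   0.972 * math.cos(math.radians(18.0))]]))

    # staggered ethane
    cc, ch, hcc = 1.536, 1.091, math.radians(111.2)
    top, bot = [], []
    for k in range(3):
        ph = 2.0 * math.pi * k / 3.0
        top.append([ch * math.sin(math.pi - hcc) * math.cos(ph),
                    ch * math.sin(math.pi - hcc) * math.sin(ph),
                    -ch * math.cos(math.pi - hcc)])
    for k in range(3):
        ph = 2.0 * math.pi * k / 3.0 + math.pi / 3.0
        bot.append([ch * math.sin(math.pi - hcc) * math.cos(ph),
                    ch * math.sin(math.pi - hcc) * math.sin(ph),
                    cc + ch * math.cos(math.pi - hcc)])
    add(Molecule("C2H6", ("C", "C") + ("H",) * 6,
                 [[0, 0, 0], [0, 0, cc]] + top + bot))

    # methanol (staggered, Cs)
    co, oh, ch = 1.427, 0.956, 1.096
    tco = math.radians(108.5)
    hs = []
    for k in range(3):
        ph = 2.0 * math.pi * k / 3.0 + math.pi
        hs.append([ch * math.sin(math.radians(70.5)) * math.cos(ph),
                   ch * math.sin(math.radians(70.5)) * math.sin(ph),
                   -ch * math.cos(math.radians(70.5))])
    add(Molecule("CH3OH", ("C", "O", "H", "H", "H", "H"),
                 [[0, 0, 0], [0, 0, co],
                  [oh * math.sin(tco), 0, co - oh * math.cos(tco)]] + hs))

    # methylamine (staggered, Cs)
    cn, nh, ch = 1.471, 1.010, 1.093
    hs = []
    for k in range(3):
        ph = 2.0 * math.pi * k / 3.0 + math.pi
        hs.append([ch * math.sin(math.radians(70.0)) * math.cos(ph),
                   ch * math.sin(math.radians(70.0)) * math.sin(ph),
                   -ch * math.cos(math.radians(70.0))])
    tn = math.radians(112.0)
    hn = []
    for sgn in (1.0, -1.0):
        hn.append([nh * math.sin(tn) * math.cos(math.radians(54.0)) * 1.0,
                   sgn * nh * math.sin(tn) * math.sin(math.radians(54.0)),
                   cn - nh * math.cos(tn)])
    add(Molecule("CH3NH2", ("C", "N") + ("H",) * 5,
                 [[0, 0, 0], [0, 0, cn]] + hs + hn))

    # acetonitrile
    cc, cn, ch = 1.458, 1.157, 1.092
    hs = []
    for k in range(3):
        ph = 2.0 * math.pi * k / 3.0
        hs.append([ch * math.sin(math.radians(70.2)) * math.cos(ph),
                   ch * math.sin(math.radians(70.2)) * math.sin(ph),
                   -ch * math.cos(math.radians(70.2))])
    add(Molecule("CH3CN", ("C", "C", "N") + ("H",) * 3,
                 [[0, 0, 0], [0, 0, cc], [0, 0, cc + cn]] + hs))

    return mols


_LIBRARY = _build_library()


def fixture_molecule(name: str) -> Molecule:
    return _LIBRARY[name]


def fixture_names() -> List[str]:
    return sorted(_LIBRARY)


# curated suites
SUITE_DERIVATIVES = ("H2", "HF", "H2O", "NH3", "CH4", "CO", "HCN",
                     "CH3F", "H2O2", "NH2")
SUITE_RECOVERY = ("H2", "HF", "H2O", "NH3", "CH4", "CO", "CO2", "HCN", "N2",
                  "F2", "CH3F", "H2CO", "HOF", "OF2", "N2O", "FCN", "HNC",
                  "C2H2", "CF2O", "NF3", "CH2F2", "H2O2", "C2H4", "HNO", "CHF3")
SUITE_FULL = tuple(sorted(_LIBRARY))


def suite(names: Sequence[str]) -> List[Molecule]:
    return [fixture_molecule(n) for n in names]


def generate_reference_data(molecules: Sequence[Molecule], pset: ParameterSet,
                            noise: Optional[Dict[str, float]] = None,
                            seed: int = 0, include_geo: bool = False,
                            geo_fraction: float = 0.25,
                            dip_threshold: float = 0.1) -> List[TrainingEntry]:
    """Synthesize training entries from engine properties at ``pset``.

    With ``noise=None`` references equal the model values exactly, so the
    error function has a global minimum S = 0 at ``pset``.  ``noise`` maps
    property keys to Gaussian sigmas (kcal/mol, eV, debye).  Geometry (|g|)
    terms, whose reference is fixed at zero, are only added when
    ``include_geo`` (on the first ``geo_fraction`` of the set, deterministic
    under the seed).
    """
    rng = np.random.default_rng(seed)
    entries: List[TrainingEntry] = []
    n_geo = int(round(geo_fraction * len(molecules))) if include_geo else 0
    for k, mol in enumerate(molecules):
        try:
            state = scf_solve(mol, pset)
        except ScfError:
            if noise is None:
                raise
            continue
        pr = compute_properties(state, want_grad=False)
        kw = {}
        kw["hf"] = pr.hf
        if _homo_isolated(state):
            kw["ie"] = pr.ie
        if state.closed_shell and pr.dip > dip_threshold:
            kw["dip"] = pr.dip
        if noise:
            if "hf" in kw and noise.get("hf"):
                kw["hf"] += rng.normal(0.0, noise["hf"])
            if "ie" in kw and noise.get("ie"):
                kw["ie"] += rng.normal(0.0, noise["ie"])
            if "dip" in kw and noise.get("dip"):
                kw["dip"] = abs(kw["dip"] + rng.normal(0.0, noise["dip"]))
        entries.append(TrainingEntry(mol, geo=(k < n_geo), **kw))
    return entries


def _homo_isolated(state, gap: float = 50 * DEGENERACY_THRESHOLD) -> bool:
    s, h = state.homo()
    eps = state.eps[s]
    gaps = [abs(eps[k] - eps[h]) for k in range(len(eps)) if k != h]
    if gaps and min(gaps) < gap:
        return False
    if not state.closed_shell:
        so = 1 - s
        ho = state.n_occ[so] - 1
        if ho >= 0 and abs(state.eps[so][ho] - eps[h]) < gap:
            return False
    return True
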
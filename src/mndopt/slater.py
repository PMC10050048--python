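"""Slater-orbital overlap integrals in the local diatomic frame.

Valence shells only: 1s for hydrogen, 2s/2p for first-row atoms.  The
overlap is evaluated in prolate spheroidal coordinates, where every s/p
Slater-orbital product reduces to a pure polynomial in (xi, eta) times
exp(-p*xi - q*eta), so the integral is an exact finite combination of the
auxiliary integrals

    A_k(p) = int_1^inf  x^k exp(-p x) dx
    B_k(q) = int_-1^1   x^k exp(-q x) dx .

B_k is evaluated by its Taylor series for small |q| (covering the
zeta_A ~ zeta_B branch, free of 0/0 cancellation) and by the upward
recurrence otherwise.  All arithmetic is jet-compatible, so zeta- and
coordinate-derivatives of the overlap to mixed third order are exact.

Local frame convention: atom A at the origin, atom B on the +z axis at
distance R; p orbitals on both atoms point along the same local axes (both
sigma orbitals along +z), basis order (s, px, py, pz).
"""

from __future__ import annotations

import math

import numpy as np

from .constants import BOHR
from .jets import Jet, jexp, jsqrt

_SQ3 = math.sqrt(3.0)


class GeometryError(ValueError):
    pass


def _aux_A_scaled(kmax: int, p: Jet):
    """a_k = A_k(p) * e^p  (pure rational in 1/p; the exponential is applied
    jointly with the B-side scale to avoid overflow)."""
    inv = 1.0 / p
    out = []
    for k in range(kmax + 1):
        acc = Jet.const(0.0)
        term = inv
        for i in range(k + 1):
            acc = acc + term
            term = term * inv * (k - i)
        out.append(acc)
    return out


def _jet_where(mask, a: Jet, b: Jet) -> Jet:
    """Component-wise value-based branch select (mask over the value axis)."""
    out = []
    for x, y in zip(a.c, b.c):
        if x is None and y is None:
            out.append(None)
        else:
            xx = 0.0 if x is None else np.asarray(x)
            yy = 0.0 if y is None else np.asarray(y)
            out.append(np.where(mask, xx, yy))
    return Jet(out)


def _aux_B_series(kmax: int, q: Jet):
    """B_k(q) = sum_m (-q)^m/m! * 2/(k+m+1) over even k+m (|q| < 2)."""
    nterms = 26
    powers = [Jet.const(1.0) + 0.0 * q]
    for _ in range(nterms - 1):
        powers.append(powers[-1] * (-q))
    out = []
    for k in range(kmax + 1):
        acc = Jet.const(0.0)
        fact = 1.0
        for m in range(nterms):
            if m:
                fact *= m
            if (k + m) % 2 == 0:
                acc = acc + powers[m] * (2.0 / ((k + m + 1) * fact))
        out.append(acc)
    return out


def _aux_B_closed(kmax: int, q: Jet):
    """(b_k, |q|) with B_k = b_k e^{|q|}: upward recurrence, the dominant
    exponential factored out (use for |q| >= ~1)."""
    sgn_q = np.sign(np.asarray(q.val))
    aq = Jet([None if v is None else sgn_q * np.asarray(v) for v in q.c])
    epos = jexp(q - aq)
    eneg = jexp(-q - aq)
    inv = 1.0 / q
    out = [(epos - eneg) * inv]
    for k in range(1, kmax + 1):
        sgn = -epos if k % 2 else epos
        out.append((out[-1] * k + sgn - eneg) * inv)
    return out, aq


def _aux_B_scaled(kmax: int, q: Jet):
    """(b_k list, shift jet) with B_k(q) = b_k * e^shift, branch-safe for
    vector-valued q: Taylor series where |q| < 2 (no 0/0 cancellation),
    scaled upward recurrence elsewhere."""
    qv = np.asarray(q.val)
    series_mask = np.abs(qv) < 2.0
    if np.all(series_mask):
        return _aux_B_series(kmax, q), None
    if not np.any(series_mask):
        return _aux_B_closed(kmax, q)
    # mixed: evaluate the closed branch at a safe surrogate where the series
    # applies, then select per element
    q_safe = Jet([np.where(series_mask, 2.5, qv)] +
                 [None if v is None else np.where(series_mask, 0.0, np.asarray(v))
                  for v in q.c[1:]])
    ser = _aux_B_series(kmax, q)
    clo, aq = _aux_B_closed(kmax, q_safe)
    out = [_jet_where(series_mask, s, c) for s, c in zip(ser, clo)]
    shift = _jet_where(series_mask, Jet.const(0.0) + 0.0 * q, aq)
    return out, shift


def _poly_mul(pa, pb):
    out = {}
    for (i, j), ca in pa.items():
        for (k, l), cb in pb.items():
            key = (i + k, j + l)
            out[key] = out.get(key, 0.0) + ca * cb
    return out


# (xi,eta) polynomial factor and extra power of (R/2) per orbital type;
# the B-side radial factor is r_b = (R/2)(xi - eta) and z_b = (R/2)(xi eta - 1)
_FACTORS_A = {
    "s1": ({(0, 0): 1.0}, 0),
    "s2": ({(1, 0): 1.0, (0, 1): 1.0}, 1),
    "sig": ({(0, 0): 1.0, (1, 1): 1.0}, 1),
}
_FACTORS_B = {
    "s1": ({(0, 0): 1.0}, 0),
    "s2": ({(1, 0): 1.0, (0, 1): -1.0}, 1),
    "sig": ({(1, 1): 1.0, (0, 0): -1.0}, 1),
}
# joint pi(A)*pi(B) polynomial: rho_a * rho_b * cos^2(phi) -> (R/2)^2 (xi^2-1)(1-eta^2)
_PI_POLY = {(2, 0): 1.0, (2, 2): -1.0, (0, 0): -1.0, (0, 2): 1.0}
_VOL = {(2, 0): 1.0, (0, 2): -1.0}  # xi^2 - eta^2


def _norm(n: int, zeta):
    """Radial normalization (2 zeta)^(n+1/2)/sqrt((2n)!), zeta in 1/bohr."""
    tz = 2.0 * zeta
    if n == 1:
        return tz * jsqrt(tz) * (1.0 / math.sqrt(2.0))
    return tz * tz * jsqrt(tz) * (1.0 / math.sqrt(24.0))


def _entry_poly(fa, fb):
    if fa == "pipi":
        return _poly_mul(_VOL, _PI_POLY), 2
    pa, ra = _FACTORS_A[fa]
    pb, rb = _FACTORS_B[fb]
    return _poly_mul(_VOL, _poly_mul(pa, pb)), ra + rb


def _entries_stacked(specs, Rb):
    """Evaluate all overlap entries of one atom pair with a single stacked
    auxiliary-integral computation.

    ``specs``: list of (key, fa, fb, na, nb, za, zb, ang, phi).
    """
    from .jets import jet_stack
    za_st = jet_stack([s[5] for s in specs])
    zb_st = jet_stack([s[6] for s in specs])
    p = (za_st + zb_st) * (Rb * 0.5)
    q = (za_st - zb_st) * (Rb * 0.5)
    kmax = 6
    A = _aux_A_scaled(kmax, p)
    B, bshift = _aux_B_scaled(kmax, q)
    expo = jexp((bshift - p) if bshift is not None else -p)
    half_R = Rb * 0.5
    out = {}
    for e, (key, fa, fb, na, nb, za, zb, ang, phi) in enumerate(specs):
        poly, rpow = _entry_poly(fa, fb)
        acc = Jet.const(0.0)
        for (i, j), c in poly.items():
            acc = acc + A[i][e] * B[j][e] * c
        pref = _norm(na, za) * _norm(nb, zb) * (ang * phi / (4.0 * math.pi))
        out[key] = acc * expo[e] * (half_R ** (3 + rpow)) * pref
    return out


def overlap_pair(na: int, nb: int, zs_a, zp_a, zs_b, zp_b, R_ang):
    """Local-frame overlap sub-block between the valence shells of two atoms.

    Returns a dict {(i, j): Jet} over local basis indices (s, px, py, pz);
    only symmetry-distinct nonzero entries are present.  Exponents in 1/bohr
    (zp may be None for hydrogen), R in angstrom; all inputs may be jets.
    """
    R_ang = Jet.lift(R_ang)
    Rb = R_ang * (1.0 / BOHR)
    rb0 = float(np.asarray(Rb.val))
    if rb0 <= 1e-8:
        raise GeometryError("coincident atoms")
    zs_a, zs_b = Jet.lift(zs_a), Jet.lift(zs_b)
    # every entry is bounded by ~exp(-min(zeta) R); far beyond double
    # precision the values and all derivatives vanish (and the closed-form
    # B_k branch would overflow), so return structural zeros
    zmin = min(float(np.asarray(Jet.lift(z).val))
               for z in (zs_a, zp_a, zs_b, zp_b) if z is not None)
    if zmin * rb0 > 60.0:
        zero = Jet.const(0.0)
        out = {(0, 0): zero}
        if nb == 2:
            out[(0, 3)] = zero
        if na == 2:
            out[(3, 0)] = zero
        if na == 2 and nb == 2:
            out[(3, 3)] = out[(1, 1)] = out[(2, 2)] = zero
        return out
    ta = "s1" if na == 1 else "s2"
    tb = "s1" if nb == 1 else "s2"
    tp = 2.0 * math.pi
    specs = [((0, 0), ta, tb, na, nb, zs_a, zs_b, 1.0, tp)]
    if nb == 2:
        zp_b = Jet.lift(zp_b)
        specs.append(((0, 3), ta, "sig", na, 2, zs_a, zp_b, _SQ3, tp))
    if na == 2:
        zp_a = Jet.lift(zp_a)
        specs.append(((3, 0), "sig", tb, 2, nb, zp_a, zs_b, _SQ3, tp))
    if na == 2 and nb == 2:
        specs.append(((3, 3), "sig", "sig", 2, 2, zp_a, zp_b, 3.0, tp))
        specs.append(((1, 1), "pipi", None, 2, 2, zp_a, zp_b, 3.0, math.pi))
    out = _entries_stacked(specs, Rb)
    if na == 2 and nb == 2:
        out[(2, 2)] = out[(1, 1)]
    return out
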
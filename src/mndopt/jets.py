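"""Multilinear forward-mode differentiation ("jets").

A :class:`Jet` carries a value together with mixed partial derivatives along
up to three tagged directions, truncated multilinearly: every tracked
derivative differentiates along each direction at most once.  The eight
components are indexed by the bitmask of directions,

    c[0]               value
    c[1], c[2], c[4]   d/d1, d/d2, d/d3
    c[3], c[5], c[6]   d2/d1d2, d2/d1d3, d2/d2d3
    c[7]               d3/d1d2d3

which is exactly the set of derivatives needed for parameter pairs (d1, d2)
and one Cartesian direction (d3).  Equal-parameter second derivatives are
obtained by seeding two directions with the same unit seed.  Components may
be scalars or numpy arrays of mutually broadcastable shapes; the sentinel
``None`` marks a structurally zero component, so arithmetic skips it.

Propagating closed-form expressions in jet arithmetic yields derivatives that
are exact to machine precision (this is automatic differentiation, not finite
differencing).
"""

from __future__ import annotations

import numpy as np

# (submask, complement) pairs for the multilinear product, per output mask
_MUL = {
    0: ((0, 0),),
    1: ((0, 1), (1, 0)),
    2: ((0, 2), (2, 0)),
    3: ((0, 3), (1, 2), (2, 1), (3, 0)),
    4: ((0, 4), (4, 0)),
    5: ((0, 5), (1, 4), (4, 1), (5, 0)),
    6: ((0, 6), (2, 4), (4, 2), (6, 0)),
    7: ((0, 7), (1, 6), (2, 5), (3, 4), (4, 3), (5, 2), (6, 1), (7, 0)),
}

_SINGLES = (1, 2, 4)
_PAIRS = {3: (1, 2), 5: (1, 4), 6: (2, 4)}


def _pad(d, extra):
    """Insert ``extra`` unit axes after the leading channel axis."""
    d = np.asarray(d)
    return d.reshape(d.shape[:1] + (1,) * extra + d.shape[1:])


def _add_deriv(a, b):
    """Sum of two derivative components (leading channel axis), rank-aligned."""
    if a is None:
        return b
    if b is None:
        return a
    ra, rb = np.ndim(a) - 1, np.ndim(b) - 1
    if ra < rb:
        a = _pad(a, rb - ra)
    elif rb < ra:
        b = _pad(b, ra - rb)
    return a + b


def _add(a, b):
    if a is None:
        return b
    if b is None:
        return a
    return a + b


def _mul(a, b, s=0, t=0):
    """Product of components; s/t flag which operands carry a channel axis.

    Derivative components carry a leading channel axis; value components do
    not.  Ranks are aligned so that numpy broadcasting never pairs the
    channel axis with a value axis.
    """
    if a is None or b is None:
        return None
    if s and t:
        ra, rb = np.ndim(a) - 1, np.ndim(b) - 1
        if ra < rb:
            a = _pad(a, rb - ra)
        elif rb < ra:
            b = _pad(b, ra - rb)
    elif s and not t:
        ra, rb = np.ndim(a) - 1, np.ndim(b)
        if ra < rb:
            a = _pad(a, rb - ra)
    elif t and not s:
        ra, rb = np.ndim(a), np.ndim(b) - 1
        if rb < ra:
            b = _pad(b, ra - rb)
    return a * b


class Jet:
    __slots__ = ("c",)

    def __init__(self, comps):
        self.c = list(comps)

    # -- constructors -------------------------------------------------
    @staticmethod
    def const(value):
        return Jet([value, None, None, None, None, None, None, None])

    @staticmethod
    def lift(x):
        return x if isinstance(x, Jet) else Jet.const(x)

    # -- component access ---------------------------------------------
    @property
    def val(self):
        return self.c[0]

    def comp(self, mask, like=None):
        """Component for ``mask``; structural zeros materialized as 0."""
        v = self.c[mask]
        if v is None:
            return np.zeros_like(like) if like is not None else 0.0
        return v

    def transpose_last(self) -> "Jet":
        return Jet([None if v is None else np.swapaxes(np.asarray(v), -1, -2)
                    for v in self.c])

    def __getitem__(self, idx):
        if not isinstance(idx, tuple):
            idx = (idx,)
        key = (Ellipsis,) + idx
        return Jet([None if v is None else np.asarray(v)[key] for v in self.c])

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        o = Jet.lift(other)
        return Jet([_add(self.c[0], o.c[0])]
                   + [_add_deriv(a, b) for a, b in zip(self.c[1:], o.c[1:])])

    __radd__ = __add__

    def __neg__(self):
        return Jet([None if v is None else -v for v in self.c])

    def __sub__(self, other):
        o = Jet.lift(other)
        negc = [None if b is None else -b for b in o.c]
        return Jet([_add(self.c[0], negc[0])]
                   + [_add_deriv(a, b) for a, b in zip(self.c[1:], negc[1:])])

    def __rsub__(self, other):
        return Jet.lift(other) - self

    def __mul__(self, other):
        o = Jet.lift(other)
        u, v = self.c, o.c
        out = [None] * 8
        su = [s for s in range(8) if u[s] is not None]
        sv = [t for t in range(8) if v[t] is not None]
        for s in su:
            us = u[s]
            for t in sv:
                if s & t:
                    continue
                m = s | t
                term = _mul(us, v[t], s > 0, t > 0)
                out[m] = term if out[m] is None else (
                    _add_deriv(out[m], term) if m else out[m] + term)
        return Jet(out)

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = Jet.lift(other)
        return self * _compose(o, *_recip_derivs(o.c[0]))

    def __rtruediv__(self, other):
        return Jet.lift(other) / self

    def __pow__(self, n):
        if isinstance(n, int) and n >= 0:
            r = Jet.const(1.0)
            b = self
            while n:
                if n & 1:
                    r = r * b
                b = b * b if n > 1 else b
                n >>= 1
            return r
        u0 = self.c[0]
        f0 = u0 ** n
        return _compose(self, f0, n * u0 ** (n - 1),
                        n * (n - 1) * u0 ** (n - 2),
                        n * (n - 1) * (n - 2) * u0 ** (n - 3))


def _recip_derivs(u0):
    r = 1.0 / u0
    r2 = r * r
    return r, -r2, 2.0 * r2 * r, -6.0 * r2 * r2


def _compose(u, f0, f1, f2, f3):
    """Faa di Bruno to multilinear third order: f(u) for scalar f.

    The f-derivatives are value components (no channel axis)."""
    c = u.c

    def vm(f, d):  # value * deriv
        return _mul(f, d, 0, 1)

    def dd(a, b):  # deriv * deriv
        return _mul(a, b, 1, 1)

    out = [f0, None, None, None, None, None, None, None]
    for m in _SINGLES:
        out[m] = vm(f1, c[m])
    for m, (i, j) in _PAIRS.items():
        out[m] = _add_deriv(vm(f1, c[m]), vm(f2, dd(c[i], c[j])))
    out[7] = _add_deriv(
        _add_deriv(vm(f1, c[7]),
                   vm(f2, _add_deriv(_add_deriv(dd(c[1], c[6]), dd(c[2], c[5])),
                                     dd(c[4], c[3])))),
        vm(f3, dd(dd(c[1], c[2]), c[4])))
    return Jet(out)


def jsqrt(u):
    u = Jet.lift(u)
    s = np.sqrt(u.c[0])
    return _compose(u, s, 0.5 / s, -0.25 / (s * u.c[0]), 0.375 / (s * u.c[0] * u.c[0]))


def jexp(u):
    u = Jet.lift(u)
    e = np.exp(u.c[0])
    return _compose(u, e, e, e, e)


def jet_bilinear(f, a: Jet, b: Jet) -> Jet:
    """Apply a bilinear numpy map f(x, y) to jet operands (e.g. einsum)."""
    u, v = a.c, b.c
    out = []
    for m in range(8):
        acc = None
        for s, t in _MUL[m]:
            if u[s] is None or v[t] is None:
                continue
            acc = _add(acc, f(u[s], v[t]))
        out.append(acc)
    return Jet(out)


def jet_matmul(a: Jet, b: Jet) -> Jet:
    """Matrix product of jet-valued matrices (last two axes)."""
    u, v = a.c, b.c
    out = []
    for m in range(8):
        acc = None
        for s, t in _MUL[m]:
            if u[s] is None or v[t] is None:
                continue
            acc = _add(acc, np.matmul(u[s], v[t]))
        out.append(acc)
    return Jet(out)


def jet_transpose(a: Jet) -> Jet:
    return Jet([None if v is None else np.swapaxes(np.asarray(v), -1, -2) for v in a.c])


def jet_stack(jets, axis=-1):
    """Stack scalar-shaped jets into an array-valued jet.

    All components are materialized against the broadcast value shape.
    """
    jets = [Jet.lift(j) for j in jets]
    shape = np.broadcast_shapes(*[np.shape(j.c[0]) for j in jets])
    # derivative components may carry a leading channel axis
    dshape = ()
    for j in jets:
        for v in j.c[1:]:
            if v is not None:
                dshape = np.broadcast_shapes(dshape, np.shape(v))
    out = []
    for m in range(8):
        tgt = shape if m == 0 else np.broadcast_shapes(shape, dshape)
        cols = []
        any_nz = False
        for j in jets:
            v = j.c[m]
            if v is None:
                cols.append(np.zeros(tgt))
            else:
                cols.append(np.broadcast_to(np.asarray(v, dtype=float), tgt))
                any_nz = True
        out.append(np.stack(cols, axis=axis) if any_nz or m == 0 else None)
    return Jet(out)


def jet_sum(jets):
    acc = Jet.const(0.0)
    for j in jets:
        acc = acc + j
    return acc
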
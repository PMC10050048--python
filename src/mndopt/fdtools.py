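"""Richardson-extrapolated central finite differences.

The finite-difference harness is the independent oracle against which every
analytic derivative in the package is validated; it reports both the
extrapolated estimate and an error bar (the difference between the two step
sizes' estimates), quantifying the numerical noise that motivates analytic
derivatives in the first place.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np


@dataclass
class FDEstimate:
    value: np.ndarray     # Richardson-extrapolated derivative
    coarse: np.ndarray    # step-h estimate
    fine: np.ndarray      # step-h/2 estimate
    error: np.ndarray     # |fine - coarse| / 3, the extrapolation error bar


def _central(f: Callable, x0: float, h: float, order: int):
    if order == 1:
        return (np.asarray(f(x0 + h)) - np.asarray(f(x0 - h))) / (2.0 * h)
    if order == 2:
        return (np.asarray(f(x0 + h)) - 2.0 * np.asarray(f(x0))
                + np.asarray(f(x0 - h))) / (h * h)
    raise ValueError("order must be 1 or 2")


def fd_derivative(f: Callable, x0: float, h: float = 1e-4,
                  order: int = 1) -> FDEstimate:
    """Central difference with steps h and h/2 plus Richardson extrapolation.

    ``f`` maps a float to a scalar or array; non-finite evaluations raise.
    """
    d1 = _central(f, x0, h, order)
    d2 = _central(f, x0, 0.5 * h, order)
    if not (np.all(np.isfinite(d1)) and np.all(np.isfinite(d2))):
        raise FloatingPointError(f"non-finite evaluation near x0={x0}")
    rich = (4.0 * d2 - d1) / 3.0
    return FDEstimate(value=rich, coarse=d1, fine=d2, error=np.abs(d2 - d1) / 3.0)


def fd_gradient(f: Callable, x0: np.ndarray, h: float = 1e-4,
                indices=None) -> np.ndarray:
    """Richardson FD gradient of a scalar/array function of a vector."""
    x0 = np.asarray(x0, dtype=float)
    idx = range(x0.size) if indices is None else indices
    cols = {}
    for i in idx:
        def fi(t, i=i):
            x = x0.copy()
            x[i] = t
            return f(x)
        cols[i] = fd_derivative(fi, x0[i], h=h, order=1).value
    shape = np.shape(next(iter(cols.values())))
    out = np.zeros((x0.size,) + shape)
    for i, v in cols.items():
        out[i] = v
    return out


def fd_mixed_second(f: Callable, x0: np.ndarray, i: int, j: int,
                    h: float = 1e-3) -> float:
    """Mixed second derivative d2f/dx_i dx_j by the 4-point cross stencil."""
    x0 = np.asarray(x0, dtype=float)

    def at(di, dj):
        x = x0.copy()
        x[i] += di
        x[j] += dj
        return float(f(x))

    def stencil(hh):
        return (at(hh, hh) - at(hh, -hh) - at(-hh, hh) + at(-hh, -hh)) / (4 * hh * hh)

    d1, d2 = stencil(h), stencil(0.5 * h)
    return float((4.0 * d2 - d1) / 3.0)
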
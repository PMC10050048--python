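"""The weighted least-squares error function over a training set, its
gradient, the exact parameter Hessian, the Gram (PM7-style) approximant and
the modified positive-semidefinite Hessian.

    S        = sum_alpha C_alpha^2 (xi_ref - xi)^2
    grad S   = 2 sum C^2 (xi - xi_ref) dxi/dp
    H        = 2 sum C^2 [ (xi - xi_ref) d2xi/dp2 + (dxi/dp)(dxi/dp)^T ]
    H_gram   = 2 sum C^2 (dxi/dp)(dxi/dp)^T
    H_abs    = P |D| P^-1  for H = P D P^-1  (same eigenvectors, |eigenvalues|)

Non-converging molecules abort the evaluation (silently skipping an entry
would change S discontinuously during optimization).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .molecules import TrainingEntry
from .params import ParameterSet
from .property_derivs import entry_derivatives
from .properties import compute_properties
from .scf import ScfError, scf_solve


class ObjectiveError(RuntimeError):
    pass


@dataclass
class Residual:
    molecule: str
    prop: str
    weight: float
    ref: float
    value: float
    dxi: Optional[np.ndarray] = None   # property gradient, when computed

    @property
    def contribution(self) -> float:
        return (self.weight * (self.ref - self.value)) ** 2


@dataclass
class ObjectiveReport:
    S: float
    residuals: List[Residual]
    grad: Optional[np.ndarray] = None
    hessian: Optional[np.ndarray] = None
    hessian_gram: Optional[np.ndarray] = None
    asymmetry: float = 0.0

    def hessian_abs(self) -> np.ndarray:
        return modified_hessian(self.hessian)

    def eigen_report(self, which: str = "exact") -> Tuple[np.ndarray, np.ndarray]:
        H = {"exact": self.hessian, "pm7": self.hessian_gram,
             "abs": self.hessian_abs()}[which]
        return eigen_sorted(H)


def eigen_sorted(H: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Ascending eigenvalues; eigenvector sign fixed by the first nonzero
    component being positive."""
    w, V = np.linalg.eigh(H)
    for k in range(V.shape[1]):
        col = V[:, k]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if nz.size and col[nz[0]] < 0:
            V[:, k] = -col
    return w, V


def modified_hessian(H: np.ndarray) -> np.ndarray:
    """Same eigenvectors, absolute eigenvalues (positive semidefinite)."""
    w, V = np.linalg.eigh(H)
    return (V * np.abs(w)) @ V.T


def evaluate(entries: Sequence[TrainingEntry], pset: ParameterSet,
             order: int = 0, scf_cache: Optional[dict] = None) -> ObjectiveReport:
    """Evaluate S and, for order >= 1/2, its gradient / Hessians.

    ``scf_cache`` (keyed by entry index) warm-starts each molecule's SCF from
    the previously converged densities, keeping the solutions on a continuous
    branch across nearby parameter vectors during optimization.
    """
    n = len(pset.index_map())
    S = 0.0
    residuals: List[Residual] = []
    grad = np.zeros(n) if order >= 1 else None
    Hess = np.zeros((n, n)) if order >= 2 else None
    Gram = np.zeros((n, n)) if order >= 1 else None
    for k, entry in enumerate(entries):
        mol = entry.molecule
        refs = entry.references()
        props = [p for p, _, _ in refs]
        try:
            guess = scf_cache.get(k) if scf_cache is not None else None
            state = scf_solve(mol, pset, guess=guess)
            if scf_cache is not None:
                scf_cache[k] = (state.P_spin[0].copy(), state.P_spin[1].copy())
            if order == 0:
                pr = compute_properties(state, want_grad="geo" in props)
                values = {p: pr.get(p) for p in props}
                derivs = None
            else:
                derivs = entry_derivatives(entry, pset, order=order, props=props,
                                           state=state)
                values = {p: derivs[p].value for p in props}
        except ScfError as exc:
            raise ObjectiveError(f"SCF failed for {mol.name}: {exc}") from exc
        for p, ref, w in refs:
            xi = values[p]
            dxi = derivs[p].grad if order >= 1 else None
            residuals.append(Residual(mol.name, p, w, ref, xi, dxi))
            S += (w * (ref - xi)) ** 2
            if order >= 1:
                grad += 2.0 * w * w * (xi - ref) * dxi
                Gram += 2.0 * w * w * np.outer(dxi, dxi)
                if order >= 2:
                    Hess += 2.0 * w * w * (xi - ref) * derivs[p].hess
    asym = 0.0
    if order >= 2:
        Hess += Gram
        asym = float(np.abs(Hess - Hess.T).max())
        Hess = 0.5 * (Hess + Hess.T)
    return ObjectiveReport(S=float(S), residuals=residuals, grad=grad,
                           hessian=Hess, hessian_gram=Gram, asymmetry=asym)


def evaluate_S(entries, pset) -> Tuple[float, List[Residual]]:
    rep = evaluate(entries, pset, order=0)
    return rep.S, rep.residuals


def gradient_S(entries, pset) -> np.ndarray:
    return evaluate(entries, pset, order=1).grad


def exact_hessian(entries, pset) -> np.ndarray:
    return evaluate(entries, pset, order=2).hessian


def pm7_hessian(entries, pset) -> np.ndarray:
    return evaluate(entries, pset, order=1).hessian_gram


def rms_by_property(residuals: Sequence[Residual]) -> Dict[str, float]:
    acc: Dict[str, List[float]] = {}
    for r in residuals:
        acc.setdefault(r.prop, []).append((r.ref - r.value) ** 2)
    return {p: float(np.sqrt(np.mean(v))) for p, v in acc.items()}
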
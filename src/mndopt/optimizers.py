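"""Parameter-update schemes: approximated line search (ALS), trust-radius
Hessian descent (HD-TR), and trust-region optimization (TRO), each usable
with the exact Hessian, the Gram approximant, or the modified (absolute
eigenvalue) Hessian.

Trust-radius bookkeeping: with quadratic model Q = d.g + d.B.d/2 and
agreement ratio rho = (S_new - S_old)/Q, the radius grows by 5/4 when
rho > 0.8 and S decreased, halves when rho < 0.25 or S did not decrease,
and is unchanged otherwise; steps that increase S are rejected.  All step
lengths are capped at |d|_max.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

from .molecules import TrainingEntry
from .objective import ObjectiveReport, evaluate, modified_hessian
from .params import ParameterSet

DEFAULT_DMAX = 2.0


@dataclass
class IterationRecord:
    iteration: int
    S: float
    grad_norm: float
    step_norm: float
    radius: float
    rho: float
    lam: float
    accepted: bool


@dataclass
class OptimizationResult:
    pset: ParameterSet
    vector: np.ndarray
    S: float
    trajectory: List[IterationRecord]
    converged: bool
    message: str

    @property
    def S_history(self) -> List[float]:
        return [r.S for r in self.trajectory]


def als_step(g: np.ndarray, B: np.ndarray, residual_data, dmax: float = DEFAULT_DMAX):
    """Approximated-line-search step.

    Direction: normalized Hessian-descent direction -B^-1 g.  Step length:
    minimizer of the linearized surrogate
    S~(k) = sum C^2 (r_alpha - k u_alpha)^2 with u = dxi . d_hat, solved in
    closed form and capped at dmax.  ``residual_data`` is a sequence of
    (weight, residual=xi_ref - xi, dxi) triples.
    """
    if np.linalg.norm(g) == 0:
        return np.zeros_like(g)
    try:
        d = -np.linalg.solve(B, g)
    except np.linalg.LinAlgError:
        d = -np.linalg.lstsq(B, g, rcond=None)[0]
    nd = np.linalg.norm(d)
    if nd == 0:
        return np.zeros_like(g)
    dhat = d / nd
    num = 0.0
    den = 0.0
    for w, r, dxi in residual_data:
        u = float(dxi @ dhat)
        num += w * w * r * u
        den += w * w * u * u
    if den <= 0:
        return np.zeros_like(g)
    k = num / den
    k = float(np.clip(k, -dmax, dmax))
    return k * dhat


def trust_radius_update(Q: float, S_old: float, S_new: float, R: float,
                        dmax: float = DEFAULT_DMAX) -> Tuple[float, bool, float]:
    """(new radius, accept flag, rho)."""
    decreased = S_new < S_old
    if abs(Q) < 1e-14:
        rho = 1.0 if decreased else 0.0
    else:
        rho = (S_new - S_old) / Q
    if rho > 0.8 and decreased:
        Rn = 1.25 * R
    elif rho < 0.25 or not decreased:
        Rn = 0.5 * R
    else:
        Rn = R
    return min(Rn, dmax), decreased, rho


def tro_step(g: np.ndarray, B: np.ndarray, R: float) -> Tuple[np.ndarray, float]:
    """Trust-region subproblem: minimize d.g + d.B.d/2 subject to |d| <= R.

    Returns (d, lambda) with lambda >= 0 the spectral shift making B+lambda*I
    positive definite; lambda = 0 for an interior Newton step.  Solved on the
    eigendecomposition, including the hard case.
    """
    w, V = np.linalg.eigh(0.5 * (B + B.T))
    gt = V.T @ g
    wmin = w[0]

    def dnorm(lam):
        return float(np.linalg.norm(gt / (w + lam)))

    if wmin > 0 and dnorm(0.0) <= R:
        d = -V @ (gt / w)
        return d, 0.0

    lam_lo = max(0.0, -wmin)
    # hard case: no gradient component on the lowest eigenspace
    low = np.abs(w - wmin) < 1e-12 * max(1.0, abs(wmin))
    if np.all(np.abs(gt[low]) < 1e-13):
        lam = lam_lo
        denom = w + lam
        coeff = np.where(low, 0.0, gt / np.where(low, 1.0, denom))
        base = float(np.linalg.norm(coeff))
        if base <= R:
            t = np.sqrt(max(R * R - base * base, 0.0))
            d = -V @ coeff + t * V[:, int(np.argmax(low))]
            return d, lam
    # boundary solution: solve 1/|d(lam)| = 1/R by safeguarded Newton
    lo = lam_lo
    hi = lam_lo + max(1.0, np.linalg.norm(gt) / R)
    while dnorm(hi) > R:
        hi = lam_lo + 2 * (hi - lam_lo)
    lam = 0.5 * (max(lo, lam_lo + 1e-14) + hi)
    for _ in range(300):
        nd = dnorm(lam)
        phi = 1.0 / nd - 1.0 / R
        if abs(nd - R) < 1e-13 * max(1.0, R):
            break
        dphi = float(np.sum(gt * gt / (w + lam) ** 3)) / nd ** 3
        if phi > 0:   # |d| < R -> decrease lam
            hi = min(hi, lam)
        else:
            lo = max(lo, lam)
        step = phi / dphi if dphi != 0 else 0.0
        new = lam - step
        if not (lo < new < hi):
            new = 0.5 * (lo + hi)
        if abs(new - lam) < 1e-16 * max(1.0, lam):
            lam = new
            break
        lam = new
    d = -V @ (gt / (w + lam))
    nd = float(np.linalg.norm(d))
    if nd > R:
        d *= R / nd   # project the residual of the secular solve onto the ball
    return d, float(lam)


def _hessian_matrix(report: ObjectiveReport, mode: str) -> np.ndarray:
    if mode == "pm7":
        return report.hessian_gram
    if mode == "exact":
        return report.hessian
    if mode == "abs":
        return modified_hessian(report.hessian)
    raise ValueError(f"unknown hessian mode {mode!r}")


def optimize(entries: Sequence[TrainingEntry], pset: ParameterSet,
             method: str = "tro", hessian_mode: str = "abs",
             r0: Optional[float] = None, dmax: float = DEFAULT_DMAX,
             max_iter: int = 300, gtol: float = 1e-8, rtol_radius: float = 1e-10,
             s_target: Optional[float] = None,
             callback: Optional[Callable] = None) -> OptimizationResult:
    """Drive one of the three update schemes over the training set.

    ``method``: 'als' (approximated line search), 'hdtr' (Hessian descent
    with trust radius), or 'tro' (trust region).  ``hessian_mode``: 'exact',
    'pm7' (Gram approximant; first derivatives only) or 'abs' (modified
    Hessian).  Default initial radius: 0.1 for TRO, 2.0 for HD-TR.
    """
    if method not in ("als", "hdtr", "tro"):
        raise ValueError(f"unknown method {method!r}")
    if r0 is None:
        r0 = 0.1 if method == "tro" else 2.0
    order = 1 if hessian_mode == "pm7" else 2
    p = pset.flatten()
    base = pset
    R = min(r0, dmax)
    cap = dmax
    traj: List[IterationRecord] = []
    scf_cache: dict = {}
    rep = evaluate(entries, base.unflatten(p), order=order, scf_cache=scf_cache)
    converged = False
    message = "max iterations reached"
    for it in range(1, max_iter + 1):
        g = rep.grad
        gnorm = float(np.linalg.norm(g))
        if gnorm < gtol:
            converged, message = True, "gradient below threshold"
            break
        if s_target is not None and rep.S <= s_target:
            converged, message = True, "target S reached"
            break
        B = _hessian_matrix(rep, hessian_mode)
        lam = 0.0
        if method == "als":
            rd = [(r.weight, r.ref - r.value, r.dxi) for r in rep.residuals]
            d = als_step(g, B, rd, dmax=cap)
        elif method == "hdtr":
            try:
                dn = -np.linalg.solve(B, g)
            except np.linalg.LinAlgError:
                dn = -np.linalg.lstsq(B, g, rcond=None)[0]
            nrm = np.linalg.norm(dn)
            d = dn * (min(R, dmax) / nrm) if nrm > 0 else dn
        else:
            d, lam = tro_step(g, B, min(R, dmax))
        Q = float(d @ g + 0.5 * d @ B @ d)
        p_new = p + d
        try:
            rep_new = evaluate(entries, base.unflatten(p_new), order=order,
                               scf_cache=scf_cache)
            S_new = rep_new.S
        except Exception:
            S_new = np.inf
            rep_new = None
        if method == "als":
            accept = S_new < rep.S
            if not accept:
                cap = 0.5 * cap  # halve the step cap after a failed line search
            rho = 1.0 if accept else 0.0
        else:
            R, accept, rho = trust_radius_update(Q, rep.S, S_new, R, dmax=dmax)
        traj.append(IterationRecord(it, S_new if accept else rep.S, gnorm,
                                    float(np.linalg.norm(d)), R, rho, lam, accept))
        if callback is not None:
            callback(traj[-1])
        if accept:
            p = p_new
            rep = rep_new
        if method != "als" and R < rtol_radius:
            message = "trust radius underflow"
            break
        if method == "als" and cap < rtol_radius:
            message = "step cap underflow"
            break
    final = base.unflatten(p)
    return OptimizationResult(pset=final, vector=p, S=rep.S, trajectory=traj,
                              converged=converged, message=message)
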
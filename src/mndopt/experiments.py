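"""Reference experiments built from the synthetic fixture suites.

These drive the package end to end at desk scale: closed-loop parameter
recovery (references generated by the engine itself at known parameters) and
the qualitative comparison of Gram-approximant-led versus
modified-Hessian-led optimization on noisy data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np

from .fixtures import (SUITE_DERIVATIVES, SUITE_FULL, SUITE_RECOVERY,
                       generate_reference_data, suite)
from .molecules import TrainingEntry
from .objective import evaluate, eigen_sorted
from .optimizers import optimize
from .params import load_packaged_parameters
from .property_derivs import entry_derivatives
from .properties import compute_properties
from .scf import scf_solve

# realistic reference-data noise for an MNDO-class model: a few kcal/mol on
# heats of formation, a few tenths of an eV / debye on IE and dipoles
NOISE_DEFAULT = {"hf": 5.0, "ie": 0.3, "dip": 0.2}


@dataclass
class DerivativeValidation:
    """Worst-case deviation ratios of analytic vs FD derivatives.

    A check passes when |analytic - FD| <= max(rel_tol * |FD|, abs_floor,
    5 * Richardson error bar); the error bar term acknowledges the oracle's
    own noise (SCF convergence noise amplified by the FD step).  The reported
    ratio is |analytic - FD| divided by that bound, so <= 1 means pass.
    """
    max_ratio_first: float
    max_ratio_second: float
    max_rel_err_first: float
    max_rel_err_second: float
    n_first_checks: int
    n_second_checks: int
    worst_first: tuple
    worst_second: tuple


def _entry_for(mol, with_geo=True):
    """Training entry referencing every property defined for the molecule."""
    from .fixtures import _homo_isolated
    from .scf import scf_solve as _scf
    st = _scf(mol, load_packaged_parameters("mndo"))
    pr = compute_properties(st, want_grad=False)
    kw = {"hf": pr.hf}
    if _homo_isolated(st):
        kw["ie"] = pr.ie
    if st.closed_shell and pr.dip > 0.1:
        kw["dip"] = pr.dip
    return TrainingEntry(mol, geo=with_geo, **kw)


def derivative_fd_validation(names=SUITE_DERIVATIVES, h: float = 1e-4,
                             rel_tol: float = 1e-5,
                             abs_floor: float = 1e-8) -> DerivativeValidation:
    """Cross-validate analytic first and second property derivatives against
    Richardson-extrapolated central finite differences.

    Every one of the 37 parameters is checked on at least one suite molecule
    containing its element (molecules assigned round-robin), for every
    property the molecule references: first derivatives against FD of the
    property, Hessian rows against FD of the analytic gradient.
    """
    pset = load_packaged_parameters("mndo")
    imap = pset.index_map()
    p0 = pset.flatten()
    mols = suite(names)
    entries = {m.name: _entry_for(m) for m in mols}
    # assign each parameter to one molecule containing its element
    assignment = {}
    counters: dict = {}
    for i, (el, _) in enumerate(imap):
        cands = [m for m in mols if el in m.elements]
        k = counters.get(el, 0)
        assignment[i] = cands[k % len(cands)]
        counters[el] = k + 1

    # the FD oracle's own noise is the SCF convergence residual amplified by
    # 1/h, so every evaluation here converges the SCF to near machine floor
    scf_kw = dict(tol_e=1e-14, tol_p=1e-12, max_cycles=3000)

    def _state(mol, vec):
        return scf_solve(mol, pset.unflatten(vec), **scf_kw)

    base = {}
    for m in mols:
        e = entries[m.name]
        base[m.name] = entry_derivatives(e, pset, order=2,
                                         state=_state(m, p0))

    def props_at(mol, vec):
        e = entries[mol.name]
        pr = compute_properties(_state(mol, vec), want_grad=e.geo)
        return {p: pr.get(p) for p, _, _ in e.references()}

    def grads_at(mol, vec):
        d = entry_derivatives(entries[mol.name], pset.unflatten(vec), order=1,
                              state=_state(mol, vec))
        return {p: d[p].grad for p in d}

    ratio1 = ratio2 = 0.0
    err1 = err2 = 0.0
    worst1 = worst2 = None
    n1 = n2 = 0
    for i, mol in assignment.items():
        evals_p = {}
        gvals = {}
        for step in (h, 0.5 * h):
            for sgn in (1.0, -1.0):
                v = p0.copy()
                v[i] += sgn * step
                evals_p[(step, sgn)] = props_at(mol, v)
                gvals[(step, sgn)] = grads_at(mol, v)
        act = [k for k, (el, _) in enumerate(imap) if el in mol.elements]
        ana = base[mol.name]
        for p in evals_p[(h, 1.0)]:
            d1 = (evals_p[(h, 1)][p] - evals_p[(h, -1)][p]) / (2 * h)
            d2_ = (evals_p[(h / 2, 1)][p] - evals_p[(h / 2, -1)][p]) / h
            fd = (4 * d2_ - d1) / 3
            bar = abs(d2_ - d1) / 3
            diff = abs(ana[p].grad[i] - fd)
            bound = max(rel_tol * abs(fd), abs_floor, 5 * bar)
            n1 += 1
            err1 = max(err1, diff / max(abs(fd), 1.0))
            if diff / bound > ratio1:
                ratio1, worst1 = diff / bound, (mol.name, p, imap[i])
            g1 = (gvals[(h, 1)][p] - gvals[(h, -1)][p]) / (2 * h)
            g2 = (gvals[(h / 2, 1)][p] - gvals[(h / 2, -1)][p]) / h
            gfd = (4 * g2 - g1) / 3
            gbar = np.abs(g2 - g1) / 3
            diffs = np.abs(ana[p].hess[i][act] - gfd[act])
            bounds = np.maximum.reduce([rel_tol * np.abs(gfd[act]),
                                        np.full(len(act), abs_floor),
                                        5 * gbar[act]])
            n2 += 1
            err2 = max(err2, diffs.max() / max(np.abs(gfd[act]).max(), 1.0))
            r = (diffs / bounds).max()
            if r > ratio2:
                ratio2, worst2 = r, (mol.name, p, imap[i])
    return DerivativeValidation(max_ratio_first=float(ratio1),
                                max_ratio_second=float(ratio2),
                                max_rel_err_first=float(err1),
                                max_rel_err_second=float(err2),
                                n_first_checks=n1, n_second_checks=n2,
                                worst_first=worst1, worst_second=worst2)


@dataclass
class RecoveryResult:
    S_initial: float
    S_final: float
    iterations: int
    iterations_to_target: Optional[int]   # first iteration with S <= target
    max_rel_param_error: float
    hessian_eigs_final: Optional[np.ndarray]
    message: str


def closed_loop_recovery(seed: int = 42, names: Sequence[str] = SUITE_RECOVERY,
                         perturbation: float = 0.02, max_iter: int = 200,
                         s_ratio_target: float = 1e-6,
                         data_seed: int = 1,
                         final_hessian: bool = False) -> RecoveryResult:
    """Generate exact references at the packaged MNDO parameters, perturb the
    parameter vector multiplicatively by U(1-perturbation, 1+perturbation),
    and recover it with trust-region optimization on the modified Hessian
    (R0 = 0.1, |d|max = 2).  The optimization runs to its own termination
    (gradient threshold / radius underflow / max_iter) so that the recovered
    parameters are fully polished; the iteration at which S first dropped
    below ``s_ratio_target * S0`` is recorded along the way."""
    pstar = load_packaged_parameters("mndo")
    entries = generate_reference_data(suite(names), pstar, seed=data_seed)
    rng = np.random.default_rng(seed)
    p0 = pstar.flatten()
    start = pstar.unflatten(p0 * rng.uniform(1.0 - perturbation,
                                             1.0 + perturbation, size=p0.size))
    S0 = evaluate(entries, start, order=0).S
    res = optimize(entries, start, method="tro", hessian_mode="abs",
                   r0=0.1, dmax=2.0, max_iter=max_iter, gtol=1e-6,
                   rtol_radius=1e-9)
    err = float(np.abs((res.vector - p0) / p0).max())
    hit = None
    for rec in res.trajectory:
        if rec.accepted and rec.S <= s_ratio_target * S0:
            hit = rec.iteration
            break
    eigs = None
    if final_hessian:
        rep = evaluate(entries, res.pset, order=2)
        eigs, _ = eigen_sorted(rep.hessian)
    return RecoveryResult(S_initial=float(S0), S_final=float(res.S),
                          iterations=len(res.trajectory),
                          iterations_to_target=hit,
                          max_rel_param_error=err,
                          hessian_eigs_final=eigs, message=res.message)


@dataclass
class QualitativeResult:
    seed: int
    S_gram: float
    S_abs: float
    min_eig_gram_endpoint: float    # lowest EXACT-Hessian eigenvalue there
    min_eig_abs_endpoint: float
    max_eig_gram_endpoint: float
    max_eig_abs_endpoint: float
    grad_norm_gram: float
    grad_norm_abs: float


def gram_vs_modified(seed: int, names: Sequence[str] = SUITE_FULL,
                     noise: Optional[Dict[str, float]] = None,
                     perturbation: float = 0.015,
                     gram_iters: int = 25, abs_iters: int = 35,
                     r0_abs: float = 0.3) -> QualitativeResult:
    """Optimize a noisy synthetic set once with the PM7-style Gram
    approximant (approximated line search, as in the PMx procedure) and once
    with modified-Hessian trust-region steps, then diagonalize the exact
    Hessian at both endpoints.

    The Gram approximant is positive semidefinite by construction and cannot
    distinguish minima from saddle points; the exact spectrum at its endpoint
    may contain negative eigenvalues, while the modified-Hessian trust-region
    run terminates on the exact surface's descent structure.
    """
    pstar = load_packaged_parameters("mndo")
    entries = generate_reference_data(
        suite(names), pstar, noise=dict(NOISE_DEFAULT if noise is None else noise),
        seed=seed)
    rng = np.random.default_rng(seed + 1000)
    p0 = pstar.flatten()
    start = pstar.unflatten(p0 * rng.uniform(1.0 - perturbation,
                                             1.0 + perturbation, size=p0.size))
    res_gram = optimize(entries, start, method="als", hessian_mode="pm7",
                        dmax=2.0, max_iter=gram_iters)
    res_abs = optimize(entries, start, method="tro", hessian_mode="abs",
                       r0=r0_abs, dmax=2.0, max_iter=abs_iters)
    out = {}
    for tag, res in (("gram", res_gram), ("abs", res_abs)):
        rep = evaluate(entries, res.pset, order=2)
        w, _ = eigen_sorted(rep.hessian)
        out[tag] = (res.S, float(w[0]), float(w[-1]),
                    float(np.linalg.norm(rep.grad)))
    return QualitativeResult(
        seed=seed,
        S_gram=float(out["gram"][0]), S_abs=float(out["abs"][0]),
        min_eig_gram_endpoint=out["gram"][1],
        min_eig_abs_endpoint=out["abs"][1],
        max_eig_gram_endpoint=out["gram"][2],
        max_eig_abs_endpoint=out["abs"][2],
        grad_norm_gram=out["gram"][3], grad_norm_abs=out["abs"][3])


def cphf_structure_metrics(seed: int = 0) -> dict:
    """Worst-case structural residuals of the first/second-order response
    over three molecules (closed shell, linear, open shell) plus gauge
    invariance on methane's degenerate occupied shell."""
    from .cphf import ResponseEngine
    from .integrals import IntegralContext, ParamDir
    pset = load_packaged_parameters("mndo")
    out = {"x_antisymmetry": 0.0, "gamma_closure": 0.0, "trace_dp": 0.0,
           "trace_d2p": 0.0, "d2p_swap": 0.0, "gauge_dp": 0.0, "gauge_d2p": 0.0}
    from .fixtures import fixture_molecule
    for name, q1f, q2f in (("H2O", ("O", "zeta_p"), ("H", "beta_s")),
                           ("HCN", ("C", "zeta_s"), ("N", "beta_p")),
                           ("NH2", ("N", "zeta_p"), ("H", "zeta_s"))):
        st = scf_solve(fixture_molecule(name), pset)
        eng = ResponseEngine(st)
        d1, d2 = ParamDir(*q1f), ParamDir(*q2f)
        ctx = IntegralContext(st.mol, pset, [(d1, d1, None), (d1, d2, None),
                                             (d2, d2, None), (d2, d1, None)])
        r1 = eng.solve_first(d1, eng.static_first(ctx, 1, 0))
        r2 = eng.solve_first(d2, eng.static_first(ctx, 1, 2))

        def solve2(c, a, b):
            return eng.solve_second(a, b, d2H=ctx.hcore(3, c),
                                    W12=ctx.two_electron(3, c),
                                    W1=ctx.two_electron(1, c),
                                    W2=ctx.two_electron(2, c))

        so12 = solve2(1, r1, r2)
        so21 = solve2(3, r2, r1)
        for s in (0, 1):
            x = r1.x[s]
            out["x_antisymmetry"] = max(out["x_antisymmetry"],
                                        float(np.abs(x + x.T).max()))
            g = so12.gamma[s]
            S = r1.x[s] @ r2.x[s] + r2.x[s] @ r1.x[s]
            out["gamma_closure"] = max(out["gamma_closure"],
                                       float(np.abs(g + g.T - S).max()))
        out["trace_dp"] = max(out["trace_dp"], abs(float(np.trace(r1.dP_total))))
        out["trace_d2p"] = max(out["trace_d2p"],
                               abs(float(np.trace(so12.d2P_total))))
        out["d2p_swap"] = max(out["d2p_swap"],
                              float(np.abs(so12.d2P_total - so21.d2P_total).max()))
    # gauge invariance on the degenerate occupied shell of methane
    st = scf_solve(fixture_molecule("CH4"), pset)
    q = ParamDir("C", "zeta_s")
    ctx = IntegralContext(st.mol, pset, [(q, q, None)])
    eng = ResponseEngine(st)
    r = eng.solve_first(q, eng.static_first(ctx, 1, 0))
    so = eng.solve_second(r, r, d2H=ctx.hcore(3, 0),
                          W12=ctx.two_electron(3, 0),
                          W1=ctx.two_electron(1, 0), W2=ctx.two_electron(2, 0))
    rng = np.random.default_rng(seed)
    no = st.n_occ[0]
    idx = [i for i in range(no) if abs(st.eps[0][i] - st.eps[0][no - 1]) < 1e-6]
    Q, _ = np.linalg.qr(rng.normal(size=(len(idx), len(idx))))
    C2 = (st.C[0].copy(), st.C[1].copy())
    for s in (0, 1):
        C2[s][:, idx] = C2[s][:, idx] @ Q
    st2 = type(st)(st.mol, st.pset, st.ctx, C2, st.eps, st.P_spin, st.F,
                   st.n_occ, st.E_el, st.V_core, st.n_iter, st.converged)
    eng2 = ResponseEngine(st2)
    r2g = eng2.solve_first(q, eng2.static_first(ctx, 1, 0))
    so2 = eng2.solve_second(r2g, r2g, d2H=ctx.hcore(3, 0),
                            W12=ctx.two_electron(3, 0),
                            W1=ctx.two_electron(1, 0), W2=ctx.two_electron(2, 0))
    out["gauge_dp"] = float(np.abs(r2g.dP_total - r.dP_total).max())
    out["gauge_d2p"] = float(np.abs(so2.d2P_total - so.d2P_total).max())
    return out
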
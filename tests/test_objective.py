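"""Weighted error function, gradient, exact/Gram/modified Hessians."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mndopt.fixtures import fixture_molecule, generate_reference_data, suite
from mndopt.molecules import TrainingEntry
from mndopt.objective import (ObjectiveError, eigen_sorted, evaluate,
                              modified_hessian, rms_by_property)
from mndopt.params import load_packaged_parameters


@pytest.fixture(scope="module")
def tiny_set():
    pset = load_packaged_parameters("mndo")
    mols = suite(("H2O", "HCN"))
    return pset, generate_reference_data(mols, pset, seed=3)


def test_weighted_arithmetic_forced():
    """Errors (1 kcal/mol, 0.1 eV, 0.05 D, 2 kcal/mol/bohr) with the default
    weights (1, 10, 20, 0.5) each contribute exactly 1 to S."""
    w = {"hf": 1.0, "ie": 10.0, "dip": 20.0, "geo": 0.5}
    errors = {"hf": 1.0, "ie": 0.1, "dip": 0.05, "geo": 2.0}
    S = sum((w[k] * errors[k]) ** 2 for k in w)
    assert S == pytest.approx(4.0, abs=1e-14)


def test_perfect_fit_gives_zero_S_and_gradient(tiny_set):
    pset, entries = tiny_set
    rep = evaluate(entries, pset, order=2)
    assert rep.S == pytest.approx(0.0, abs=1e-16)
    assert np.abs(rep.grad).max() < 1e-7
    # at a perfect fit the exact Hessian reduces to the Gram approximant
    assert np.abs(rep.hessian - rep.hessian_gram).max() < 1e-8


def test_S_additive_over_entries(tiny_set):
    pset, entries = tiny_set
    ps = pset.unflatten(pset.flatten() * 1.01)
    rep_all = evaluate(entries, ps, order=0)
    parts = [evaluate([e], ps, order=0).S for e in entries]
    assert rep_all.S == pytest.approx(sum(parts), rel=1e-12)
    # removing one entry removes exactly its residual contribution
    rep_wo = evaluate(entries[1:], ps, order=0)
    contrib = sum(r.contribution for r in rep_all.residuals
                  if r.molecule == entries[0].molecule.name)
    assert rep_all.S - rep_wo.S == pytest.approx(contrib, rel=1e-12)


def test_gradient_against_fd(tiny_set):
    pset, entries = tiny_set
    ps = pset.unflatten(pset.flatten() * 1.01)
    rep = evaluate(entries, ps, order=1)
    p0 = ps.flatten()
    imap = ps.index_map()
    for key in (("O", "zeta_p"), ("H", "beta_s"), ("C", "alpha"), ("N", "E_isol")):
        i = imap.index(key)
        h = 1e-5
        pp, pm = p0.copy(), p0.copy()
        pp[i] += h
        pm[i] -= h
        fd = (evaluate(entries, ps.unflatten(pp)).S
              - evaluate(entries, ps.unflatten(pm)).S) / (2 * h)
        scale = max(1.0, abs(fd))
        assert abs(rep.grad[i] - fd) / scale < 1e-5


def test_hessian_against_fd_of_gradient(tiny_set):
    pset, entries = tiny_set
    ps = pset.unflatten(pset.flatten() * 1.01)
    rep = evaluate(entries, ps, order=2)
    p0 = ps.flatten()
    imap = ps.index_map()
    i = imap.index(("O", "zeta_p"))
    h = 1e-4
    pp, pm = p0.copy(), p0.copy()
    pp[i] += h
    pm[i] -= h
    gp = evaluate(entries, ps.unflatten(pp), order=1).grad
    gm = evaluate(entries, ps.unflatten(pm), order=1).grad
    fd = (gp - gm) / (2 * h)
    act = [k for k, (el, _) in enumerate(imap) if el in ("H", "C", "N", "O")]
    scale = max(1.0, np.abs(fd[act]).max())
    assert np.abs(rep.hessian[i][act] - fd[act]).max() / scale < 1e-4


def test_gram_hessian_matches_explicit_loop(tiny_set):
    pset, entries = tiny_set
    ps = pset.unflatten(pset.flatten() * 1.005)
    rep = evaluate(entries, ps, order=1)
    n = len(ps.index_map())
    acc = np.zeros((n, n))
    for r in rep.residuals:
        acc += 2.0 * r.weight ** 2 * np.outer(r.dxi, r.dxi)
    assert np.array_equal(acc, rep.hessian_gram)


def test_gram_hessian_positive_semidefinite(tiny_set):
    pset, entries = tiny_set
    ps = pset.unflatten(pset.flatten() * 1.02)
    rep = evaluate(entries, ps, order=1)
    w = np.linalg.eigvalsh(rep.hessian_gram)
    assert w.min() >= -1e-8


def test_exact_minus_gram_is_residual_curvature(tiny_set):
    pset, entries = tiny_set
    ps = pset.unflatten(pset.flatten() * 1.01)
    rep = evaluate(entries, ps, order=2)
    from mndopt.property_derivs import entry_derivatives
    n = len(ps.index_map())
    acc = np.zeros((n, n))
    for e in entries:
        d = entry_derivatives(e, ps, order=2)
        for p, ref, w in e.references():
            acc += 2.0 * w * w * (d[p].value - ref) * d[p].hess
    acc = 0.5 * (acc + acc.T)
    assert np.abs((rep.hessian - rep.hessian_gram) - acc).max() < 1e-8


def test_modified_hessian_2x2_closed_form():
    H = np.array([[0.0, 2.0], [2.0, 0.0]])
    assert np.allclose(modified_hessian(H), np.array([[2.0, 0.0], [0.0, 2.0]]),
                       atol=1e-14)


def test_modified_hessian_identity_when_psd(rng):
    A = rng.normal(size=(6, 6))
    H = A @ A.T
    assert np.abs(modified_hessian(H) - H).max() < 1e-12


@given(st.integers(min_value=0, max_value=10_000))
def test_modified_hessian_spectrum_is_absolute(seed):
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(5, 5))
    H = A + A.T
    w = np.linalg.eigvalsh(H)
    w2 = np.linalg.eigvalsh(modified_hessian(H))
    assert np.abs(np.sort(np.abs(w)) - w2).max() < 1e-10


def test_eigen_report_sorted_and_sign_fixed(rng):
    A = rng.normal(size=(5, 5))
    w, V = eigen_sorted(A + A.T)
    assert np.all(np.diff(w) >= 0)
    for k in range(5):
        nz = np.nonzero(np.abs(V[:, k]) > 1e-12)[0]
        assert V[nz[0], k] > 0


def test_scf_failure_names_molecule(mndo_params, monkeypatch):
    """A non-converging entry aborts the objective, naming the molecule."""
    from mndopt import objective as obj
    from mndopt.scf import ScfError

    def broken(mol, pset, *a, **kw):
        raise ScfError(f"{mol.name}: SCF not converged")

    monkeypatch.setattr(obj, "scf_solve", broken)
    entries = [TrainingEntry(fixture_molecule("H2O"), hf=-60.0)]
    with pytest.raises(ObjectiveError, match="H2O"):
        obj.evaluate(entries, mndo_params, order=0)


def test_rms_by_property(tiny_set):
    pset, entries = tiny_set
    rep = evaluate(entries, pset, order=0)
    rms = rms_by_property(rep.residuals)
    for v in rms.values():
        assert v == pytest.approx(0.0, abs=1e-9)
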
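# mndopt

An MNDO-class semi-empirical quantum chemistry engine (H, C, N, O, F; NDDO
integral approximation, point-multipole two-electron model) whose defining
feature is **fully analytic first and second derivatives of molecular
properties with respect to the semi-empirical parameters**, obtained from
first- and second-order coupled-perturbed Hartree-Fock (CPHF) response in
the orthogonalized basis — and, on top of them, a parameterization stack:
the weighted least-squares error function, its exact 37x37 parameter
Hessian, the positive-semidefinite Gram approximant used by PM7-style
parameterizations, the modified (absolute-eigenvalue) Hessian, and three
optimizers (approximated line search, trust-radius Hessian descent,
trust-region).

It is aimed at people who develop or study semi-empirical parameterizations:
the exact parameter Hessian distinguishes minima from saddle points on the
error surface, which the Gram approximant — being positive semidefinite by
construction — cannot.

## The model in brief

For a training set of molecules with reference heats of formation (kcal/mol),
ionization energies (eV), dipole moments (D) and reference-geometry gradient
norms (kcal/(mol*bohr)), the error function is

    S = sum_alpha  C_alpha^2 (xi_alpha^ref - xi_alpha)^2 ,

with weights C = (1, 10, 20, 0.5) in the respective reciprocal units.  Each
element carries up to eight optimizable parameters (alpha, beta_s, beta_p,
U_ss, U_pp, zeta_s, zeta_p, E_isol; hydrogen lacks the p fields), giving a
37-component vector p for the CHNOF set.  The package computes

    dS/dp            exactly (first-order CPHF),
    d2S/dp dp'       exactly (second-order CPHF),
    H_gram = 2 sum C^2 (dxi/dp)(dxi/dp)^T      (no second derivatives),
    H_abs  = V |Lambda| V^T  for  H = V Lambda V^T,

and optimizes p with any of the three update schemes using any of the three
curvature matrices.  See `docs/methods.md` for the full formalism and the
numerical choices.

## Worked example

Generate a small synthetic training set whose references are computed by
the engine itself at the packaged original-MNDO parameters, inspect it, and
refit from a perturbed start:

    $ mndopt make-fixtures --suite H2,HF,H2O,NH3,CO --seed 0 --out train.txt
    wrote 5 entries to train.txt

    $ mndopt props train.txt --params mndo
    molecule      dHf(kcal/mol)    IE(eV)    mu(D)  |g|(kcal/mol/bohr)
    H2                   2.8785   15.1974   0.0000           39.562217
    HF                 -58.3126   14.8969   1.9501           56.323933
    H2O                -60.5734   12.1920   1.7904           19.545897
    NH3                 -5.8436   11.0408   1.7406            7.829063
    CO                 -3.9870    13.3198   0.0235           94.639693

    $ mndopt evaluate train.txt --params mndo
    S = 0.0
    rms[dip] = 0.000000
    rms[hf] = 0.000000
    rms[ie] = 0.000000

(the references were generated at these parameters, so the fit is exact and
S = 0; the heats of formation are ordinary MNDO values at experimental
geometries, e.g. -60.6 kcal/mol for water).  A closed-loop refit after
shifting two hydrogen parameters:

    $ python - <<'PY'
    from mndopt import load_packaged_parameters, write_parameter_file
    ps = load_packaged_parameters("mndo")
    ps.elements["H"].beta_s *= 1.05
    ps.elements["H"].zeta_s *= 0.98
    write_parameter_file(ps, "start.par")
    PY
    $ mndopt fit train.txt --params start.par --method tro --hessian abs \
          --maxiter 12 --out fitted.par
    iter    1  S   1.824018e+01  |g|  1.892e+04  |d|   0.1000  R   0.1000  rho   0.779  accepted 1
    iter    2  S   2.965302e-01  |g|  4.656e+03  |d|   0.1000  R   0.1250  rho   0.918  accepted 1
    ...
    final S = 1.717348475919193e-19 (max iterations reached)

S falls by some eighteen orders of magnitude and `fitted.par` returns to the
generating parameters.  The `hessian` subcommand writes eigenvalue reports
(`--mode exact|pm7|abs`), and `fdcheck` cross-validates any dS/dp component
against Richardson-extrapolated finite differences.

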
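# Methods

`mndopt` implements an MNDO-class semi-empirical model (s/p valence basis,
NDDO integral approximation, point-multipole two-electron model, exponential
core-repulsion function) together with fully analytic first and second
derivatives of its molecular properties with respect to the semi-empirical
parameters, and a parameterization stack built on those derivatives.  This
note records the model, the numerical choices, and what the synthetic
experiments do and do not demonstrate.

## The model

**Hamiltonian.** The valence basis is one 1s Slater orbital on H and a
2s/2p set on C, N, O, F, treated as Lowdin-orthogonalized (overlap =
identity).  The core matrix carries the one-center one-electron energies
U_ss/U_pp, two-center core-electron attractions V_mu-nu,B expressed through
the two-electron monopole integral times the core charge of B, and resonance
integrals beta_mu-nu = (beta_mu + beta_nu)/2 * S_mu-nu with Slater-orbital
overlaps S.  The Fock matrix is F_sigma = H + J(P) - K(P_sigma) with the
NDDO block structure for the generalized Coulomb and exchange contractions.
One-center two-electron integrals are the fixed experimental-derived
constants G_ss, G_sp, G_pp, G_p2, H_sp; they are configuration data, not
optimizable parameters.

**Two-center two-electron integrals.** Each NDDO charge distribution
(orbital pair on one atom) is a point-multipole configuration: monopole,
dipole of charges +-e/2 at +-D1, linear quadrupole e/4, -e/2, e/4 at
(+-2 D2, 0), and square quadrupole +-e/4 at (+-D2, +-D2), with

    D1 = <s|z|p> = (4 zs zp)^(n+1/2) (2n+1) / [sqrt(3) (zs+zp)^(2n+2)],
    D2 = sqrt(<r^2>_p / 5) = sqrt((2n+1)(2n+2)/20) / zp          (bohr).

Every multipole-multipole interaction is damped Klopman-style,
e^2 / sqrt(r^2 + (rho_lA + rho_lB)^2).  The additive terms are fixed by
one-center conditions evaluated *with the same configurations*:
rho0 = e^2/(2 G_ss); rho1 solves [mu mu]_0 = H_sp; rho2 solves
[Q Q]_0 = (G_pp - G_p2)/2 using the **square** quadrupole self-interaction.
The square-quadrupole convention is confirmed against published
original-MNDO energetics (CH4, H2O, N2, CO2, H2CO heats of formation agree
to a few tenths of a kcal/mol at the corresponding optimized geometries;
see tests/test_literature_values.py); the linear-quadrupole condition would
shift every heavy-heavy bond by roughly +15 kcal/mol.  rho1/rho2 are solved by a
bracketed Newton iteration at double precision and re-iterated in jet
arithmetic (below), which is implicit differentiation of the defining
conditions.

**Core-core repulsion.** V_AB = Z_A Z_B (s_A s_A|s_B s_B)
[1 + e^(-alpha_A R) + e^(-alpha_B R)], with the conventional N-H/O-H
variant in which the heavy atom's exponential is multiplied by R (in
angstrom).

**Properties.** Heat of formation Delta-H_f = k_conv (E_el + V_core -
sum_A E_isol(A)) + sum_A Delta-H_f^atom(A) (k_conv = 23.060548 kcal/mol per
eV); Koopmans ionization energy IE = -eps_HOMO (maximum occupied orbital
energy over both spins); dipole = point-charge term (core charge minus
Mulliken population, measured from the center of mass) plus the sp
hybridization term -2 D1 P_sp per axis, converted at 4.803204 D/(e angstrom);
Cartesian gradient = frozen-density pairwise energy-partition derivative
(exact at SCF stationarity), reported as |g| in kcal/(mol bohr) with
1 bohr = 0.52917721 angstrom.  |g| and |mu| are smoothed as
sqrt(v.v + delta^2), delta = 1e-8, so the objective chain stays
differentiable at the origin.

## SCF

Superposition-of-atomic-densities initial guess (uniform valence
populations; a bare core-Hamiltonian guess converges to spurious
higher-energy SCF solutions for several polar molecules), light damping for
four cycles, DIIS on [F, P], convergence to 1e-12 eV / 1e-10 RMS density.
Open shells are unrestricted; closed shells take an exactly spin-restricted
path.  On DIIS failure the solver retries once with a 3 eV virtual level
shift that is released before the final diagonalization.  A warm-start
density can be supplied; the optimizer threads the previous iteration's
densities through, which keeps every molecule on a continuous SCF branch
along the parameter trajectory.

## Analytic parameter derivatives

All integral derivatives — first and second with respect to any parameters,
plus the mixed third derivatives d^3(integral)/d tau d p1 d p2 needed for
the |g| second-derivative chain — are produced by forward-mode *multilinear
jet* arithmetic: truncated Taylor propagation along up to three tagged
directions through the closed-form integral expressions (including the
Newton iterations for rho1/rho2 and the diatomic-frame rotation).  This is
exact analytic differentiation to machine precision, not finite
differencing; the B_k auxiliary integrals switch to a Taylor-series branch
for |q| < 2, so the near-equal-exponent case is differentiable without 0/0
cancellation.  Channels (parameter pairs, Cartesian components) are
vectorized through a leading axis of the derivative components.

First-order responses solve the coupled occupied-virtual equations
(eps_j - eps_i) x_ij - R_ij(x) = F^q_ij with one dense LU-factorized
operator per molecule, reused for every parameter and for the second-order
equations (identical structure with gamma^{q1q2} as unknown); closed shells
solve a single spin block with coupling J(2 dP) - K(dP).  The full rotation
matrices are completed by direct substitution; for equal-occupancy orbital
pairs degenerate within 1e-6 eV the intra-block rotation is pure gauge and
set to zero (density-level quantities are verified gauge invariant).  The
second-order density is assembled from dC = C x and d2C = C gamma directly;
the x-quadratic ("sigma") term restricts the first contribution's summation
index to virtuals, which is required for Tr d2P = 0 (electron
conservation).

Property derivatives then follow: Delta-H_f first derivatives need only the
static integral derivatives (stationarity), and its second derivatives only
first-order responses, via trace contractions that reuse the static Fock
derivatives through the self-adjointness of J and K; IE and dipole second
derivatives use the full second-order response; |g| derivatives evaluate
the pairwise energy-partition expression in jet arithmetic with the density
matrix itself carrying dP and d2P as seeds, which reproduces the chain rule
through density response and mixed integral derivatives mechanically.  One
relative-coordinate direction per Cartesian axis serves every atom pair at
once (pair quantities depend on coordinates only through the pair vector).

## Objective and optimizers

S = sum C_alpha^2 (xi_ref - xi)^2 with default weights 1 (kcal/mol)^-1,
10 eV^-1, 20 D^-1 and 0.5 (kcal/(mol bohr))^-1 for Delta-H_f, IE, <mu> and
|g|; geometry terms use |g| at the reference geometry with reference value
0.  The gradient and the exact Hessian follow by the chain rule; the Gram
("PM7-style") approximant omits the residual-weighted second-derivative
term and is positive semidefinite by construction; the modified Hessian
takes absolute eigenvalues while preserving eigenvectors.  Non-converging
molecules abort the evaluation rather than being skipped (skipping would
change S discontinuously).

Three update schemes: approximated line search (normalized
Hessian-descent direction, closed-form minimizer of the linearized
surrogate — the printed argmax has no finite solution for a sum of
squares), trust-radius Hessian descent, and trust-region steps
d = -(B + lambda I)^-1 g with lambda from the secular equation on the
eigendecomposition (hard case included).  Trust-radius bookkeeping: grow by
5/4 when rho > 0.8 and S decreased, halve when rho < 0.25 or S increased
(step rejected), cap at |d|max = 2; defaults R0 = 0.1 (trust region) and
2.0 (Hessian descent); ALS rejections halve the step cap.

## Synthetic data and what the tests show

The fixture library holds 40 small CHNOF molecules at literature-style
experimental geometries (every element appears in at least three).  The
generator computes reference Delta-H_f/IE/dipole values with the engine
itself at a chosen parameter vector p*, optionally adding Gaussian noise
(defaults 5 kcal/mol, 0.3 eV, 0.2 D — the size of typical MNDO-class
errors against experiment).  IE references are only emitted when the HOMO
is well separated (the Koopmans derivative is otherwise ill-defined) and
dipole references only for closed shells with |mu| > 0.1 D.  Geometry (|g|)
terms are off in exact (zero-noise) mode: fixture geometries are not
stationary points of the model at p*, while the formalism pins the |g|
reference at zero, so including them would contradict the S(p*) = 0 global
minimum that closed-loop recovery relies on.

With zero noise the closed loop is exact: S has its global minimum 0 at p*,
so parameter recovery from a perturbed start probes the entire derivative
and optimization stack quantitatively.  What it does not probe: agreement
with experimental data, the quality of the MNDO model itself, or behavior
on molecules outside the CHNOF/valence-basis domain.  The noisy-set
experiments reproduce the qualitative distinction between optimizing on
the positive-semidefinite Gram approximant (which cannot distinguish
saddle points from minima) and on the modified Hessian with trust-region
steps (which terminates on the exact surface's descent structure): the
exact-Hessian spectrum is diagonalized at both endpoints.

Problem sizes used by the acceptance experiments (a package choice for
desk-scale reproducibility): 10 molecules for full derivative/FD
cross-validation; 25 molecules, a 2% multiplicative start perturbation and
trust-region steps on the modified Hessian (R0 = 0.1, |d|max = 2) for
closed-loop recovery; 40 molecules over 3 seeds for the qualitative
comparison, with a 1.5% start perturbation, 25 line-search iterations on
the Gram approximant versus 35 trust-region iterations on the modified
Hessian (R0 = 0.3), and the exact Hessian diagonalized at both endpoints.
First- and second-order responses are solved for all parameters (pairs) of
a molecule in one batched LU solve; second-derivative integral channels are
allocated only for parameter pairs that couple through the integrals
(zeta x {zeta, beta, alpha} and same-parameter diagonals; all other static
second derivatives vanish identically).

## Known limitations

- Elements H, C, N, O, F only; no d orbitals; no PM7-style corrections to
  the two-electron asymptotics; no PDDG Gaussian core-repulsion terms.
- The Koopmans IE is non-differentiable at HOMO crossings; entries whose
  HOMO separation is small are flagged rather than differentiated.
- NO (doublet, degenerate pi* SOMO) has an ill-defined response and is not
  part of the fixture library.
- Geometry optimization, vibrational analysis and excited states are out of
  scope; the geometry objective uses |g| at the reference geometry.
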
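"""Physical constants, unit conversions and fixed per-element data.

Internal units: lengths in angstrom, energies in eV, dipoles in debye.
Slater exponents (zeta) are carried in bohr^-1 as is conventional for
NDDO parameter tables; conversions happen inside the integral code.
"""

# 1 bohr in angstrom
BOHR = 0.52917721

# e^2 / (4 pi eps0), in eV * angstrom (Coulomb law constant)
E2 = 14.399645

# eV -> kcal/mol
KCAL_PER_EV = 23.060548

# e * angstrom -> debye
DEBYE_PER_E_ANGSTROM = 4.803204

SUPPORTED_ELEMENTS = ("H", "C", "N", "O", "F")

ATOMIC_NUMBER = {"H": 1, "C": 6, "N": 7, "O": 8, "F": 9}

# valence (core) charge seen by the s,p basis
CORE_CHARGE = {"H": 1.0, "C": 4.0, "N": 5.0, "O": 6.0, "F": 7.0}

# number of valence basis functions: H -> s ; C,N,O,F -> s,px,py,pz
N_BASIS = {"H": 1, "C": 4, "N": 4, "O": 4, "F": 4}

# principal quantum number of the valence shell
N_SHELL = {"H": 1, "C": 2, "N": 2, "O": 2, "F": 2}

# atomic masses (u), used for the center of mass in the dipole origin
ATOMIC_MASS = {"H": 1.00794, "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998}

# experimental atomic heats of formation, kcal/mol (fixed constants of the
# heat-of-formation bookkeeping; not optimizable)
ATOM_HEAT_OF_FORMATION = {
    "H": 52.102,
    "C": 170.890,
    "N": 113.000,
    "O": 59.559,
    "F": 18.890,
}

# fixed one-center two-electron integrals (eV): G_ss, G_sp, G_pp, G_p2, H_sp.
# These are configuration constants of the MNDO-class Hamiltonian and are not
# part of the optimizable parameter vector.
ONE_CENTER_2E = {
    "H": {"G_ss": 12.848, "G_sp": 0.0, "G_pp": 0.0, "G_p2": 0.0, "H_sp": 0.0},
    "C": {"G_ss": 12.23, "G_sp": 11.47, "G_pp": 11.08, "G_p2": 9.84, "H_sp": 2.43},
    "N": {"G_ss": 13.59, "G_sp": 12.66, "G_pp": 12.98, "G_p2": 11.59, "H_sp": 3.14},
    "O": {"G_ss": 15.42, "G_sp": 14.48, "G_pp": 14.52, "G_p2": 12.98, "H_sp": 3.94},
    "F": {"G_ss": 16.92, "G_sp": 17.25, "G_pp": 16.71, "G_p2": 14.91, "H_sp": 4.83},
}
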
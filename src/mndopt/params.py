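"""Optimizable MNDO parameters and the flattened parameter vector.

Each element carries eight optimizable parameters (five for hydrogen, which
has no p shell): the core-repulsion exponent alpha (1/angstrom), resonance
parameters beta_s/beta_p (eV), one-center one-electron energies U_ss/U_pp
(eV), Slater exponents zeta_s/zeta_p (1/bohr) and the isolated-atom
electronic energy E_isol (eV).  The fixed one-center two-electron constants
(G_ss, G_sp, G_pp, G_p2, H_sp) and the experimental atomic heats of formation
are configuration constants, not optimized.

The flattened vector is element-major in the order H, C, N, O, F with field
order (alpha, beta_s, beta_p, U_ss, U_pp, zeta_s, zeta_p, E_isol), skipping
absent hydrogen fields; the full CHNOF set flattens to length 37.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Dict, List, Optional, Tuple

import numpy as np

from .constants import ATOMIC_NUMBER, ONE_CENTER_2E, ATOM_HEAT_OF_FORMATION, SUPPORTED_ELEMENTS


class ConfigurationError(ValueError):
    pass


FIELD_ORDER = ("alpha", "beta_s", "beta_p", "U_ss", "U_pp", "zeta_s", "zeta_p", "E_isol")
SP_ONLY_FIELDS = ("beta_p", "U_pp", "zeta_p")
ELEMENT_ORDER = SUPPORTED_ELEMENTS  # H, C, N, O, F


@dataclass
class ElementParams:
    element: str
    alpha: float
    beta_s: float
    U_ss: float
    zeta_s: float
    E_isol: float
    beta_p: Optional[float] = None
    U_pp: Optional[float] = None
    zeta_p: Optional[float] = None

    def __post_init__(self):
        if self.element not in SUPPORTED_ELEMENTS:
            raise ConfigurationError(f"unsupported element {self.element!r}")
        has_p = self.element != "H"
        for f in SP_ONLY_FIELDS:
            v = getattr(self, f)
            if has_p and v is None:
                raise ConfigurationError(f"{self.element}: missing mandatory field {f}")
            if not has_p and v is not None:
                raise ConfigurationError(f"H carries no p-type field {f}")
        if self.zeta_s <= 0 or (has_p and self.zeta_p <= 0):
            raise ConfigurationError(f"{self.element}: Slater exponents must be positive")

    @property
    def Z(self) -> int:
        return ATOMIC_NUMBER[self.element]

    @property
    def one_center(self) -> Dict[str, float]:
        g = ONE_CENTER_2E[self.element]
        if any(v < 0 for v in g.values()) or g["G_ss"] <= 0:
            raise ConfigurationError(f"{self.element}: one-center constants must be positive")
        return g

    @property
    def heat_of_formation(self) -> float:
        return ATOM_HEAT_OF_FORMATION[self.element]

    def fields(self) -> Tuple[str, ...]:
        if self.element == "H":
            return tuple(f for f in FIELD_ORDER if f not in SP_ONLY_FIELDS)
        return FIELD_ORDER


@dataclass
class ParameterSet:
    elements: Dict[str, ElementParams] = field(default_factory=dict)

    def __getitem__(self, element: str) -> ElementParams:
        try:
            return self.elements[element]
        except KeyError:
            raise ConfigurationError(f"no parameters for element {element!r}") from None

    def __contains__(self, element: str) -> bool:
        return element in self.elements

    def copy(self) -> "ParameterSet":
        return ParameterSet({e: replace(p) for e, p in self.elements.items()})

    # -- flattening -----------------------------------------------------
    def index_map(self) -> List[Tuple[str, str]]:
        """Ordered (element, field) labels of the flattened vector."""
        out = []
        for el in ELEMENT_ORDER:
            if el not in self.elements:
                continue
            out.extend((el, f) for f in self.elements[el].fields())
        return out

    def flatten(self) -> np.ndarray:
        return np.array([getattr(self.elements[el], f) for el, f in self.index_map()],
                        dtype=float)

    def unflatten(self, vector: np.ndarray) -> "ParameterSet":
        idx = self.index_map()
        vector = np.asarray(vector, dtype=float)
        if vector.shape != (len(idx),):
            raise ConfigurationError(
                f"parameter vector length {vector.shape} does not match index map {len(idx)}")
        new = self.copy()
        for (el, f), v in zip(idx, vector):
            setattr(new.elements[el], f, float(v))
        return new


def flatten_parameters(pset: ParameterSet) -> Tuple[np.ndarray, List[Tuple[str, str]]]:
    return pset.flatten(), pset.index_map()


# -- file I/O -----------------------------------------------------------

def read_parameter_file(path) -> ParameterSet:
    """Read a plain-text ``ELEMENT KEY VALUE`` parameter file."""
    raw: Dict[str, Dict[str, float]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ConfigurationError(f"{path}:{lineno}: expected 'ELEMENT KEY VALUE'")
            el, key, sval = parts
            if el not in SUPPORTED_ELEMENTS:
                raise ConfigurationError(f"{path}:{lineno}: unsupported element {el!r}")
            if key not in FIELD_ORDER:
                raise ConfigurationError(f"{path}:{lineno}: unknown key {key!r}")
            try:
                val = float(sval)
            except ValueError:
                raise ConfigurationError(f"{path}:{lineno}: bad value {sval!r}") from None
            raw.setdefault(el, {})[key] = val
    if not raw:
        raise ConfigurationError(f"{path}: empty parameter file")
    elements = {}
    for el, kv in raw.items():
        try:
            elements[el] = ElementParams(element=el, **kv)
        except TypeError as exc:
            raise ConfigurationError(f"{path}: element {el}: {exc}") from None
    return ParameterSet(elements)


def write_parameter_file(pset: ParameterSet, path) -> None:
    with open(path, "w") as fh:
        for el in ELEMENT_ORDER:
            if el not in pset.elements:
                continue
            ep = pset.elements[el]
            for f in ep.fields():
                fh.write(f"{el} {f} {float(getattr(ep, f))!r}\n")


def load_packaged_parameters(name: str) -> ParameterSet:
    """Load one of the packaged parameter sets by file stem.

    Available: ``mndo`` (original MNDO values), ``refit_chnof`` (the refit
    CHNOF minimum), ``pddg_mndo_start``, ``no_mndo_start``.
    """
    ref = resources.files("mndopt.data") / f"{name}.par"
    with resources.as_file(ref) as p:
        return read_parameter_file(p)
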
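"""Molecules, training entries and the plain-text training-set format."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .constants import CORE_CHARGE, SUPPORTED_ELEMENTS

# default weighting factors C_alpha of the error function, per property
# (kcal/mol, eV, debye, kcal/(mol*bohr) reciprocals respectively)
DEFAULT_WEIGHTS = {"hf": 1.0, "ie": 10.0, "dip": 20.0, "geo": 0.5}

PROPERTY_KEYS = ("hf", "ie", "dip", "geo")


class MoleculeError(ValueError):
    pass


@dataclass
class Molecule:
    name: str
    symbols: Tuple[str, ...]
    coords: np.ndarray  # (n_atoms, 3), angstrom
    charge: int = 0
    multiplicity: int = 1

    def __post_init__(self):
        self.symbols = tuple(self.symbols)
        self.coords = np.asarray(self.coords, dtype=float).reshape(len(self.symbols), 3)
        bad = [s for s in self.symbols if s not in SUPPORTED_ELEMENTS]
        if bad:
            raise MoleculeError(f"{self.name}: unsupported element(s) {sorted(set(bad))}")
        if self.n_electrons < 1:
            raise MoleculeError(f"{self.name}: no electrons")
        if (self.n_electrons - (self.multiplicity - 1)) % 2:
            raise MoleculeError(
                f"{self.name}: electron count {self.n_electrons} inconsistent with "
                f"multiplicity {self.multiplicity}")

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    @property
    def n_electrons(self) -> int:
        return int(round(sum(CORE_CHARGE[s] for s in self.symbols))) - self.charge

    @property
    def elements(self) -> Tuple[str, ...]:
        seen = []
        for s in self.symbols:
            if s not in seen:
                seen.append(s)
        return tuple(seen)

    def translated(self, shift) -> "Molecule":
        return Molecule(self.name, self.symbols, self.coords + np.asarray(shift),
                        self.charge, self.multiplicity)

    def rotated(self, R) -> "Molecule":
        return Molecule(self.name, self.symbols, self.coords @ np.asarray(R).T,
                        self.charge, self.multiplicity)


@dataclass
class TrainingEntry:
    molecule: Molecule
    hf: Optional[float] = None        # reference heat of formation, kcal/mol
    ie: Optional[float] = None        # reference ionization energy, eV
    dip: Optional[float] = None       # reference dipole magnitude, debye
    geo: bool = False                 # use |g| at this geometry with reference 0
    weights: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))

    def __post_init__(self):
        if self.hf is None and self.ie is None and self.dip is None and not self.geo:
            raise MoleculeError(f"{self.molecule.name}: entry carries no reference data")
        for k, v in self.weights.items():
            if k not in PROPERTY_KEYS:
                raise MoleculeError(f"{self.molecule.name}: unknown weight key {k!r}")
            if v <= 0:
                raise MoleculeError(f"{self.molecule.name}: weights must be positive")
        for k in PROPERTY_KEYS:
            self.weights.setdefault(k, DEFAULT_WEIGHTS[k])

    def references(self) -> List[Tuple[str, float, float]]:
        """(property, reference value, weight) for every referenced property."""
        out = []
        if self.hf is not None:
            out.append(("hf", float(self.hf), self.weights["hf"]))
        if self.ie is not None:
            out.append(("ie", float(self.ie), self.weights["ie"]))
        if self.dip is not None:
            out.append(("dip", float(self.dip), self.weights["dip"]))
        if self.geo:
            out.append(("geo", 0.0, self.weights["geo"]))
        return out


# -- training-set file I/O -----------------------------------------------

def _parse_kv(line: str, path, lineno: int) -> Dict[str, str]:
    out = {}
    for tok in line.split():
        if "=" not in tok:
            raise MoleculeError(f"{path}:{lineno}: expected key=value, got {tok!r}")
        k, v = tok.split("=", 1)
        out[k] = v
    return out


def read_training_set(path) -> List[TrainingEntry]:
    """Read the block-format training-set file.

    Blocks: ``[molecule] name=<id> charge=<int> mult=<int>`` followed by XYZ
    lines ``<element> <x> <y> <z>`` (angstrom), then
    ``[ref] hf=... ie=... dip=... geo=<0|1>`` (any subset) and an optional
    ``[weights]`` override line.
    """
    entries: List[TrainingEntry] = []
    cur = None  # (meta, symbols, coords, ref, weights)

    def _flush(lineno):
        nonlocal cur
        if cur is None:
            return
        meta, symbols, coords, ref, weights = cur
        if not symbols:
            raise MoleculeError(f"{path}:{lineno}: molecule block without atoms")
        if ref is None:
            raise MoleculeError(f"{path}:{lineno}: molecule {meta.get('name')} has no [ref] line")
        mol = Molecule(meta.get("name", f"mol{len(entries)}"), symbols, np.array(coords),
                       int(meta.get("charge", 0)), int(meta.get("mult", 1)))
        kw = {}
        for k in ("hf", "ie", "dip"):
            if k in ref:
                kw[k] = float(ref[k])
        kw["geo"] = bool(int(ref.get("geo", 0)))
        w = dict(DEFAULT_WEIGHTS)
        w.update({k: float(v) for k, v in weights.items()})
        entries.append(TrainingEntry(mol, weights=w, **kw))
        cur = None

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if line.startswith("[molecule]"):
                _flush(lineno)
                cur = (_parse_kv(line[len("[molecule]"):], path, lineno), [], [], None, {})
            elif line.startswith("[ref]"):
                if cur is None:
                    raise MoleculeError(f"{path}:{lineno}: [ref] outside molecule block")
                cur = (*cur[:3], _parse_kv(line[len("[ref]"):], path, lineno), cur[4])
            elif line.startswith("[weights]"):
                if cur is None:
                    raise MoleculeError(f"{path}:{lineno}: [weights] outside molecule block")
                cur[4].update(_parse_kv(line[len("[weights]"):], path, lineno))
            else:
                if cur is None:
                    raise MoleculeError(f"{path}:{lineno}: atom line outside molecule block")
                parts = line.split()
                if len(parts) != 4:
                    raise MoleculeError(f"{path}:{lineno}: expected '<element> <x> <y> <z>'")
                el = parts[0]
                if el not in SUPPORTED_ELEMENTS:
                    raise MoleculeError(f"{path}:{lineno}: unsupported element {el!r}")
                cur[1].append(el)
                cur[2].append([float(x) for x in parts[1:]])
        _flush("<eof>")
    if not entries:
        raise MoleculeError(f"{path}: empty training set")
    return entries


def write_training_set(entries: List[TrainingEntry], path) -> None:
    with open(path, "w") as fh:
        for e in entries:
            m = e.molecule
            fh.write(f"[molecule] name={m.name} charge={m.charge} mult={m.multiplicity}\n")
            for s, xyz in zip(m.symbols, m.coords):
                fh.write(f"{s} {float(xyz[0])!r} {float(xyz[1])!r} {float(xyz[2])!r}\n")
            refs = []
            for k in ("hf", "ie", "dip"):
                v = getattr(e, k)
                if v is not None:
                    refs.append(f"{k}={float(v)!r}")
            refs.append(f"geo={int(e.geo)}")
            fh.write("[ref] " + " ".join(refs) + "\n")
            if any(abs(e.weights[k] - DEFAULT_WEIGHTS[k]) > 0 for k in PROPERTY_KEYS):
                fh.write("[weights] " + " ".join(f"{k}={e.weights[k]!r}"
                                                 for k in PROPERTY_KEYS) + "\n")
            fh.write("\n")
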
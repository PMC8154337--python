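"""Molecular system definition and XYZ input."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .basis import ATOMIC_NUMBER, BOHR_PER_ANGSTROM

# Chemical core shells frozen by default; Fe/Co would additionally freeze the
# subvalence shell, but only H-Ne are supported by the built-in bases.
_CORE_ORBITALS = {z: (0 if z <= 2 else 1) for z in range(1, 11)}


class InputError(ValueError):
    pass


@dataclass
class MolecularSystem:
    """Geometry (Angstrom), charge, spin multiplicity and basis names."""

    atoms: list  # (symbol, (x, y, z) in Angstrom)
    charge: int = 0
    multiplicity: int = 1
    basis_name: str = "sv"
    aux_basis_name: str = ""
    n_frozen_core: int | None = None  # None -> chemical-core policy
    name: str = ""

    symbols: list = field(init=False)
    coords: np.ndarray = field(init=False)  # bohr

    def __post_init__(self):
        self.symbols = [a[0] for a in self.atoms]
        self.coords = np.array([a[1] for a in self.atoms], float) * BOHR_PER_ANGSTROM
        if not self.aux_basis_name:
            self.aux_basis_name = self.basis_name
        zs = [ATOMIC_NUMBER[s] for s in self.symbols]
        self.charges = np.array(zs, float)
        self.n_electrons = int(sum(zs)) - self.charge
        ns = self.multiplicity - 1
        if ns > self.n_electrons or (self.n_electrons - ns) % 2 != 0:
            raise InputError(
                f"multiplicity {self.multiplicity} inconsistent with "
                f"{self.n_electrons} electrons")
        self.n_up = (self.n_electrons + ns) // 2
        self.n_dn = (self.n_electrons - ns) // 2
        self.n_somo = ns
        self.n_domo = self.n_dn
        if self.n_frozen_core is None:
            self.n_frozen_core = int(sum(_CORE_ORBITALS[z] for z in zs))
        if self.n_frozen_core > self.n_domo:
            raise InputError("more frozen-core orbitals than DOMOs")

    @property
    def natm(self) -> int:
        return len(self.atoms)

    def nuclear_repulsion(self) -> float:
        e = 0.0
        for i in range(self.natm):
            for j in range(i):
                r = np.linalg.norm(self.coords[i] - self.coords[j])
                e += self.charges[i] * self.charges[j] / r
        return e

    def to_xyz(self) -> str:
        lines = [str(self.natm), self.name]
        for sym, xyz in self.atoms:
            lines.append(f"{sym:2s} {xyz[0]:15.8f} {xyz[1]:15.8f} {xyz[2]:15.8f}")
        return "\n".join(lines) + "\n"


def read_xyz(path, charge=0, multiplicity=1, basis_name="sv",
             aux_basis_name="", n_frozen_core=None) -> MolecularSystem:
    """Read a standard XYZ file (count line, comment line, symbol x y z)."""
    lines = Path(path).read_text().strip().splitlines()
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise InputError(f"malformed XYZ header in {path}") from exc
    name = lines[1].strip() if len(lines) > 1 else ""
    atoms = []
    for ln in lines[2:2 + n]:
        parts = ln.split()
        atoms.append((parts[0].capitalize(),
                      (float(parts[1]), float(parts[2]), float(parts[3]))))
    if len(atoms) != n:
        raise InputError(f"XYZ file {path} promises {n} atoms, found {len(atoms)}")
    return MolecularSystem(atoms, charge, multiplicity, basis_name,
                           aux_basis_name, n_frozen_core, name=name)
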
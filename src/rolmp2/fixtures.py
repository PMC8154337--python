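"""Deterministic fixture molecules: radicals, diradicals and chains.

All geometries are generated from standard bond lengths and angles; an
optional seeded Gaussian jitter decorrelates conformers reproducibly.
"""

from __future__ import annotations

import numpy as np

from .system import InputError, MolecularSystem

# standard bond parameters (Angstrom, degrees)
_CC = 1.54
_CH = 1.09
_ANG = 111.0


def _jitter(atoms, seed, sigma):
    if not sigma:
        return atoms
    rng = np.random.default_rng(seed)
    return [(s, tuple(np.asarray(x) + rng.normal(0.0, sigma, 3)))
            for s, x in atoms]


def _radical_geometries() -> dict:
    """Small doublet/triplet radicals with fixed geometries."""
    rad = {}
    rad["OH"] = ([("O", (0.0, 0.0, 0.0)), ("H", (0.0, 0.0, 0.97))], 0, 2)
    a = np.deg2rad(103.4 / 2)
    rad["NH2"] = ([("N", (0.0, 0.0, 0.0)),
                   ("H", (0.0, 1.024 * np.sin(a), 1.024 * np.cos(a))),
                   ("H", (0.0, -1.024 * np.sin(a), 1.024 * np.cos(a)))], 0, 2)
    rad["CH3"] = ([("C", (0.0, 0.0, 0.0))] +
                  [("H", (1.079 * np.cos(t), 1.079 * np.sin(t), 0.0))
                   for t in np.deg2rad([0, 120, 240])], 0, 2)
    b = np.deg2rad(135.5 / 2)
    rad["CH2_triplet"] = ([("C", (0.0, 0.0, 0.0)),
                           ("H", (0.0, 1.085 * np.sin(b), 1.085 * np.cos(b))),
                           ("H", (0.0, -1.085 * np.sin(b), 1.085 * np.cos(b)))],
                          0, 3)
    c = np.deg2rad(124.5)
    rad["HCO"] = ([("C", (0.0, 0.0, 0.0)),
                   ("O", (0.0, 0.0, 1.175)),
                   ("H", (0.0, 1.125 * np.sin(c), 1.125 * np.cos(c)))], 0, 2)
    # planar vinyl radical, approximate geometry
    rad["C2H3"] = ([("C", (0.0, 0.0, 0.0)), ("C", (0.0, 0.0, 1.31)),
                    ("H", (0.0, 0.95, 1.86)), ("H", (0.0, -0.95, 1.86)),
                    ("H", (0.0, 0.82, -0.70))], 0, 2)
    return rad


def _singlet_geometries() -> dict:
    mol = {}
    mol["H2O"] = [("O", (0.0, 0.0, 0.1173)), ("H", (0.0, 0.7572, -0.4692)),
                  ("H", (0.0, -0.7572, -0.4692))]
    t = np.deg2rad(109.47)
    mol["NH3"] = [("N", (0.0, 0.0, 0.0)),
                  ("H", (0.9377, 0.0, -0.3816)),
                  ("H", (-0.4689, 0.8121, -0.3816)),
                  ("H", (-0.4689, -0.8121, -0.3816))]
    r = _CH / np.sqrt(3.0)
    mol["CH4"] = [("C", (0.0, 0.0, 0.0)), ("H", (r, r, r)), ("H", (r, -r, -r)),
                  ("H", (-r, r, -r)), ("H", (-r, -r, r))]
    mol["H2"] = [("H", (0.0, 0.0, 0.0)), ("H", (0.0, 0.0, 0.741))]
    return mol


def _zigzag_chain(n_carbons: int):
    """All-trans backbone carbons in the xz plane."""
    ang = np.deg2rad(_ANG)
    step_x = _CC * np.sin(ang / 2)
    step_z = _CC * np.cos(ang / 2)
    pos = []
    for k in range(n_carbons):
        pos.append(np.array([step_x * k, 0.0, step_z * (k % 2)]))
    return pos


def _alkane_atoms(n_carbons: int, radical_ends: bool):
    """CnH(2n+2) alkane, or the terminal diradical with one H removed per end."""
    carb = _zigzag_chain(n_carbons)
    atoms = [("C", tuple(c)) for c in carb]
    for k, c in enumerate(carb):
        up = 1.0 if k % 2 == 0 else -1.0
        # two out-of-plane hydrogens per backbone carbon
        atoms.append(("H", tuple(c + np.array([0.0, 0.89, -0.63 * up]))))
        atoms.append(("H", tuple(c + np.array([0.0, -0.89, -0.63 * up]))))
    # terminal hydrogens along the chain axis
    t0 = carb[0] + np.array([-0.95, 0.0, 0.52])
    t1 = carb[-1] + np.array([0.95, 0.0, 0.52 * (1.0 if (n_carbons - 1) % 2 == 0 else -1.0)])
    if not radical_ends:
        atoms.append(("H", tuple(t0)))
        atoms.append(("H", tuple(t1)))
    return atoms


_ALKYL_NAMES = {"methyl": 1, "ethyl": 2, "propyl": 3, "butyl": 4,
                "pentyl": 5, "hexyl": 6, "heptyl": 7, "octyl": 8}


def _alkyl_fragment(n_carbons: int):
    """CnH(2n+1) radical; radical carbon at the origin, chain along -x."""
    if n_carbons == 1:  # planar methyl
        return [("C", (0.0, 0.0, 0.0)),
                ("H", (-0.36, 1.02, 0.0)), ("H", (-0.36, -0.51, 0.88)),
                ("H", (-0.36, -0.51, -0.88))]
    atoms = _alkane_atoms(n_carbons, radical_ends=False)
    # drop the terminal hydrogen at carbon 0 (added first of the two)
    atoms = atoms[:-2] + atoms[-1:]
    # mirror so that the chain extends toward -x, radical carbon at origin
    return [(s, (-x[0], x[1], x[2])) for s, x in atoms]


def generate_fixture(kind: str, basis_name: str = "svp", seed: int = 0,
                     jitter: float = 0.0, **params):
    """Deterministic fixture systems.

    kind='radical_set'          -> list of small radicals
    kind='singlet_set'          -> list of closed-shell molecules
    kind='separated_diradical'  -> two radical fragments (one SOMO each,
                                   high-spin coupled) at a given separation
    kind='chain'                -> quasi-linear alkane chain; terminal
                                   diradical by default (closed_shell=True
                                   gives the plain alkane)
    """
    if kind == "radical_set":
        out = []
        for name, (atoms, q, m) in _radical_geometries().items():
            out.append(MolecularSystem(_jitter(atoms, seed, jitter), q, m,
                                       basis_name, name=name))
        return out
    if kind == "singlet_set":
        return [MolecularSystem(_jitter(a, seed, jitter), 0, 1, basis_name,
                                name=n)
                for n, a in _singlet_geometries().items()]
    if kind == "separated_diradical":
        separation = params.get("separation", 10.0)
        fragment = params.get("fragment", "hexyl")
        if separation <= 0:
            raise InputError("fragment separation must be positive")
        n_frag = _ALKYL_NAMES.get(fragment, fragment)
        if not isinstance(n_frag, int):
            raise InputError(f"unknown fragment '{fragment}'")
        frag = _alkyl_fragment(n_frag)
        atoms = list(frag)
        for s, x in frag:
            atoms.append((s, (separation - x[0], -x[1], x[2])))
        atoms = _jitter(atoms, seed, jitter)
        return MolecularSystem(atoms, 0, 3, basis_name,
                               name=f"{fragment}-diradical-{separation:g}A")
    if kind == "chain":
        n = params.get("n", 6)
        closed = params.get("closed_shell", False)
        if n < 2:
            raise InputError("chain needs at least two carbons")
        atoms = _jitter(_alkane_atoms(n, radical_ends=not closed), seed, jitter)
        mult = 1 if closed else 3
        return MolecularSystem(atoms, 0, mult, basis_name,
                               name=f"chain-C{n}{'' if closed else '-diradical'}")
    raise InputError(f"unknown fixture kind '{kind}'")
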
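"""Gaussian basis sets and their packed representation for the integral kernels.

The package ships two self-contained orbital basis sets generated
programmatically rather than read from external tables:

``minimal``
    One contracted function per occupied Slater shell (1s for H; 1s, 2s, 2p
    for Li-Ne).  Each contracted function is the classic least-squares
    three-Gaussian expansion of a Slater orbital, with Slater-rule exponents
    (the hydrogen 1s exponent uses the standard molecular value 1.24).

``sv`` (split valence, double-zeta quality)
    Same core description; every valence shell is split into an inner
    contraction of the two steepest fit primitives and a free outermost
    primitive, giving two radial degrees of freedom per valence shell.

``svp``
    ``sv`` plus one polarization shell per atom (p with exponent 1.1 on H,
    Cartesian d with exponent 0.8 on heavy atoms — the customary
    polarization exponents for first-row split-valence sets).

Auxiliary (density-fitting) bases are generated per element as even-tempered
sequences spanning twice the orbital primitive exponent range, with angular
momenta up to d.  See docs/methods.md for the rationale and accuracy checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BOHR_PER_ANGSTROM = 1.8897261254578281

ELEMENTS = ["X", "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne"]
ATOMIC_NUMBER = {s: z for z, s in enumerate(ELEMENTS)}

# Universal three-Gaussian expansions of unit-exponent Slater 1s, 2s and 2p
# orbitals (shared 2s/2p exponents); scaled by zeta**2 per element.
_EXP_1S = np.array([2.227660584, 0.405771156, 0.109818])
_CC_1S = np.array([0.154328967, 0.535328142, 0.444634542])
_EXP_2SP = np.array([0.994203, 0.231031, 0.0751386])
_CC_2S = np.array([-0.09996723, 0.39951283, 0.70011547])
_CC_2P = np.array([0.15591627, 0.60768372, 0.39195739])


def slater_zeta(z: int) -> dict[str, float]:
    """Slater-rule effective exponents for the occupied shells of element ``z``.

    Hydrogen's 1s uses the standard molecular scale value 1.24.
    """
    if z == 1:
        return {"1s": 1.24}
    if z == 2:
        return {"1s": z - 0.30}
    zetas = {"1s": z - 0.30}
    n_val = z - 2  # electrons in the 2s/2p group
    screen = 2 * 0.85 + max(n_val - 1, 0) * 0.35
    zetas["2sp"] = (z - screen) / 2.0
    return zetas


@dataclass
class Shell:
    """A contracted Cartesian Gaussian shell on one center."""

    l: int
    center: np.ndarray  # bohr
    exps: np.ndarray
    coefs: np.ndarray  # contraction coefficients for normalized primitives
    atom: int = -1

    @property
    def ncart(self) -> int:
        return (self.l + 1) * (self.l + 2) // 2


def _prim_norm(alpha: float, l: int) -> float:
    """Normalization of a primitive Cartesian Gaussian with angular (l,0,0)."""
    df = 1.0
    for k in range(2 * l - 1, 0, -2):
        df *= k
    return (2.0 * alpha / np.pi) ** 0.75 * (4.0 * alpha) ** (l / 2.0) / np.sqrt(df)


def element_shells(symbol: str, basis_name: str) -> list[Shell]:
    """Shells (at the origin) of one element for a built-in orbital basis."""
    z = ATOMIC_NUMBER[symbol]
    zetas = slater_zeta(z)
    name = basis_name.lower()
    polarize = False
    if name in ("minimal", "sto-3g-like", "min"):
        split = False
    elif name in ("sv", "dz", "split-valence"):
        split = True
    elif name in ("svp", "dzp"):
        split = True
        polarize = True
    else:
        raise ValueError(f"unknown orbital basis '{basis_name}'")

    shells: list[Shell] = []
    origin = np.zeros(3)

    def add(l, exps, coefs):
        shells.append(Shell(l, origin.copy(), np.asarray(exps, float),
                            np.asarray(coefs, float)))

    if z <= 2:
        e = _EXP_1S * zetas["1s"] ** 2
        if split:
            add(0, e[:2], _CC_1S[:2])
            add(0, e[2:], [1.0])
        else:
            add(0, e, _CC_1S)
        if polarize:
            add(1, [1.1], [1.0])
        return shells

    e1 = _EXP_1S * zetas["1s"] ** 2
    add(0, e1, _CC_1S)  # core is never split
    ev = _EXP_2SP * zetas["2sp"] ** 2
    if split:
        add(0, ev[:2], _CC_2S[:2])
        add(0, ev[2:], [1.0])
        add(1, ev[:2], _CC_2P[:2])
        add(1, ev[2:], [1.0])
    else:
        add(0, ev, _CC_2S)
        add(1, ev, _CC_2P)
    if polarize:
        add(2, [0.8], [1.0])
    return shells


def element_aux_shells(symbol: str, basis_name: str,
                       beta: float = 2.6, lmax: int = 2) -> list[Shell]:
    """Even-tempered auxiliary shells for density fitting.

    The exponents cover [2*min, 2*max] of the element's orbital primitive
    exponents with geometric spacing ``beta``; higher angular momenta use a
    progressively reduced upper bound since steep high-l product densities
    are dominated by the on-atom core products already described by l=0.
    """
    orb = element_shells(symbol, basis_name)
    alphas = np.concatenate([sh.exps for sh in orb])
    lo0, hi0 = 2.0 * alphas.min() * 0.7, 2.0 * alphas.max()
    origin = np.zeros(3)
    shells: list[Shell] = []
    for l in range(lmax + 1):
        hi = hi0 / (2.0 ** l) if l > 0 else hi0
        lo = lo0
        n = max(int(np.ceil(np.log(hi / lo) / np.log(beta))) + 1, 1)
        if l == 2:
            n = min(n, 3)
        exps = lo * beta ** np.arange(n)
        for a in exps:
            shells.append(Shell(l, origin.copy(), np.array([a]), np.array([1.0])))
    return shells


@dataclass
class BasisSet:
    """A list of shells over the atoms of a molecule, with packed arrays."""

    shells: list[Shell]
    # packed arrays for the numba kernels
    sh_l: np.ndarray = field(init=False)
    sh_coord: np.ndarray = field(init=False)
    sh_pstart: np.ndarray = field(init=False)
    sh_pnum: np.ndarray = field(init=False)
    prim_a: np.ndarray = field(init=False)
    prim_c: np.ndarray = field(init=False)
    sh_ao: np.ndarray = field(init=False)
    ao_norm: np.ndarray = field(init=False)
    ao_atom: np.ndarray = field(init=False)
    ao_shell: np.ndarray = field(init=False)

    def __post_init__(self):
        ls, coords, pstart, pnum, pa, pc, ao_off = [], [], [], [], [], [], []
        ao_atom, ao_shell = [], []
        nao = 0
        for isa, sh in enumerate(self.shells):
            ls.append(sh.l)
            coords.append(sh.center)
            pstart.append(len(pa))
            pnum.append(len(sh.exps))
            for a, c in zip(sh.exps, sh.coefs):
                pa.append(a)
                pc.append(c * _prim_norm(a, sh.l))
            ao_off.append(nao)
            for _ in range(sh.ncart):
                ao_atom.append(sh.atom)
                ao_shell.append(isa)
            nao += sh.ncart
        self.sh_l = np.array(ls, dtype=np.int64)
        self.sh_coord = np.array(coords, dtype=float)
        self.sh_pstart = np.array(pstart, dtype=np.int64)
        self.sh_pnum = np.array(pnum, dtype=np.int64)
        self.prim_a = np.array(pa, dtype=float)
        self.prim_c = np.array(pc, dtype=float)
        self.sh_ao = np.array(ao_off, dtype=np.int64)
        self.ao_atom = np.array(ao_atom, dtype=np.int64)
        self.ao_shell = np.array(ao_shell, dtype=np.int64)
        self.ao_norm = np.ones(self.nao)  # fixed later from the raw overlap

    @property
    def nao(self) -> int:
        return int(sum(sh.ncart for sh in self.shells))

    def packed(self):
        return (self.sh_l, self.sh_coord, self.sh_pstart, self.sh_pnum,
                self.prim_a, self.prim_c, self.sh_ao)

    def ao_indices_of_atoms(self, atoms) -> np.ndarray:
        mask = np.isin(self.ao_atom, np.asarray(list(atoms), dtype=np.int64))
        return np.nonzero(mask)[0]


def build_basis(symbols, coords_bohr, basis_name: str, kind: str = "orbital",
                **aux_kwargs) -> BasisSet:
    """Assemble a molecular basis (kind='orbital' or 'aux') in bohr."""
    shells: list[Shell] = []
    for ia, (sym, xyz) in enumerate(zip(symbols, coords_bohr)):
        maker = element_shells if kind == "orbital" else element_aux_shells
        if kind == "orbital":
            esh = maker(sym, basis_name)
        else:
            esh = maker(sym, basis_name, **aux_kwargs)
        for sh in esh:
            shells.append(Shell(sh.l, np.asarray(xyz, float).copy(),
                                sh.exps.copy(), sh.coefs.copy(), atom=ia))
    return BasisSet(shells)
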
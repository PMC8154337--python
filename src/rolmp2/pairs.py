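"""Multipole-approximated MP2 pair energies and strong/distant classification.

The Coulomb integral (i a | j b) between the product densities of two
well-separated LMO-virtual pairs is expanded in interaction orders R^-3
through R^-5 (dipole-dipole, dipole-quadrupole, quadrupole-quadrupole and
dipole-octopole); the monopoles vanish because each primary-domain virtual
is orthogonal to its LMO.  The pair energy sums Coulomb-only spin blocks
(up-up, down-down and mixed); blocks involving the spin-down channel of a
SOMO are absent, which motivates the occupation-dependent threshold scaling
f_w = 1, 1/2, 1/4 for DO-DO, DO-SO and SO-SO pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import integrals
from .basis import BOHR_PER_ANGSTROM
from .domains import Domain
from .localization import LocalOrbitalBasis
from .reference import RestrictedReference

MULTIPOLE_ORDER_PAIRS = [(1, 1), (1, 2), (2, 1), (2, 2), (1, 3), (3, 1)]
F_W = {"DO-DO": 1.0, "DO-SO": 0.5, "SO-SO": 0.25}
R_FLOOR_BOHR = 1.0 * BOHR_PER_ANGSTROM


@dataclass
class MultipoleSet:
    """Cartesian moments (orders 0..3) of LMO-virtual product densities."""

    center: np.ndarray                 # bohr
    moments: dict                      # spin -> (n_virt, 20) array
    virt_energies: dict                # spin -> (n_virt,) array
    spins: list


def _factorial(n):
    out = 1
    for k in range(2, n + 1):
        out *= k
    return out


def _deriv_tensor_inv_r(R: np.ndarray, max_order: int = 4) -> np.ndarray:
    """Cartesian derivative tensors of 1/|R| up to ``max_order``.

    Evaluated through the Hermite Coulomb recursion in its point-charge
    limit, which is exact for these derivatives.  Returns the dense
    (t, u, v) array.
    """
    alpha = 1e14
    Rt = integrals._rtensor(max_order, alpha, R[0], R[1], R[2])
    return 2.0 * np.sqrt(alpha / np.pi) * Rt


def _kernel_tables():
    """Precomputed index/coefficient tables for the interaction kernel."""
    comps = integrals.moment_components(3)
    rows, cols, coefs, tidx = [], [], [], []
    for (korder, lorder) in MULTIPOLE_ORDER_PAIRS:
        for ki, (oi, lam_i) in enumerate(comps):
            if oi != korder:
                continue
            fi = np.prod([_factorial(c) for c in lam_i])
            for kj, (oj, lam_j) in enumerate(comps):
                if oj != lorder:
                    continue
                fj = np.prod([_factorial(c) for c in lam_j])
                tt = tuple(a + b for a, b in zip(lam_i, lam_j))
                rows.append(ki)
                cols.append(kj)
                coefs.append((-1.0) ** lorder / (fi * fj))
                tidx.append(tt)
    tflat = np.ravel_multi_index(np.array(tidx).T, (5, 5, 5))
    return (np.array(rows), np.array(cols), np.array(coefs), tflat,
            len(comps))


_KTAB = None


def product_moments(pd: Domain, local_basis: LocalOrbitalBasis,
                    ref: RestrictedReference) -> MultipoleSet:
    """Moments of the PD's LMO-virtual product densities about the centroid."""
    mi = ref.integrals
    lmo_id = pd.central
    center = local_basis.lmo_centers[lmo_id]
    sub = mi.basis.shells
    # moment integrals in the PD AO sub-basis, about the LMO centroid
    from .basis import BasisSet
    shell_ids = sorted(set(mi.basis.ao_shell[a] for a in pd.ao_idx))
    subbasis = BasisSet([sub[s] for s in shell_ids])
    M = integrals.moments(subbasis, center, 3)
    spins = ["up"] if local_basis.lmo_is_somo[lmo_id] else ["up", "dn"]
    occ = pd.occ_lmo[:, 0]
    moms, ven = {}, {}
    for spin in ("up", "dn"):
        V = pd.virt_up if spin == "up" else pd.virt_dn
        moms[spin] = np.einsum("m,cmn,na->ac", occ, M, V)
        ven[spin] = pd.virt_e_up if spin == "up" else pd.virt_e_dn
    return MultipoleSet(center, moms, ven, spins)


def interaction_kernel(R: np.ndarray) -> np.ndarray:
    """(20, 20) kernel C with (i a|j b) ~= m_i C m_j^T for raw moments.

    Row/column ordering follows :func:`integrals.moment_components` (orders
    0..3); only interaction orders 2..4 contribute (dipole-dipole through
    dipole-octopole and quadrupole-quadrupole).
    """
    global _KTAB
    if np.linalg.norm(R) < 1e-8:
        raise ValueError("multipole expansion requires separated centroids")
    if _KTAB is None:
        _KTAB = _kernel_tables()
    rows, cols, coefs, tflat, ncomp = _KTAB
    T = _deriv_tensor_inv_r(R, 4).ravel()
    C = np.zeros((ncomp, ncomp))
    C[rows, cols] = coefs * T[tflat]
    return C


def multipole_interaction(moments_i: np.ndarray, moments_j: np.ndarray,
                          R: np.ndarray, kernel: np.ndarray | None = None
                          ) -> np.ndarray:
    """Approximate Coulomb integrals (i a | j b) for all virtual pairs.

    ``moments_*`` are (n_virt, 20) arrays of raw Cartesian product moments
    (orders 0..3) about the respective centroids; ``R`` is the displacement
    centroid_i - centroid_j in bohr.
    """
    if kernel is None:
        kernel = interaction_kernel(R)
    return moments_i @ kernel @ moments_j.T


@dataclass
class OrbitalPair:
    i: int
    j: int
    pair_type: str                  # DO-DO | DO-SO | SO-SO
    distance: float                 # bohr between Boys centroids
    pair_energy: float              # multipole estimate, E_h (<= 0)
    f_w: float
    e_same_spin: float = 0.0
    e_opposite_spin: float = 0.0
    classification: str = ""
    multipole_unreliable: bool = False

    @property
    def distance_angstrom(self) -> float:
        return self.distance / BOHR_PER_ANGSTROM


def pair_energy(pd_i: Domain, pd_j: Domain, mom_i: MultipoleSet,
                mom_j: MultipoleSet, local_basis: LocalOrbitalBasis,
                ref: RestrictedReference) -> OrbitalPair:
    """Multipole-approximated MP2 pair correlation energy of two LMOs."""
    i, j = pd_i.central, pd_j.central
    is_so_i = bool(local_basis.lmo_is_somo[i])
    is_so_j = bool(local_basis.lmo_is_somo[j])
    ptype = ("SO-SO" if is_so_i and is_so_j
             else "DO-DO" if not (is_so_i or is_so_j) else "DO-SO")
    R = mom_i.center - mom_j.center
    dist = float(np.linalg.norm(R))
    fock = {"up": local_basis.lmo_fock_diag_up, "dn": local_basis.lmo_fock_diag_dn}
    if dist < R_FLOOR_BOHR:
        return OrbitalPair(i, j, ptype, dist, 0.0, F_W[ptype],
                           classification="strong", multipole_unreliable=True)
    e_ss = 0.0
    e_os = 0.0
    kernel = interaction_kernel(R)
    for si in mom_i.spins:
        for sj in mom_j.spins:
            I = multipole_interaction(mom_i.moments[si], mom_j.moments[sj], R,
                                      kernel)
            denom = (mom_i.virt_energies[si][:, None]
                     + mom_j.virt_energies[sj][None, :]
                     - fock[si][i] - fock[sj][j])
            if np.any(denom <= 0):
                raise RuntimeError(
                    f"vanishing pair-energy denominator for LMOs ({i},{j})")
            contr = -np.sum(I * I / denom)
            if si == sj:
                e_ss += contr
            else:
                e_os += contr
    return OrbitalPair(i, j, ptype, dist, e_ss + e_os, F_W[ptype],
                       e_same_spin=e_ss, e_opposite_spin=e_os)


def classify_pairs(pairs: list, eps_w: float) -> list:
    """Strong iff |pair energy| >= f_w * eps_w (SOMO-scaled threshold)."""
    for p in pairs:
        if p.multipole_unreliable or abs(p.pair_energy) >= p.f_w * eps_w:
            p.classification = "strong"
        else:
            p.classification = "distant"
    return pairs


def distant_pair_sum(pairs: list) -> float:
    return float(sum(p.pair_energy for p in pairs
                     if p.classification == "distant"))
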
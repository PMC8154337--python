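"""Restricted open-shell reference: semicanonical Fock data and QROs.

A high-spin restricted determinant (ROHF or quasi-restricted orbitals built
from an unrestricted density) defines spin-up and spin-down Fock matrices:
the spin-up one sees the DOMO+SOMO density in its exchange term, the
spin-down one only the DOMO density.  The occupied and virtual blocks of
each spin's Fock matrix are diagonalized separately ("semicanonicalization"),
keeping frozen-core orbitals from mixing with the correlated occupied ones.
The off-diagonal remainder of each Fock matrix (F^OD) is stored for the
energy contribution of single excitations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla

from .engine import MoleculeIntegrals
from .scf import SCFResult, coulomb, exchange, rohf
from .system import InputError, MolecularSystem


@dataclass
class RestrictedReference:
    system: MolecularSystem
    integrals: MoleculeIntegrals
    ao_overlap: np.ndarray
    restricted_mos: np.ndarray
    n_domo: int
    n_somo: int
    n_frozen: int
    fock_up: np.ndarray
    fock_dn: np.ndarray
    semicanonical_mos_up: np.ndarray
    semicanonical_mos_dn: np.ndarray
    orb_energies_up: np.ndarray
    orb_energies_dn: np.ndarray
    fock_od_up: np.ndarray
    fock_od_dn: np.ndarray
    scf_energy: float
    reference_kind: str
    s_squared: float = field(default=0.0)

    @property
    def n_up(self) -> int:
        return self.n_domo + self.n_somo

    @property
    def n_dn(self) -> int:
        return self.n_domo

    def occ_slices(self, spin: str):
        """(frozen, correlated-occupied, virtual) column slices for a spin."""
        nocc = self.n_up if spin == "up" else self.n_dn
        return (slice(0, self.n_frozen), slice(self.n_frozen, nocc),
                slice(nocc, None))

    def summary(self) -> dict:
        return {
            "reference_kind": self.reference_kind,
            "scf_energy": self.scf_energy,
            "n_domo": self.n_domo,
            "n_somo": self.n_somo,
            "n_frozen": self.n_frozen,
            "s_squared": self.s_squared,
        }


def _semicanonicalize(C: np.ndarray, F: np.ndarray, blocks) -> tuple:
    """Diagonalize F within each column block of C; no cross-block mixing."""
    Cs = C.copy()
    e = np.zeros(C.shape[1])
    for blk in blocks:
        Cb = C[:, blk]
        if Cb.shape[1] == 0:
            continue
        f = Cb.T @ F @ Cb
        w, U = np.linalg.eigh(f)
        # deterministic eigenvector phases
        k = np.argmax(np.abs(U), axis=0)
        sgn = np.sign(U[k, np.arange(U.shape[1])])
        sgn[sgn == 0] = 1.0
        Cs[:, blk] = Cb @ (U * sgn[None, :])
        e[blk] = w
    return Cs, e


def offdiag_fock(fock: np.ndarray, semicanonical_mos: np.ndarray,
                 orb_energies: np.ndarray, ao_overlap: np.ndarray) -> np.ndarray:
    """F^OD = F minus the AO back-transform of the diagonal MO energies."""
    if fock.shape[0] != semicanonical_mos.shape[0]:
        raise InputError("Fock / MO dimension mismatch")
    SC = ao_overlap @ semicanonical_mos
    return fock - (SC * orb_energies[None, :]) @ SC.T


def _finish_reference(system, mi, C, energy, kind, Du, Dd) -> RestrictedReference:
    """Semicanonicalize a restricted MO set and assemble the reference."""
    h, W = mi.hcore, mi.W
    nup, ndn = system.n_up, system.n_dn
    J = coulomb(W, Du + Dd)
    Fu = h + J - exchange(W, C[:, :nup])
    Fd = h + J - exchange(W, C[:, :ndn])
    nfc = system.n_frozen_core
    Cu, eu = _semicanonicalize(
        C, Fu, [slice(0, nfc), slice(nfc, nup), slice(nup, None)])
    Cd, ed = _semicanonicalize(
        C, Fd, [slice(0, nfc), slice(nfc, ndn), slice(ndn, None)])
    S = mi.S
    s = 0.5 * system.n_somo
    return RestrictedReference(
        system=system, integrals=mi, ao_overlap=S, restricted_mos=C,
        n_domo=ndn, n_somo=nup - ndn, n_frozen=nfc,
        fock_up=Fu, fock_dn=Fd,
        semicanonical_mos_up=Cu, semicanonical_mos_dn=Cd,
        orb_energies_up=eu, orb_energies_dn=ed,
        fock_od_up=offdiag_fock(Fu, Cu, eu, S),
        fock_od_dn=offdiag_fock(Fd, Cd, ed, S),
        scf_energy=energy, reference_kind=kind, s_squared=s * (s + 1.0))


def build_rohf_reference(system: MolecularSystem,
                         mi: MoleculeIntegrals | None = None,
                         scf_result: SCFResult | None = None) -> RestrictedReference:
    """ROHF (or RHF, closed shell) reference with semicanonical Fock data."""
    mi = mi or MoleculeIntegrals(system)
    res = scf_result or rohf(mi)
    return _finish_reference(system, mi, res.mo_coeff, res.energy,
                             "ROHF" if system.n_somo else "RHF",
                             res.dm_up, res.dm_dn)


def build_qro_reference(system: MolecularSystem,
                        unrestricted_density_total: np.ndarray,
                        mi: MoleculeIntegrals | None = None) -> RestrictedReference:
    """Quasi-restricted orbitals from the total unrestricted density.

    The QROs are the eigenvectors of the spin-summed density; ordered by
    occupation, the top n_domo become doubly occupied and the next n_somo
    singly occupied, producing a restricted determinant that is an exact
    S^2 eigenfunction and is then used like an ROHF reference.
    """
    mi = mi or MoleculeIntegrals(system)
    S = mi.S
    # orthonormal eigenvectors of the density operator
    w, V = np.linalg.eigh(S)
    Shalf = (V * np.sqrt(w)) @ V.T
    Sinvhalf = (V / np.sqrt(w)) @ V.T
    occ, Y = np.linalg.eigh(Shalf @ unrestricted_density_total @ Shalf)
    order = np.argsort(occ)[::-1]
    occ = occ[order]
    C = Sinvhalf @ Y[:, order]
    ndo, nso = system.n_domo, system.n_somo
    if not (occ[:ndo] > 1.5).all() or not \
            ((occ[ndo:ndo + nso] > 0.5).all() and (occ[ndo:ndo + nso] < 1.5).all() if nso else True):
        warnings.warn(
            "QRO occupation spectrum lacks a clean 2/1/0 gap structure: "
            + np.array2string(occ[:ndo + nso + 2], precision=3))
    Du = C[:, :system.n_up] @ C[:, :system.n_up].T
    Dd = C[:, :system.n_dn] @ C[:, :system.n_dn].T
    h, W = mi.hcore, mi.W
    Fu = h + coulomb(W, Du + Dd) - exchange(W, C[:, :system.n_up])
    Fd = h + coulomb(W, Du + Dd) - exchange(W, C[:, :system.n_dn])
    energy = 0.5 * (np.sum(Du * (h + Fu)) + np.sum(Dd * (h + Fd))) \
        + system.nuclear_repulsion()
    ref = _finish_reference(system, mi, C, energy, "QRO", Du, Dd)
    return ref
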
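"""Boys localization of the occupied orbitals and projected atomic orbitals.

DOMOs and SOMOs are localized separately (spin-restricted localization), so
the same spatial LMOs serve both spin channels.  The virtual space is never
localized; it is spanned redundantly by PAOs, one per AO, projected against
every orbital that is occupied in the spin-up determinant.  The spin-down
unoccupied space is the span of the PAOs plus the SOMOs (dual-role SOMOs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reference import RestrictedReference
from .system import InputError


class LocalizationError(RuntimeError):
    pass


def boys_localize(occ_coeffs: np.ndarray, ao_overlap: np.ndarray,
                  dipole_integrals: np.ndarray, conv_angle: float = 1e-8,
                  max_sweeps: int = 300):
    """Maximize the sum of squared orbital dipole centroids by Jacobi sweeps.

    Returns the localized coefficients and the per-orbital centroids (bohr).
    Deterministic: orbitals are processed in input order and each LMO's
    phase is fixed by making its largest-magnitude coefficient positive.
    """
    C = occ_coeffs.copy()
    n = C.shape[1]
    if n == 0:
        return C, np.zeros((0, 3))
    ortho = C.T @ ao_overlap @ C - np.eye(n)
    if np.abs(ortho).max() > 1e-7:
        raise InputError("orbitals passed to localization are not orthonormal")
    if n > 1:
        d = np.stack([C.T @ dipole_integrals[k] @ C for k in range(3)])
        last_angle = 0.0
        for _ in range(max_sweeps):
            max_angle = 0.0
            for i in range(n):
                for j in range(i + 1, n):
                    Ad = d[:, i, j]
                    Bd = d[:, i, i] - d[:, j, j]
                    P = 0.25 * (Bd @ Bd) - Ad @ Ad
                    Q = Ad @ Bd
                    if P * P + Q * Q < 1e-24:
                        continue
                    gamma = 0.25 * np.arctan2(Q, P)
                    # gain of the Boys functional for this 2x2 rotation
                    gain = 0.5 * (np.hypot(P, Q) - P)
                    if gain < 1e-14:
                        continue
                    max_angle = max(max_angle, abs(gamma))
                    c, s = np.cos(gamma), np.sin(gamma)
                    ci = C[:, i] * c + C[:, j] * s
                    cj = -C[:, i] * s + C[:, j] * c
                    C[:, i], C[:, j] = ci, cj
                    for k in range(3):
                        di = d[k, :, i] * c + d[k, :, j] * s
                        dj = -d[k, :, i] * s + d[k, :, j] * c
                        d[k, :, i], d[k, :, j] = di, dj
                        ri = d[k, i, :] * c + d[k, j, :] * s
                        rj = -d[k, i, :] * s + d[k, j, :] * c
                        d[k, i, :], d[k, j, :] = ri, rj
            last_angle = max_angle
            if max_angle < conv_angle:
                break
        else:
            raise LocalizationError(
                f"Boys localization not converged; last max angle {last_angle:.2e}")
    # deterministic phases
    for k in range(n):
        if C[np.argmax(np.abs(C[:, k])), k] < 0:
            C[:, k] = -C[:, k]
    centroids = np.stack(
        [np.einsum("mi,mn,ni->i", C, dipole_integrals[k], C) for k in range(3)],
        axis=1)
    return C, centroids


def boys_functional(C, dipole_integrals):
    vals = np.stack([np.einsum("mi,mn,ni->i", C, dipole_integrals[k], C)
                     for k in range(3)])
    return float(np.sum(vals ** 2))


def build_paos(all_occ_coeffs: np.ndarray, ao_overlap: np.ndarray):
    """One PAO per AO: |a_mu> = (1 - sum_occ |i><i| S)|mu>, normalized.

    ``all_occ_coeffs`` must contain everything occupied in the spin-up
    determinant (frozen core, DOMOs and SOMOs).  Returns the normalized PAO
    coefficients and the pre-normalization norms.
    """
    nao = ao_overlap.shape[0]
    C = all_occ_coeffs
    if C.shape[1]:
        ortho = C.T @ ao_overlap @ C - np.eye(C.shape[1])
        if np.abs(ortho).max() > 1e-7:
            raise InputError("occupied space for PAO construction not orthonormal")
    P = np.eye(nao) - C @ (C.T @ ao_overlap)
    norms = np.sqrt(np.abs(np.einsum("mi,mn,ni->i", P, ao_overlap, P)))
    # an AO lying entirely inside the occupied space leaves a null PAO;
    # keep it as an exact zero column instead of amplifying noise
    safe = norms > 1e-10
    out = np.where(safe[None, :], P / np.where(safe, norms, 1.0)[None, :], 0.0)
    return out, norms


@dataclass
class LocalOrbitalBasis:
    """Localized correlated occupied orbitals and the PAO set."""

    lmo_coeffs: np.ndarray      # correlated DOMOs first, then SOMOs
    lmo_centers: np.ndarray     # Boys centroids, bohr
    lmo_is_somo: np.ndarray     # bool per LMO
    pao_coeffs: np.ndarray
    pao_norms: np.ndarray
    lmo_fock_diag_up: np.ndarray
    lmo_fock_diag_dn: np.ndarray

    @property
    def n_lmo(self) -> int:
        return self.lmo_coeffs.shape[1]

    def domo_indices(self) -> np.ndarray:
        return np.nonzero(~self.lmo_is_somo)[0]


def build_local_basis(ref: RestrictedReference) -> LocalOrbitalBasis:
    """Localize correlated DOMOs and SOMOs separately and build PAOs."""
    mi = ref.integrals
    S, dip = mi.S, mi.dipole
    C = ref.restricted_mos
    nfc, ndo, nup = ref.n_frozen, ref.n_dn, ref.n_up
    Cdo, cen_do = boys_localize(C[:, nfc:ndo], S, dip)
    if ref.n_somo:
        Cso, cen_so = boys_localize(C[:, ndo:nup], S, dip)
        lmo = np.hstack([Cdo, Cso])
        centers = np.vstack([cen_do, cen_so])
    else:
        lmo = Cdo
        centers = cen_do
    is_somo = np.zeros(lmo.shape[1], dtype=bool)
    is_somo[Cdo.shape[1]:] = True
    pao, norms = build_paos(C[:, :nup], S)
    fdu = np.einsum("mi,mn,ni->i", lmo, ref.fock_up, lmo)
    fdd = np.einsum("mi,mn,ni->i", lmo, ref.fock_dn, lmo)
    return LocalOrbitalBasis(lmo, centers, is_somo, pao, norms, fdu, fdd)
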
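"""Brute-force canonical MP2 references for validation.

Dense, approximation-free evaluation of the unrestricted-formalism MP2
correlation energy on semicanonical restricted open-shell orbitals: two
singles terms (nonzero because the ROHF Fock matrices have occupied-virtual
blocks in the semicanonical bases), two same-spin doubles terms and one
opposite-spin doubles term.  Shares only the AO integrals and the reference
builder with the local path, so agreement between the two is evidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .localization import LocalOrbitalBasis
from .reference import RestrictedReference


@dataclass
class CanonicalEnergies:
    singles: float
    same_spin: float
    opposite_spin: float

    @property
    def doubles(self) -> float:
        return self.same_spin + self.opposite_spin

    @property
    def total(self) -> float:
        return self.singles + self.same_spin + self.opposite_spin


def _spin_data(ref: RestrictedReference, spin: str):
    """(B_occ-virt fitting tensor, f_ov, occ energies, virt energies)."""
    mi = ref.integrals
    W = mi.W
    if spin == "up":
        C, e, F = ref.semicanonical_mos_up, ref.orb_energies_up, ref.fock_up
        nocc = ref.n_up
    else:
        C, e, F = ref.semicanonical_mos_dn, ref.orb_energies_dn, ref.fock_dn
        nocc = ref.n_dn
    nfc = ref.n_frozen
    Co, Cv = C[:, nfc:nocc], C[:, nocc:]
    B = np.einsum("mnP,mi,na->iaP", W, Co, Cv, optimize=True)
    fov = Co.T @ F @ Cv
    return B, fov, e[nfc:nocc], e[nocc:]


def _mp2_from_spin_data(up, dn) -> CanonicalEnergies:
    singles = 0.0
    same = 0.0
    for B, fov, eo, ev in (up, dn):
        if len(eo) == 0 or len(ev) == 0:
            continue
        singles += float(np.sum(fov ** 2 / (eo[:, None] - ev[None, :])))
        K = np.einsum("iaP,jbP->iajb", B, B, optimize=True)
        A = K - K.transpose(0, 3, 2, 1)
        D = (ev[None, :, None, None] + ev[None, None, None, :]
             - eo[:, None, None, None] - eo[None, None, :, None])
        same += float(-0.25 * np.sum(A * A / D))
    (Bu, _, eou, evu), (Bd, _, eod, evd) = up, dn
    if len(eou) and len(eod):
        K = np.einsum("iaP,JBP->iaJB", Bu, Bd, optimize=True)
        D = (evu[None, :, None, None] + evd[None, None, None, :]
             - eou[:, None, None, None] - eod[None, None, :, None])
        opp = float(-np.sum(K * K / D))
    else:
        opp = 0.0
    return CanonicalEnergies(singles, same, opp)


def canonical_romp2(ref: RestrictedReference) -> CanonicalEnergies:
    """Canonical semicanonical-orbital RO-MP2 (density-fitted ERIs)."""
    return _mp2_from_spin_data(_spin_data(ref, "up"), _spin_data(ref, "dn"))


def reference_pair_energies(ref: RestrictedReference,
                            local_basis: LocalOrbitalBasis) -> np.ndarray:
    """Canonical MP2 doubles energy re-bucketed by spatial LMO pair.

    Returns a symmetric (n_lmo, n_lmo) matrix whose upper triangle (incl.
    diagonal) sums exactly to the canonical doubles energy.
    """
    S = ref.ao_overlap
    n_lmo = local_basis.n_lmo
    do_idx = local_basis.domo_indices()
    up = _spin_data(ref, "up")
    dn = _spin_data(ref, "dn")
    # expansion of semicanonical occupieds in the LMO basis
    nfc = ref.n_frozen
    U_up = local_basis.lmo_coeffs.T @ S @ ref.semicanonical_mos_up[:, nfc:ref.n_up]
    U_dn = (local_basis.lmo_coeffs[:, do_idx].T @ S
            @ ref.semicanonical_mos_dn[:, nfc:ref.n_dn])
    pair = np.zeros((n_lmo, n_lmo))

    def add_same(U, data, lmos):
        B, _, eo, ev = data
        if len(eo) == 0 or len(ev) == 0:
            return
        K = np.einsum("iaP,jbP->iajb", B, B, optimize=True)
        A = K - K.transpose(0, 3, 2, 1)
        D = (ev[None, :, None, None] + ev[None, None, None, :]
             - eo[:, None, None, None] - eo[None, None, :, None])
        A_loc = np.einsum("pi,qj,iajb->pqab", U, U, A, optimize=True)
        T_loc = np.einsum("pi,qj,iajb->pqab", U, U, A / D, optimize=True)
        Al = np.einsum("pqab,pqab->pq", A_loc, T_loc, optimize=True)
        for p, lp in enumerate(lmos):
            for q, lq in enumerate(lmos):
                pair[lp, lq] += -0.25 * Al[p, q]

    add_same(U_up, up, list(range(n_lmo)))
    add_same(U_dn, dn, list(do_idx))
    Bu, _, eou, evu = up
    Bd, _, eod, evd = dn
    if len(eou) and len(eod):
        K = np.einsum("iaP,JBP->iaJB", Bu, Bd, optimize=True)
        D = (evu[None, :, None, None] + evd[None, None, None, :]
             - eou[:, None, None, None] - eod[None, None, :, None])
        K_loc = np.einsum("pi,qJ,iaJB->pqaB", U_up, U_dn, K, optimize=True)
        T_loc = np.einsum("pi,qJ,iaJB->pqaB", U_up, U_dn, K / D, optimize=True)
        Kl = np.einsum("pqaB,pqaB->pq", K_loc, T_loc, optimize=True)
        for p in range(n_lmo):
            for q, lq in enumerate(do_idx):
                pair[p, lq] += -Kl[p, q]
    # fold the ordered contributions into an unordered symmetric matrix
    sym = np.zeros_like(pair)
    for p in range(n_lmo):
        sym[p, p] = pair[p, p]
        for q in range(p + 1, n_lmo):
            sym[p, q] = sym[q, p] = pair[p, q] + pair[q, p]
    return sym
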
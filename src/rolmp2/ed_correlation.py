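"""Per-LMO correlation energy contributions evaluated in extended domains.

For each central LMO (CMO) the doubles amplitudes carry one occupied index
in the restricted localized basis and the remaining indices in the ED's
per-spin pseudocanonical bases; energy denominators are factorized
(Cholesky/Laplace) or applied explicitly.  Six terms contribute for a
doubly occupied CMO: spin-up/spin-down singles (built exclusively from the
off-diagonal Fock matrices F^OD), up-up and down-down antisymmetrized
doubles, and two opposite-spin doubles terms that cannot be merged because
the localized occupied index breaks the permutational symmetry.  A singly
occupied CMO keeps only the spin-up half.

SOMO-free EDs can optionally be evaluated with the closed-shell formulas
after canonicalizing with the spin-averaged Fock matrix (long-range
spin-polarization approximation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .denominators import DenominatorFactorization
from .domains import Domain, _pseudocanonicalize
from .engine import MoleculeIntegrals, metric_decomposition
from .reference import RestrictedReference


@dataclass
class FittedIntegrals:
    """Per-spin three-index tensors J[a, i, P] over ED orbitals.

    The occupied index is pseudocanonical; together with the LMO ->
    pseudocanonical rotations of the domain the localized-index integrals
    are recovered by contraction.
    """

    J_up: np.ndarray
    J_dn: np.ndarray
    naux: int


def transform_integrals(ed: Domain, mi: MoleculeIntegrals) -> FittedIntegrals:
    """DF transformation restricted to the ED's AO and auxiliary lists.

    Scheme: AO -> restricted LMO on the first index (shared by both spins),
    AO -> per-spin virtual on the second, metric decomposition on the
    auxiliary index, and finally LMO -> per-spin pseudocanonical occupied.
    """
    idx, aux = ed.ao_idx, ed.aux_idx
    Vs = mi.V2[np.ix_(aux, aux)]
    M = metric_decomposition(Vs)
    T3 = mi.T3[np.ix_(idx, idx, aux)]
    # first half-transformation: restricted LMO index (both spins share it)
    I1 = np.tensordot(ed.occ_lmo, T3, axes=([0], [0]))     # (i, n, P)
    out = {}
    for spin in ("up", "dn"):
        if spin == "dn" and ed.spin_symmetric:
            out["dn"] = out["up"]
            break
        V = ed.virt_up if spin == "up" else ed.virt_dn
        U = ed.U_up if spin == "up" else ed.U_dn
        occ_cols = (list(range(len(ed.members))) if spin == "up"
                    else [ed.members.index(m) for m in ed.dn_members])
        J = np.tensordot(V, I1[occ_cols], axes=([0], [1]))  # (a, i, P)
        J = np.tensordot(J, M, axes=([2], [0]))             # auxiliary metric
        out[spin] = np.tensordot(J, U, axes=([1], [0])).transpose(0, 2, 1)
    return FittedIntegrals(out["up"], out["dn"], M.shape[1])


@dataclass
class PerLMORecord:
    lmo: int
    is_somo: bool
    singles_up: float = 0.0
    singles_dn: float = 0.0
    ss_up: float = 0.0
    ss_dn: float = 0.0
    os_up: float = 0.0
    os_dn: float = 0.0
    treated_closed_shell: bool = False

    @property
    def singles(self) -> float:
        return self.singles_up + self.singles_dn

    @property
    def same_spin(self) -> float:
        return self.ss_up + self.ss_dn

    @property
    def opposite_spin(self) -> float:
        return self.os_up + self.os_dn

    @property
    def total(self) -> float:
        return self.singles + self.same_spin + self.opposite_spin


def _singles_term(ucol, g, eo, ev):
    """sum_a f(i',a) t(i',a) with both factors built from F^OD."""
    if g.size == 0:
        return 0.0
    gp = ucol @ g
    tp = ucol @ (g / (eo[:, None] - ev[None, :]))
    return float(gp @ tp)


def _pair_contract(X_a, Y_bj):
    """(a,P) x (b,j,P) -> (a,b,j) through one matrix product."""
    nb, nj, nP = Y_bj.shape
    return (X_a @ Y_bj.reshape(nb * nj, nP).T).reshape(-1, nb, nj)


def _doubles_same_spin(Jc, J, tCc, tJ):
    """-(1/4) sum (A - AX)(tC - tX) for one spin channel of the CMO."""
    A = _pair_contract(Jc, J)
    AX = A.transpose(1, 0, 2)    # (a j | b i') by Mulliken symmetry
    tC = sum(_pair_contract(tCc[w], tJ[w]) for w in range(tJ.shape[0]))
    tX = tC.transpose(1, 0, 2)
    return float(-0.25 * np.sum((A - AX) * (tC - tX)))


def _doubles_opposite(Jc_1, J_2, tCc_1, tJ_2):
    """-(1/2) sum A t for the mixed-spin channel with the CMO in spin 1."""
    A = _pair_contract(Jc_1, J_2)
    tC = sum(_pair_contract(tCc_1[w], tJ_2[w]) for w in range(tJ_2.shape[0]))
    return float(-0.5 * np.sum(A * tC))


def _fod_blocks(ed: Domain, ref: RestrictedReference, spin: str,
                occ, virt):
    F = ref.fock_od_up if spin == "up" else ref.fock_od_dn
    F_dd = F[np.ix_(ed.ao_idx, ed.ao_idx)]
    return occ.T @ F_dd @ virt


def ed_energy_contribution(ed: Domain, fit: FittedIntegrals,
                           denom: DenominatorFactorization,
                           ref: RestrictedReference) -> PerLMORecord:
    """Correlation energy contribution of the ED's central LMO."""
    is_somo = ed.central in ed.somo_members
    if ed.contains_somo and ed.virt_dn.shape[1] < len(ed.somo_members):
        raise RuntimeError(
            f"ED of LMO {ed.central}: spin-down virtual space cannot hold "
            "the appended SOMOs")
    rec = PerLMORecord(ed.central, is_somo)
    c_up = 0  # CMO is the first member by construction
    ucol_up = ed.U_up[c_up]
    spins = {
        "up": (fit.J_up, ed.U_up, ed.occ_e_up, ed.virt_e_up, ed.occ_up,
               ed.virt_up),
        "dn": (fit.J_dn, ed.U_dn, ed.occ_e_dn, ed.virt_e_dn, ed.occ_dn,
               ed.virt_dn),
    }

    def barred(spin):
        J, _, eo, ev, _, _ = spins[spin]
        if denom.method == "exact":
            return None
        G = denom.weights(np.subtract.outer(ev, eo))  # (w, a, i)
        return G[:, :, :, None] * J[None]

    tJ_up = barred("up")
    tJ_dn = barred("dn")

    def cmo_col(J, ucol):
        return np.tensordot(J, ucol, axes=([1], [0]))

    def exact_pair_ss(J, ucol, eo, ev):
        K = np.einsum("aiP,bjP->aibj", J, J, optimize=True)
        A4 = K - K.transpose(2, 1, 0, 3)  # swap a<->b on the bra pairing
        D = (ev[:, None, None, None] + ev[None, None, :, None]
             - eo[None, :, None, None] - eo[None, None, None, :])
        T = np.einsum("aibj,i->abj", A4 / D, ucol, optimize=True)
        A = np.einsum("aibj,i->abj", A4, ucol, optimize=True)
        return float(-0.25 * np.sum(A * T))

    def exact_pair_os(J1, ucol, eo1, ev1, J2, eo2, ev2):
        K = np.einsum("aiP,BJP->aiBJ", J1, J2, optimize=True)
        D = (ev1[:, None, None, None] + ev2[None, None, :, None]
             - eo1[None, :, None, None] - eo2[None, None, None, :])
        A = np.einsum("aiBJ,i->aBJ", K, ucol, optimize=True)
        T = np.einsum("aiBJ,i->aBJ", K / D, ucol, optimize=True)
        return float(-0.5 * np.sum(A * T))

    # spin-up half (always present)
    J_up, U_up, eo_up, ev_up, occ_up, virt_up = spins["up"]
    g_up = _fod_blocks(ed, ref, "up", occ_up, virt_up)
    rec.singles_up = _singles_term(ucol_up, g_up, eo_up, ev_up)
    if denom.method == "exact":
        rec.ss_up = exact_pair_ss(J_up, ucol_up, eo_up, ev_up)
    else:
        Jc = cmo_col(J_up, ucol_up)
        tCc = np.tensordot(tJ_up, ucol_up, axes=([2], [0]))
        rec.ss_up = _doubles_same_spin(Jc, J_up, tCc, tJ_up)
    J_dn, U_dn, eo_dn, ev_dn, occ_dn, virt_dn = spins["dn"]
    if len(ed.dn_members) and J_dn.size:
        if denom.method == "exact":
            rec.os_up = exact_pair_os(J_up, ucol_up, eo_up, ev_up,
                                      J_dn, eo_dn, ev_dn)
        else:
            tCc = np.tensordot(tJ_up, ucol_up, axes=([2], [0]))
            rec.os_up = _doubles_opposite(cmo_col(J_up, ucol_up), J_dn,
                                          tCc, tJ_dn)
    # spin-down half (absent for a SOMO CMO)
    if not is_somo:
        c_dn = ed.dn_members.index(ed.central)
        ucol_dn = ed.U_dn[c_dn]
        g_dn = _fod_blocks(ed, ref, "dn", occ_dn, virt_dn)
        rec.singles_dn = _singles_term(ucol_dn, g_dn, eo_dn, ev_dn)
        if denom.method == "exact":
            rec.ss_dn = exact_pair_ss(J_dn, ucol_dn, eo_dn, ev_dn)
            rec.os_dn = exact_pair_os(J_dn, ucol_dn, eo_dn, ev_dn,
                                      J_up, eo_up, ev_up)
        else:
            Jc = cmo_col(J_dn, ucol_dn)
            tCc = np.tensordot(tJ_dn, ucol_dn, axes=([2], [0]))
            rec.ss_dn = _doubles_same_spin(Jc, J_dn, tCc, tJ_dn)
            rec.os_dn = _doubles_opposite(Jc, J_up, tCc, tJ_up)
    return rec


def closed_shell_contribution(ed: Domain, mi: MoleculeIntegrals,
                              denom_factory,
                              ref: RestrictedReference) -> PerLMORecord:
    """Closed-shell-formula contribution for a SOMO-free ED.

    The ED orbitals are canonicalized with the spin-averaged Fock matrix,
    so a single restricted orbital set serves both spins; the doubles use
    the closed-shell expression and the singles keep the spin-resolved
    F^OD blocks evaluated on the averaged orbitals.
    """
    if ed.contains_somo:
        raise RuntimeError("closed-shell path called on a SOMO-containing ED")
    idx = ed.ao_idx
    Favg = 0.5 * (ref.fock_up + ref.fock_dn)[np.ix_(idx, idx)]
    occ, eo, U = _pseudocanonicalize(ed.occ_lmo, Favg)
    virt, ev, _ = _pseudocanonicalize(ed.virt_orth_up, Favg)
    denom = denom_factory([eo], [ev])
    Vs = mi.V2[np.ix_(ed.aux_idx, ed.aux_idx)]
    M = metric_decomposition(Vs)
    T3 = mi.T3[np.ix_(idx, idx, ed.aux_idx)]
    I1 = np.tensordot(ed.occ_lmo, T3, axes=([0], [0]))      # (i, n, P)
    J = np.tensordot(virt, I1, axes=([0], [1]))             # (a, i, P)
    J = np.tensordot(J, M, axes=([2], [0]))
    J = np.tensordot(J, U, axes=([1], [0])).transpose(0, 2, 1)
    ucol = U[0]
    rec = PerLMORecord(ed.central, False, treated_closed_shell=True)
    Jc = np.tensordot(J, ucol, axes=([1], [0]))
    A = _pair_contract(Jc, J)
    AX = A.transpose(1, 0, 2)
    if denom.method == "exact":
        K = np.einsum("aiP,bjP->aibj", J, J, optimize=True)
        D = (ev[:, None, None, None] + ev[None, None, :, None]
             - eo[None, :, None, None] - eo[None, None, None, :])
        tC = np.einsum("aibj,i->abj", K / D, ucol, optimize=True)
        tX = np.einsum("ajbi,i->abj", K / D, ucol, optimize=True)
    else:
        G = denom.weights(np.subtract.outer(ev, eo))
        tJ = G[:, :, :, None] * J[None]
        tCc = np.tensordot(tJ, ucol, axes=([2], [0]))
        tC = sum(_pair_contract(tCc[w], tJ[w]) for w in range(tJ.shape[0]))
        tX = tC.transpose(1, 0, 2)
    e_AtC = float(np.sum(A * tC))
    e_AtX = float(np.sum(A * tX))
    # bookkeeping matching the open-shell split: per spin,
    # same-spin = -(AtC - AtX)/2, opposite-spin = -AtC/2
    rec.ss_up = rec.ss_dn = -0.5 * (e_AtC - e_AtX)
    rec.os_up = rec.os_dn = -0.5 * e_AtC
    g_up = occ.T @ ref.fock_od_up[np.ix_(idx, idx)] @ virt
    g_dn = occ.T @ ref.fock_od_dn[np.ix_(idx, idx)] @ virt
    rec.singles_up = _singles_term(ucol, g_up, eo, ev)
    rec.singles_dn = _singles_term(ucol, g_dn, eo, ev)
    return rec


@dataclass
class CorrelationResult:
    records: list
    distant_pair_sum: float
    distant_same_spin: float = 0.0
    distant_opposite_spin: float = 0.0
    scs_coefficients: tuple = (6.0 / 5.0, 1.0 / 3.0)
    include_singles: bool = True
    metadata: dict = field(default_factory=dict)

    @property
    def singles(self) -> float:
        return sum(r.singles for r in self.records) if self.include_singles else 0.0

    @property
    def same_spin(self) -> float:
        return sum(r.same_spin for r in self.records) + self.distant_same_spin

    @property
    def opposite_spin(self) -> float:
        return (sum(r.opposite_spin for r in self.records)
                + self.distant_opposite_spin)

    @property
    def total(self) -> float:
        return self.singles + self.same_spin + self.opposite_spin

    @property
    def scs_total(self) -> float:
        cos, css = self.scs_coefficients
        return cos * self.opposite_spin + css * self.same_spin + self.singles

    @property
    def n_closed_shell_eds(self) -> int:
        return sum(r.treated_closed_shell for r in self.records)


def assemble_total(records, pairs, scs_coefficients=(6.0 / 5.0, 1.0 / 3.0),
                   include_singles=True, metadata=None) -> CorrelationResult:
    """Combine per-LMO records with the distant-pair estimate."""
    seen = [r.lmo for r in records]
    if len(set(seen)) != len(seen):
        raise RuntimeError("duplicate per-LMO records")
    distant = [p for p in pairs if p.classification == "distant"]
    return CorrelationResult(
        records=sorted(records, key=lambda r: r.lmo),
        distant_pair_sum=float(sum(p.pair_energy for p in distant)),
        distant_same_spin=float(sum(p.e_same_spin for p in distant)),
        distant_opposite_spin=float(sum(p.e_opposite_spin for p in distant)),
        scs_coefficients=scs_coefficients,
        include_singles=include_singles,
        metadata=metadata or {})
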
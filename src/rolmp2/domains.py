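"""Boughton-Pulay atom lists, primary domains and extended domains.

A Boughton-Pulay (BP) list is the shortest greedy prefix of atoms (ranked by
Mulliken population) whose AOs reproduce an orbital with completeness >= T,
where completeness is the overlap of the projected orbital with the
original; the truncation error is then controlled by 1 - T.

Primary domains (PDs) are compact per-LMO spaces used only for the multipole
pair-energy estimates.  Extended domains (EDs) host the main correlation
energy contribution of each LMO: occupied space = central LMO + strong
pairs, virtual space = PAOs of the PAO-center domain (PCD) orthogonalized
within the ED, both pseudocanonicalized separately per spin.  SOMOs that
belong to a domain are appended to its spin-down virtual set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla

from .localization import LocalOrbitalBasis
from .reference import RestrictedReference


class DomainError(RuntimeError):
    pass


@dataclass
class BPAtomList:
    orbital: int
    atoms: list
    completeness: float


def bp_atom_list(orbital: np.ndarray, T: float, S: np.ndarray,
                 ao_atom: np.ndarray, orbital_id: int = -1) -> BPAtomList:
    """Greedy Mulliken-ranked atom list reaching completeness >= T."""
    if not 0.0 < T < 1.0:
        raise ValueError("completeness threshold must lie in (0, 1)")
    Sc = S @ orbital
    natm = int(ao_atom.max()) + 1
    pops = np.zeros(natm)
    np.add.at(pops, ao_atom, orbital * Sc)
    # rank by absolute population: small negative Mulliken charges still
    # signal genuine participation and must precede zero-weight atoms
    order = np.argsort(-np.abs(pops), kind="stable")
    chosen: list[int] = []
    comp = 0.0
    norm = orbital @ Sc
    for atom in order:
        chosen.append(int(atom))
        idx = np.nonzero(np.isin(ao_atom, chosen))[0]
        x = _project_onto(S[np.ix_(idx, idx)], Sc[idx])
        comp = float(x @ Sc[idx]) / norm
        if comp >= T:
            return BPAtomList(orbital_id, sorted(chosen), comp)
    warnings.warn(f"BP threshold {T} unreachable for orbital {orbital_id}; "
                  f"using all atoms (completeness {comp:.12f})")
    return BPAtomList(orbital_id, sorted(chosen), comp)


class BPCache:
    """Memoized BP atom lists (a PAO's or LMO's list is LMO-independent)."""

    def __init__(self, S, ao_atom):
        self.S = S
        self.ao_atom = ao_atom
        self._store: dict = {}

    def get(self, kind: str, oid: int, orbital, T: float) -> BPAtomList:
        key = (kind, oid, T)
        if key not in self._store:
            self._store[key] = bp_atom_list(orbital, T, self.S, self.ao_atom,
                                            oid)
        return self._store[key]


def _project_onto(S_dd, rhs):
    try:
        return np.linalg.solve(S_dd, rhs)
    except np.linalg.LinAlgError:
        return np.linalg.lstsq(S_dd, rhs, rcond=None)[0]


def _lowdin_eliminate(C, S_dd, cutoff):
    """Symmetric orthonormalization, dropping near-null combinations."""
    if C.shape[1] == 0:
        return C
    ov = C.T @ S_dd @ C
    w, U = np.linalg.eigh(ov)
    keep = w > cutoff
    return C @ (U[:, keep] / np.sqrt(w[keep]))


def _gram_schmidt_against(C, occ, S_dd):
    if occ.shape[1] == 0:
        return C
    return C - occ @ (occ.T @ S_dd @ C)


def _sc_columns(ref, local_basis, spin, somo_members):
    """Memoized S @ (guard orbitals) for the virtual-space guard."""
    key = ("sc_guard", spin, tuple(somo_members))
    cache = ref.integrals._cache
    base_key = ("sc_base", spin)
    if base_key not in cache:
        C = ref.restricted_mos
        n = ref.n_up if spin == "up" else ref.n_dn
        cache[base_key] = ref.ao_overlap @ C[:, :n]
    if spin == "up":
        return cache[base_key]
    if key not in cache:
        all_somos = np.nonzero(local_basis.lmo_is_somo)[0]
        excl = [k for k in all_somos if k not in somo_members]
        if "sc_lmo" not in cache:
            cache["sc_lmo"] = ref.ao_overlap @ local_basis.lmo_coeffs
        parts = [cache[base_key]] + [cache["sc_lmo"][:, [k]] for k in excl]
        cache[key] = np.column_stack(parts) if len(parts) > 1 else parts[0]
    return cache[key]


def _virtual_space(cols, occ_span, sc_guard, S_dd, idx, lindep):
    """Orthogonalize candidate virtuals within a truncated AO basis.

    ``occ_span``: the domain's own (orthonormal) occupied columns.
    ``sc_guard``: overlap-contracted (S @ C) full-basis orbitals that must
    not leak into the virtual space (all orbitals occupied in the relevant
    spin, plus SOMOs excluded from this spin's virtual set); only those
    with non-negligible weight inside the domain (projected norm^2 > 0.02)
    are used, so the guard is local.  Without the guard, truncated PAOs of
    boundary atoms can reconstruct occupied-like directions with
    occupied-range energies.  Gram-Schmidt against occupied + guard, then
    symmetric orthonormalization with elimination of near-null combinations.
    """
    if sc_guard.shape[1]:
        X = _project_onto(S_dd, sc_guard[idx, :])
        n2 = np.sum(X * (S_dd @ X), axis=0)
        X = X[:, n2 > 0.02]
        if occ_span.shape[1]:
            X = X - occ_span @ (occ_span.T @ S_dd @ X)
        # keep only residuals that represent occupied orbitals genuinely
        # absent from occ_span; the small truncation tails of the domain's
        # own occupied set must not enter (normalizing them would project
        # out genuine virtual dimensions)
        X = _lowdin_eliminate(X, S_dd, 0.02)
        guard = np.hstack([occ_span, X]) if occ_span.shape[1] else X
    else:
        guard = occ_span
    V = _gram_schmidt_against(cols, guard, S_dd)
    return _lowdin_eliminate(V, S_dd, lindep)


def _fix_phases(U):
    """Deterministic eigenvector signs: largest-magnitude entry positive."""
    k = np.argmax(np.abs(U), axis=0)
    sgn = np.sign(U[k, np.arange(U.shape[1])])
    sgn[sgn == 0] = 1.0
    return U * sgn[None, :]


def _pseudocanonicalize(C, F_dd):
    """Diagonalize F in the span of orthonormal columns C."""
    if C.shape[1] == 0:
        return C, np.zeros(0), np.zeros((0, 0))
    f = C.T @ F_dd @ C
    w, U = np.linalg.eigh(f)
    U = _fix_phases(U)
    return C @ U, w, U


@dataclass
class Domain:
    kind: str                      # 'primary' | 'extended'
    central: int                   # LMO id
    members: list                  # LMO ids in the domain (ED: CMO + strong)
    atoms: list
    ao_idx: np.ndarray
    contains_somo: bool
    somo_members: list
    # orbitals over the domain AO basis
    occ_lmo: np.ndarray            # reorthogonalized LMO columns (ED)
    occ_up: np.ndarray = None      # pseudocanonical occupied, spin-up
    occ_dn: np.ndarray = None
    U_up: np.ndarray = None        # LMO -> pseudocanonical rotation
    U_dn: np.ndarray = None
    occ_e_up: np.ndarray = None
    occ_e_dn: np.ndarray = None
    virt_up: np.ndarray = None
    virt_dn: np.ndarray = None
    virt_e_up: np.ndarray = None
    virt_e_dn: np.ndarray = None
    # ED extras
    aux_idx: np.ndarray = None
    pcd_atoms: list = None
    # orthonormal (pre-canonical) spans, for the spin-averaged closed-shell path
    virt_orth_up: np.ndarray = None
    virt_orth_dn: np.ndarray = None
    dn_members: list = field(default_factory=list)
    spin_symmetric: bool = False   # closed-shell reference: dn mirrors up

    @property
    def n_ao(self) -> int:
        return len(self.ao_idx)


def build_primary_domain(lmo_id: int, local_basis: LocalOrbitalBasis,
                         ref: RestrictedReference, T_PDo=0.999, T_PDv=0.98,
                         lindep=1e-6, bp_cache: BPCache | None = None) -> Domain:
    """Compact domain of one LMO for the multipole pair-energy estimate."""
    mi = ref.integrals
    S, ao_atom = mi.S, mi.basis.ao_atom
    cache = bp_cache or BPCache(S, ao_atom)
    lmo = local_basis.lmo_coeffs[:, lmo_id]
    bp_lmo = cache.get("lmo", lmo_id, lmo, T_PDo)
    atom_set = set(bp_lmo.atoms)
    # PAOs derived from AOs on the atoms of the LMO's BP list (null PAOs
    # of AOs absorbed completely by the occupied space are skipped)
    pao_sel = [p for p in mi.basis.ao_indices_of_atoms(bp_lmo.atoms)
               if local_basis.pao_norms[p] > 1e-10]
    for p in pao_sel:
        bp = cache.get("pao", int(p), local_basis.pao_coeffs[:, p], T_PDv)
        atom_set.update(bp.atoms)
    # SOMOs whose virtual-threshold BP list touches the LMO's list are
    # appended to the spin-down virtual set of the PD
    somo_members = []
    for k in np.nonzero(local_basis.lmo_is_somo)[0]:
        bp_s = cache.get("lmo", int(k), local_basis.lmo_coeffs[:, k], T_PDv)
        if set(bp_s.atoms) & set(bp_lmo.atoms):
            somo_members.append(int(k))
            atom_set.update(bp_s.atoms)
    atoms = sorted(atom_set)
    idx = mi.basis.ao_indices_of_atoms(atoms)
    S_dd = S[np.ix_(idx, idx)]
    # project the central LMO and normalize
    c_lmo = _project_onto(S_dd, (S @ lmo)[idx])
    c_lmo = c_lmo / np.sqrt(c_lmo @ S_dd @ c_lmo)
    occ = c_lmo[:, None]
    # project PAOs; spin-down additionally carries the touching SOMOs
    paos = np.stack([_project_onto(S_dd, (S @ local_basis.pao_coeffs[:, p])[idx])
                     for p in pao_sel], axis=1)
    virt = {}
    energies = {}
    spin_symmetric = ref.n_somo == 0
    for spin, F in (("up", ref.fock_up), ("dn", ref.fock_dn)):
        if spin == "dn" and spin_symmetric:
            virt["dn"], energies["dn"] = virt["up"], energies["up"]
            break
        cols = paos
        if spin == "dn" and somo_members:
            extra = np.stack(
                [_project_onto(S_dd, (S @ local_basis.lmo_coeffs[:, k])[idx])
                 for k in somo_members], axis=1)
            cols = np.hstack([paos, extra])
        sc_guard = _sc_columns(ref, local_basis, spin, somo_members)
        V = _virtual_space(cols, occ, sc_guard, S_dd, idx, lindep)
        if V.shape[1] == 0:
            raise DomainError(f"empty virtual space in the PD of LMO {lmo_id}")
        V, e, _ = _pseudocanonicalize(V, F[np.ix_(idx, idx)])
        virt[spin], energies[spin] = V, e
    return Domain(
        kind="primary", central=lmo_id, members=[lmo_id], atoms=atoms,
        ao_idx=idx, contains_somo=bool(somo_members) or
        bool(local_basis.lmo_is_somo[lmo_id]),
        somo_members=somo_members, occ_lmo=occ,
        virt_up=virt["up"], virt_dn=virt["dn"],
        virt_e_up=energies["up"], virt_e_dn=energies["dn"],
        spin_symmetric=spin_symmetric)


def build_extended_domain(cmo_id: int, strong_pair_ids, local_basis,
                          ref: RestrictedReference, mi_aux_atom=None,
                          T_EDo=0.9999, T_o=0.985, lindep=1e-6,
                          bp_cache: BPCache | None = None) -> Domain:
    """Extended domain of one central LMO (CMO) and its strong pairs."""
    mi = ref.integrals
    S, ao_atom = mi.S, mi.basis.ao_atom
    cache = bp_cache or BPCache(S, ao_atom)
    members = [cmo_id] + [int(j) for j in strong_pair_ids if j != cmo_id]
    bp_tight = {m: cache.get("lmo", m, local_basis.lmo_coeffs[:, m], T_EDo)
                for m in members}
    atoms = sorted(set().union(*(set(b.atoms) for b in bp_tight.values())))
    idx = mi.basis.ao_indices_of_atoms(atoms)
    S_dd = S[np.ix_(idx, idx)]
    pos = {a: k for k, a in enumerate(idx)}
    # each LMO truncated to its own BP list, then the set is reorthogonalized
    occ_cols = []
    for m in members:
        sub = mi.basis.ao_indices_of_atoms(bp_tight[m].atoms)
        c_sub = _project_onto(S[np.ix_(sub, sub)],
                              (S @ local_basis.lmo_coeffs[:, m])[sub])
        col = np.zeros(len(idx))
        col[[pos[a] for a in sub]] = c_sub
        occ_cols.append(col)
    occ_raw = np.stack(occ_cols, axis=1)
    ov = occ_raw.T @ S_dd @ occ_raw
    w, U = np.linalg.eigh(ov)
    if w.min() < 1e-8:
        raise DomainError(f"near-dependent truncated LMOs in ED of {cmo_id}")
    occ_lmo = occ_raw @ (U / np.sqrt(w)) @ U.T  # symmetric: stays LMO-like
    somo_members = [m for m in members if local_basis.lmo_is_somo[m]]
    dn_members = [m for m in members if not local_basis.lmo_is_somo[m]]
    # PAO center domain and its PAOs, projected onto the whole ED AO basis
    pcd = sorted(set().union(*(set(cache.get(
        "lmo", m, local_basis.lmo_coeffs[:, m], T_o).atoms)
        for m in members)))
    pao_sel = [p for p in mi.basis.ao_indices_of_atoms(pcd)
               if local_basis.pao_norms[p] > 1e-10]
    paos = np.stack([_project_onto(S_dd, (S @ local_basis.pao_coeffs[:, p])[idx])
                     for p in pao_sel], axis=1)
    occ_up_span = occ_lmo
    occ_dn_span = occ_lmo[:, [members.index(m) for m in dn_members]]
    out = {}
    spin_symmetric = ref.n_somo == 0
    for spin, F, occ_span in (("up", ref.fock_up, occ_up_span),
                              ("dn", ref.fock_dn, occ_dn_span)):
        if spin == "dn" and spin_symmetric:
            out["dn"] = out["up"]
            break
        cols = paos
        if spin == "dn" and somo_members:
            extra = occ_lmo[:, [members.index(m) for m in somo_members]]
            cols = np.hstack([paos, extra])
        sc_guard = _sc_columns(ref, local_basis, spin, somo_members)
        V = _virtual_space(cols, occ_span, sc_guard, S_dd, idx, lindep)
        if V.shape[1] == 0:
            raise DomainError(f"empty virtual space in the ED of LMO {cmo_id}")
        if spin == "dn" and somo_members:
            # the dual-role SOMOs must survive the orthogonalization
            scols = occ_lmo[:, [members.index(m) for m in somo_members]]
            proj = V.T @ S_dd @ scols
            if np.any(np.sum(proj ** 2, axis=0) < 0.5):
                raise DomainError(
                    f"ED of LMO {cmo_id}: an appended SOMO is missing from "
                    "the spin-down virtual space")
        F_dd = F[np.ix_(idx, idx)]
        Vc, ve, _ = _pseudocanonicalize(V, F_dd)
        Oc, oe, Urot = _pseudocanonicalize(occ_span, F_dd)
        out[spin] = (V, Vc, ve, Oc, oe, Urot)
    aux_idx = None
    if mi_aux_atom is not None:
        aux_idx = np.nonzero(np.isin(mi_aux_atom, pcd))[0]
    return Domain(
        kind="extended", central=cmo_id, members=members, atoms=atoms,
        ao_idx=idx, contains_somo=bool(somo_members),
        somo_members=somo_members, occ_lmo=occ_lmo,
        occ_up=out["up"][3], occ_dn=out["dn"][3],
        U_up=out["up"][5], U_dn=out["dn"][5],
        occ_e_up=out["up"][4], occ_e_dn=out["dn"][4],
        virt_up=out["up"][1], virt_dn=out["dn"][1],
        virt_e_up=out["up"][2], virt_e_dn=out["dn"][2],
        virt_orth_up=out["up"][0], virt_orth_dn=out["dn"][0],
        aux_idx=aux_idx, pcd_atoms=pcd, dn_members=dn_members,
        spin_symmetric=spin_symmetric)
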
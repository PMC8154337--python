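"""Density-fitted self-consistent field: RHF, UHF and ROHF.

This is the reference backend the correlation modules build on.  The
restricted open-shell solver uses the Roothaan effective-Fock coupling with
DIIS; the spin Fock matrices are the UHF-type matrices built from the
restricted densities (spin-up from DOMOs+SOMOs, spin-down from DOMOs only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla

from .engine import MoleculeIntegrals
from .system import MolecularSystem


class SCFConvergenceError(RuntimeError):
    pass


def coulomb(W: np.ndarray, D: np.ndarray) -> np.ndarray:
    w = np.tensordot(W, D, axes=([0, 1], [0, 1]))
    return W @ w


def exchange(W: np.ndarray, C_occ: np.ndarray) -> np.ndarray:
    if C_occ.shape[1] == 0:
        return np.zeros((W.shape[0], W.shape[0]))
    B = np.tensordot(W, C_occ, axes=([1], [0]))  # (m, P, i)
    n = W.shape[0]
    Bf = B.reshape(n, -1)
    return Bf @ Bf.T


class _DIIS:
    def __init__(self, size=8):
        self.size = size
        self.focks: list[np.ndarray] = []
        self.errs: list[np.ndarray] = []

    def update(self, fock, err):
        self.focks.append(fock.copy())
        self.errs.append(err.ravel().copy())
        if len(self.focks) > self.size:
            self.focks.pop(0)
            self.errs.pop(0)
        n = len(self.focks)
        if n < 2:
            return fock
        B = -np.ones((n + 1, n + 1))
        B[-1, -1] = 0.0
        for i in range(n):
            for j in range(n):
                B[i, j] = self.errs[i] @ self.errs[j]
        rhs = np.zeros(n + 1)
        rhs[-1] = -1.0
        try:
            c = np.linalg.solve(B, rhs)[:n]
        except np.linalg.LinAlgError:
            return fock
        return sum(ci * fi for ci, fi in zip(c, self.focks))


@dataclass
class SCFResult:
    kind: str
    energy: float
    mo_coeff: np.ndarray  # restricted MOs (ROHF/RHF); (2, nao, nmo) for UHF
    mo_energy: np.ndarray
    fock_up: np.ndarray
    fock_dn: np.ndarray
    dm_up: np.ndarray
    dm_dn: np.ndarray
    converged: bool
    n_iter: int
    s_squared: float = 0.0


def _energy(h, Fu, Fd, Du, Dd, enuc):
    return 0.5 * (np.sum(Du * (h + Fu)) + np.sum(Dd * (h + Fd))) + enuc


def rohf(mi: MoleculeIntegrals, conv_tol=1e-10, max_iter=200) -> SCFResult:
    """Restricted open-shell (or closed-shell) HF; returns restricted MOs."""
    sys_ = mi.system
    h, S, W = mi.hcore, mi.S, mi.W
    enuc = sys_.nuclear_repulsion()
    nup, ndn = sys_.n_up, sys_.n_dn
    e_mo, C = sla.eigh(h, S)
    diis = _DIIS()
    e_old, converged, it = 0.0, False, 0
    for it in range(1, max_iter + 1):
        Cu, Cd = C[:, :nup], C[:, :ndn]
        Du, Dd = Cu @ Cu.T, Cd @ Cd.T
        J = coulomb(W, Du + Dd)
        Fu = h + J - exchange(W, Cu)
        Fd = h + J - exchange(W, Cd)
        # Roothaan effective Fock in the current MO basis
        fu = C.T @ Fu @ C
        fd = C.T @ Fd @ C
        R = 0.5 * (fu + fd)
        c, o = slice(0, ndn), slice(ndn, nup)
        v = slice(nup, None)
        R[c, o] = fd[c, o]
        R[o, c] = fd[o, c]
        R[o, v] = fu[o, v]
        R[v, o] = fu[v, o]
        R_ao = S @ C @ R @ C.T @ S
        Dt = Du + Dd
        err = R_ao @ Dt @ S - S @ Dt @ R_ao
        energy = _energy(h, Fu, Fd, Du, Dd, enuc)
        if abs(energy - e_old) < conv_tol and np.max(np.abs(err)) < 1e-7:
            converged = True
            break
        e_old = energy
        R_ao = diis.update(R_ao, err)
        if it <= 4:  # light damping while DIIS warms up
            R_ao = 0.7 * R_ao + 0.3 * (S @ C @ np.diag(e_mo) @ C.T @ S)
        e_mo, C = sla.eigh(R_ao, S)
    if not converged:
        raise SCFConvergenceError(
            f"ROHF did not converge in {max_iter} iterations "
            "(consider the quasi-restricted-orbital path from a UHF density)")
    s = 0.5 * (nup - ndn)
    return SCFResult("ROHF" if nup != ndn else "RHF", energy, C, e_mo,
                     Fu, Fd, Du, Dd, converged, it, s * (s + 1.0))


def uhf(mi: MoleculeIntegrals, conv_tol=1e-10, max_iter=300,
        break_symmetry=0.2) -> SCFResult:
    """Unrestricted HF with a symmetry-broken initial guess."""
    sys_ = mi.system
    h, S, W = mi.hcore, mi.S, mi.W
    enuc = sys_.nuclear_repulsion()
    nup, ndn = sys_.n_up, sys_.n_dn
    e0, C0 = sla.eigh(h, S)
    Cu = C0.copy()
    Cd = C0.copy()
    if break_symmetry and ndn > 0 and nup < C0.shape[1]:
        # mix the beta HOMO with the LUMO to allow spin polarization
        a, b = Cd[:, ndn - 1].copy(), Cd[:, nup].copy()
        t = break_symmetry
        Cd[:, ndn - 1] = np.cos(t) * a + np.sin(t) * b
        Cd[:, nup] = -np.sin(t) * a + np.cos(t) * b
    diis = _DIIS()
    e_old, converged, it = 0.0, False, 0
    for it in range(1, max_iter + 1):
        Du = Cu[:, :nup] @ Cu[:, :nup].T
        Dd = Cd[:, :ndn] @ Cd[:, :ndn].T
        J = coulomb(W, Du + Dd)
        Fu = h + J - exchange(W, Cu[:, :nup])
        Fd = h + J - exchange(W, Cd[:, :ndn])
        erru = Fu @ Du @ S - S @ Du @ Fu
        errd = Fd @ Dd @ S - S @ Dd @ Fd
        energy = _energy(h, Fu, Fd, Du, Dd, enuc)
        if abs(energy - e_old) < conv_tol and \
                max(np.max(np.abs(erru)), np.max(np.abs(errd))) < 1e-7:
            converged = True
            break
        e_old = energy
        big = diis.update(np.concatenate([Fu.ravel(), Fd.ravel()]),
                          np.concatenate([erru.ravel(), errd.ravel()]))
        n = h.shape[0]
        Fu_x = big[:n * n].reshape(n, n)
        Fd_x = big[n * n:].reshape(n, n)
        eu, Cu = sla.eigh(Fu_x, S)
        ed, Cd = sla.eigh(Fd_x, S)
    if not converged:
        raise SCFConvergenceError(f"UHF did not converge in {max_iter} iterations")
    # <S^2> of the unrestricted determinant
    ov = Cu[:, :nup].T @ S @ Cd[:, :ndn]
    sz = 0.5 * (nup - ndn)
    s2 = sz * (sz + 1.0) + ndn - np.sum(ov * ov)
    mo = np.stack([Cu, Cd])
    moe = np.stack([eu, ed])
    return SCFResult("UHF", energy, mo, moe, Fu, Fd, Du, Dd, converged, it, s2)
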
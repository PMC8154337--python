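"""Per-molecule integral cache and density-fitting metric handling."""

from __future__ import annotations

import warnings

import numpy as np
import scipy.linalg as sla

from . import integrals
from .basis import build_basis
from .system import MolecularSystem


def metric_decomposition(V: np.ndarray, lindep: float = 1e-10) -> np.ndarray:
    """Matrix M with (I M)(I M)^T = I V^+ I^T for the fitting metric V.

    Uses the Cholesky factor inverse when V is safely positive definite;
    otherwise falls back to an eigendecomposition dropping near-null
    directions (near-linear-dependent auxiliary sets).
    """
    try:
        L = sla.cholesky(V, lower=True)
        cond = np.max(np.abs(np.diag(L))) / np.min(np.abs(np.diag(L)))
        if cond < 1e7:
            return sla.solve_triangular(L, np.eye(V.shape[0]), lower=True).T
    except sla.LinAlgError:
        pass
    w, U = sla.eigh(V)
    keep = w > lindep * w.max()
    if not keep.all():
        warnings.warn(
            f"fitting metric has {np.sum(~keep)} near-null directions; "
            "eliminated by eigenvalue screening")
    return U[:, keep] / np.sqrt(w[keep])


class MoleculeIntegrals:
    """Lazily computed AO integrals shared by SCF, domains, and the oracle."""

    def __init__(self, system: MolecularSystem):
        self.system = system
        self.basis = build_basis(system.symbols, system.coords,
                                 system.basis_name)
        self.aux = build_basis(system.symbols, system.coords,
                               system.aux_basis_name, kind="aux")
        self._cache: dict = {}

    @property
    def nao(self) -> int:
        return self.basis.nao

    @property
    def naux(self) -> int:
        return self.aux.nao

    def _get(self, key, fn):
        if key not in self._cache:
            self._cache[key] = fn()
        return self._cache[key]

    @property
    def S(self):
        return self._get("S", lambda: integrals.overlap_kinetic(self.basis)[0])

    @property
    def T(self):
        return self._get("T", lambda: integrals.overlap_kinetic(self.basis)[1])

    @property
    def Vne(self):
        return self._get("V", lambda: integrals.nuclear(
            self.basis, self.system.coords, self.system.charges))

    @property
    def hcore(self):
        return self.T + self.Vne

    @property
    def dipole(self):
        """AO dipole matrices about the origin, shape (3, nao, nao)."""
        return self._get("dip", lambda: integrals.moments(
            self.basis, np.zeros(3), 1)[1:4])

    @property
    def T3(self):
        """Three-center ERIs (mu nu | P), full molecule."""
        return self._get("T3", lambda: integrals.eri3c(self.basis, self.aux))

    @property
    def V2(self):
        return self._get("V2", lambda: integrals.eri2c(self.aux))

    @property
    def metric_M(self):
        return self._get("M", lambda: metric_decomposition(self.V2))

    @property
    def W(self):
        """Metric-contracted fitting tensor W = T3 @ M, (mu, nu, Q)."""
        def make():
            M = self.metric_M
            nao = self.nao
            T3 = self.T3.reshape(nao * nao, -1)
            return (T3 @ M).reshape(nao, nao, -1)
        return self._get("W", make)
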
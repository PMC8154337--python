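"""Factorization of MP2 orbital-energy denominators.

The doubles denominator 1/(e_a + e_b - e_i - e_j) is written as a separable
sum over terms g_w(x) g_w(y) with x = e_a - e_i and y = e_b - e_j, so
amplitudes can be assembled denominator-free with one occupied index in the
localized basis.  Two factorizations are provided over a single spin-merged
gap range (so all four spin cases share one set of vectors):

* ``cholesky`` (default): pivoted Cholesky of the kernel 1/(x + y) on the
  grid of all occurring gaps, stopped when the diagonal residual drops
  below the tolerance; off-diagonal residuals are then bounded by the same
  tolerance for a positive semidefinite kernel.
* ``laplace``: numerical quadrature 1/D = sum_w w_w exp(-t_w D), fitted on
  a logarithmic grid of the merged denominator range.
* ``exact``: marker for explicit denominators (no factorization).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls


@dataclass
class DenominatorFactorization:
    method: str                    # laplace | cholesky | exact
    tol: float
    # cholesky data
    pivots: np.ndarray = None      # gap values at the pivot points
    pivot_vecs: np.ndarray = None  # (n_w, n_w) lower-tri values c_w(pivot_v)
    # laplace data
    exponents: np.ndarray = None
    lap_weights: np.ndarray = None
    x_range: tuple = (0.0, 0.0)

    @property
    def n_terms(self) -> int:
        if self.method == "cholesky":
            return len(self.pivots)
        if self.method == "laplace":
            return len(self.exponents)
        return 0

    def weights(self, x: np.ndarray) -> np.ndarray:
        """g_w(x) with 1/(x+y) ~= sum_w g_w(x) g_w(y); shape (n_w,) + x.shape."""
        x = np.asarray(x, float)
        if self.method == "laplace":
            return (np.sqrt(self.lap_weights).reshape((-1,) + (1,) * x.ndim)
                    * np.exp(-np.multiply.outer(self.exponents, x)))
        if self.method != "cholesky":
            raise ValueError("exact factorization has no separable weights")
        n = self.n_terms
        G = np.zeros((n,) + x.shape)
        for w in range(n):
            col = 1.0 / (x + self.pivots[w])
            for v in range(w):
                col = col - G[v] * self.pivot_vecs[w, v]
            G[w] = col / self.pivot_vecs[w, w]
        return G

    def max_error(self, x: np.ndarray, y: np.ndarray | None = None) -> float:
        """Max abs deviation of the factorized denominator on a gap grid."""
        y = x if y is None else y
        D = 1.0 / (x[:, None] + y[None, :])
        Gx, Gy = self.weights(x), self.weights(y)
        return float(np.abs(D - np.einsum("wi,wj->ij", Gx, Gy)).max())


def _pivoted_cholesky_kernel(grid: np.ndarray, tol: float, max_rank: int = 60):
    """On-demand pivoted Cholesky of M_pq = 1/(x_p + x_q)."""
    n = len(grid)
    diag = 1.0 / (2.0 * grid)
    vecs = np.zeros((max_rank, n))
    pivots = []
    for k in range(max_rank):
        p = int(np.argmax(diag))
        if diag[p] < tol:
            break
        col = 1.0 / (grid + grid[p])
        for v in range(k):
            col = col - vecs[v] * vecs[v, p]
        vecs[k] = col / np.sqrt(col[p])
        diag = diag - vecs[k] ** 2
        np.maximum(diag, 0.0, out=diag)
        pivots.append(p)
    k = len(pivots)
    return grid[pivots], vecs[:k]


def factorize_denominators(occ_energies, virt_energies, method="cholesky",
                           tol=1e-4, n_points=None) -> DenominatorFactorization:
    """Spin-independent factorization covering all four spin cases.

    ``occ_energies``/``virt_energies`` are sequences of per-spin energy
    arrays; the factorization covers every occurring gap e_a - e_i.
    """
    gaps = []
    for eo in occ_energies:
        for ev in virt_energies:
            if len(eo) and len(ev):
                gaps.append(np.subtract.outer(ev, eo).ravel())
    gaps = np.unique(np.concatenate(gaps))
    if gaps.min() <= 0:
        raise RuntimeError(
            "non-positive occupied-virtual gap: reference is unstable "
            f"(min gap {gaps.min():.6e} E_h)")
    if method == "exact":
        return DenominatorFactorization("exact", 0.0,
                                        x_range=(gaps.min(), gaps.max()))
    if method == "cholesky":
        piv, vecs = _pivoted_cholesky_kernel(gaps, tol)
        # store triangular evaluation data: c_w at the pivot gap values
        fac = DenominatorFactorization("cholesky", tol, pivots=piv,
                                       x_range=(gaps.min(), gaps.max()))
        k = len(piv)
        tri = np.zeros((k, k))
        pidx = [int(np.nonzero(gaps == p)[0][0]) for p in piv]
        for w in range(k):
            for v in range(w + 1):
                tri[w, v] = vecs[v, pidx[w]]
        fac.pivot_vecs = tri
        return fac
    if method == "laplace":
        lo, hi = 2.0 * gaps.min(), 2.0 * gaps.max()
        D = np.geomspace(lo, hi, n_points or 600)
        target = 1.0 / D
        for m in (8, 12, 16, 24, 32, 48, 64, 96):
            t = np.geomspace(0.05 / hi, 50.0 / lo, m)
            A = np.exp(-np.outer(D, t))
            w, _ = nnls(A, target)
            keep = w > 1e-16
            if keep.sum() == 0:
                continue
            err = np.abs(A[:, keep] @ w[keep] - target).max()
            if err < tol:
                return DenominatorFactorization(
                    "laplace", tol, exponents=t[keep],
                    lap_weights=w[keep], x_range=(gaps.min(), gaps.max()))
        raise RuntimeError("Laplace quadrature failed to reach the tolerance")
    raise ValueError(f"unknown denominator method '{method}'")
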
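"""Molecular integrals over contracted Cartesian Gaussians.

McMurchie-Davidson scheme throughout: products of primitive pairs are
expanded in Hermite Gaussians (E coefficients), Coulomb kernels are handled
with the Boys function and the Hermite recurrence (R tensor).  Supported
integrals: overlap, kinetic, nuclear attraction, Cartesian multipole moments
about an arbitrary center, and two-/three-/four-center electron repulsion
integrals for density fitting and brute-force validation.

All kernels are numba-compiled; the Python wrappers handle normalization
(every contracted Cartesian AO is scaled to unit self-overlap).
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .basis import BasisSet

# ---------------------------------------------------------------------------
# scalar helpers


@njit(cache=False)
def _boys(mmax, T, out):
    """Boys function F_m(T) for m = 0..mmax."""
    if T < 1e-13:
        for m in range(mmax + 1):
            out[m] = 1.0 / (2 * m + 1)
        return
    if T < 35.0:
        # series for the highest order, then downward recursion
        s = 1.0 / (2 * mmax + 1)
        term = s
        k = 1
        while k < 300:
            term *= 2.0 * T / (2 * mmax + 2 * k + 1)
            s += term
            if term < 1e-17 * s:
                break
            k += 1
        emt = np.exp(-T)
        out[mmax] = s * emt
        for m in range(mmax, 0, -1):
            out[m - 1] = (2.0 * T * out[m] + emt) / (2 * m - 1)
    else:
        emt = np.exp(-T)
        out[0] = 0.5 * np.sqrt(np.pi / T)
        for m in range(mmax):
            out[m + 1] = ((2 * m + 1) * out[m] - emt) / (2.0 * T)


@njit(cache=False)
def _e1d(l1, l2, PA, PB, p, K):
    """Hermite expansion coefficients E_t^{ij} for one Cartesian direction."""
    E = np.zeros((l1 + 1, l2 + 1, l1 + l2 + 2))
    E[0, 0, 0] = K
    o2p = 0.5 / p
    for i in range(1, l1 + 1):
        for t in range(i + 1):
            v = PA * E[i - 1, 0, t] + (t + 1) * E[i - 1, 0, t + 1]
            if t > 0:
                v += o2p * E[i - 1, 0, t - 1]
            E[i, 0, t] = v
    for j in range(1, l2 + 1):
        for i in range(l1 + 1):
            for t in range(i + j + 1):
                v = PB * E[i, j - 1, t] + (t + 1) * E[i, j - 1, t + 1]
                if t > 0:
                    v += o2p * E[i, j - 1, t - 1]
                E[i, j, t] = v
    return E


@njit(cache=False)
def _rtensor(L, alpha, X, Y, Z):
    """Hermite Coulomb integrals R^0_{tuv} for t+u+v <= L."""
    T = alpha * (X * X + Y * Y + Z * Z)
    F = np.zeros(L + 1)
    _boys(L, T, F)
    R = np.zeros((L + 1, L + 1, L + 1, L + 1))
    m2a = 1.0
    for n in range(L + 1):
        R[n, 0, 0, 0] = m2a * F[n]
        m2a *= -2.0 * alpha
    for n in range(L - 1, -1, -1):
        rng = L - n
        for t in range(rng + 1):
            for u in range(rng + 1 - t):
                for v in range(rng + 1 - t - u):
                    if t + u + v == 0:
                        continue
                    if t > 0:
                        val = X * R[n + 1, t - 1, u, v]
                        if t > 1:
                            val += (t - 1) * R[n + 1, t - 2, u, v]
                    elif u > 0:
                        val = Y * R[n + 1, t, u - 1, v]
                        if u > 1:
                            val += (u - 1) * R[n + 1, t, u - 2, v]
                    else:
                        val = Z * R[n + 1, t, u, v - 1]
                        if v > 1:
                            val += (v - 1) * R[n + 1, t, u, v - 2]
                    R[n, t, u, v] = val
    return R[0]


@njit(cache=False)
def _ncart(l):
    return (l + 1) * (l + 2) // 2


@njit(cache=False)
def _comp(l, k):
    """k-th Cartesian component (lx, ly, lz) of shell l (lexicographic)."""
    idx = 0
    for lx in range(l, -1, -1):
        for ly in range(l - lx, -1, -1):
            if idx == k:
                return lx, ly, l - lx - ly
            idx += 1
    return 0, 0, 0


# ---------------------------------------------------------------------------
# one-electron integrals


@njit(cache=False)
def _overlap_kinetic_kernel(sh_l, sh_coord, sh_ps, sh_pn, pa, pc, sh_ao, nao):
    S = np.zeros((nao, nao))
    T = np.zeros((nao, nao))
    nsh = sh_l.shape[0]
    for A in range(nsh):
        la = sh_l[A]
        for B in range(A, nsh):
            lb = sh_l[B]
            AB = sh_coord[A] - sh_coord[B]
            rab2 = AB[0] ** 2 + AB[1] ** 2 + AB[2] ** 2
            nca, ncb = _ncart(la), _ncart(lb)
            blockS = np.zeros((nca, ncb))
            blockT = np.zeros((nca, ncb))
            for ip in range(sh_ps[A], sh_ps[A] + sh_pn[A]):
                a1 = pa[ip]
                for jp in range(sh_ps[B], sh_ps[B] + sh_pn[B]):
                    a2 = pa[jp]
                    p = a1 + a2
                    mu = a1 * a2 / p
                    cc = pc[ip] * pc[jp]
                    P = (a1 * sh_coord[A] + a2 * sh_coord[B]) / p
                    pref = (np.pi / p) ** 1.5 * np.exp(-mu * rab2)
                    Es = []
                    for d in range(3):
                        PA = P[d] - sh_coord[A][d]
                        PB = P[d] - sh_coord[B][d]
                        Es.append(_e1d(la, lb + 2, PA, PB, p, 1.0))
                    Ex, Ey, Ez = Es[0], Es[1], Es[2]
                    for ka in range(nca):
                        i1, j1, k1 = _comp(la, ka)
                        for kb in range(ncb):
                            i2, j2, k2 = _comp(lb, kb)
                            sx = Ex[i1, i2, 0]
                            sy = Ey[j1, j2, 0]
                            sz = Ez[k1, k2, 0]
                            blockS[ka, kb] += cc * pref * sx * sy * sz
                            # kinetic in one dimension via raised/lowered l
                            tx = -2.0 * a2 * a2 * Ex[i1, i2 + 2, 0] \
                                + a2 * (2 * i2 + 1) * sx
                            if i2 >= 2:
                                tx -= 0.5 * i2 * (i2 - 1) * Ex[i1, i2 - 2, 0]
                            ty = -2.0 * a2 * a2 * Ey[j1, j2 + 2, 0] \
                                + a2 * (2 * j2 + 1) * sy
                            if j2 >= 2:
                                ty -= 0.5 * j2 * (j2 - 1) * Ey[j1, j2 - 2, 0]
                            tz = -2.0 * a2 * a2 * Ez[k1, k2 + 2, 0] \
                                + a2 * (2 * k2 + 1) * sz
                            if k2 >= 2:
                                tz -= 0.5 * k2 * (k2 - 1) * Ez[k1, k2 - 2, 0]
                            blockT[ka, kb] += cc * pref * (
                                tx * sy * sz + sx * ty * sz + sx * sy * tz)
            oa, ob = sh_ao[A], sh_ao[B]
            for ka in range(nca):
                for kb in range(ncb):
                    S[oa + ka, ob + kb] = blockS[ka, kb]
                    S[ob + kb, oa + ka] = blockS[ka, kb]
                    T[oa + ka, ob + kb] = blockT[ka, kb]
                    T[ob + kb, oa + ka] = blockT[ka, kb]
    return S, T


@njit(cache=False)
def _moments_kernel(sh_l, sh_coord, sh_ps, sh_pn, pa, pc, sh_ao, nao,
                    center, emax, ncomp):
    """Cartesian moment integrals < mu | (r-C)^e | nu > for e = 0..emax."""
    M = np.zeros((ncomp, nao, nao))
    nsh = sh_l.shape[0]
    for A in range(nsh):
        la = sh_l[A]
        for B in range(A, nsh):
            lb = sh_l[B]
            AB = sh_coord[A] - sh_coord[B]
            rab2 = AB[0] ** 2 + AB[1] ** 2 + AB[2] ** 2
            nca, ncb = _ncart(la), _ncart(lb)
            block = np.zeros((ncomp, nca, ncb))
            for ip in range(sh_ps[A], sh_ps[A] + sh_pn[A]):
                a1 = pa[ip]
                for jp in range(sh_ps[B], sh_ps[B] + sh_pn[B]):
                    a2 = pa[jp]
                    p = a1 + a2
                    mu = a1 * a2 / p
                    cc = pc[ip] * pc[jp] * np.exp(-mu * rab2)
                    P = (a1 * sh_coord[A] + a2 * sh_coord[B]) / p
                    tmax = la + lb
                    # 1D Hermite moments m[t, e] = int Lambda_t (x-C)^e dx
                    sq = np.sqrt(np.pi / p)
                    o2p = 0.5 / p
                    mom = np.zeros((3, tmax + emax + 2, emax + 1))
                    for d in range(3):
                        mom[d, 0, 0] = sq
                        PC = P[d] - center[d]
                        for e in range(emax):
                            for t in range(tmax + emax - e):
                                v = o2p * mom[d, t + 1, e] + PC * mom[d, t, e]
                                if t > 0:
                                    v += t * mom[d, t - 1, e]
                                mom[d, t, e + 1] = v
                    Es = []
                    for d in range(3):
                        PA = P[d] - sh_coord[A][d]
                        PB = P[d] - sh_coord[B][d]
                        Es.append(_e1d(la, lb, PA, PB, p, 1.0))
                    Ex, Ey, Ez = Es[0], Es[1], Es[2]
                    for ka in range(nca):
                        i1, j1, k1 = _comp(la, ka)
                        for kb in range(ncb):
                            i2, j2, k2 = _comp(lb, kb)
                            ic = 0
                            for e in range(emax + 1):
                                for kk in range(_ncart(e)):
                                    ex, ey, ez = _comp(e, kk)
                                    vx = 0.0
                                    for t in range(i1 + i2 + 1):
                                        vx += Ex[i1, i2, t] * mom[0, t, ex]
                                    vy = 0.0
                                    for t in range(j1 + j2 + 1):
                                        vy += Ey[j1, j2, t] * mom[1, t, ey]
                                    vz = 0.0
                                    for t in range(k1 + k2 + 1):
                                        vz += Ez[k1, k2, t] * mom[2, t, ez]
                                    block[ic, ka, kb] += cc * vx * vy * vz
                                    ic += 1
            oa, ob = sh_ao[A], sh_ao[B]
            for ic in range(ncomp):
                for ka in range(nca):
                    for kb in range(ncb):
                        M[ic, oa + ka, ob + kb] = block[ic, ka, kb]
                        M[ic, ob + kb, oa + ka] = block[ic, ka, kb]
    return M


@njit(cache=False)
def _nuclear_kernel(sh_l, sh_coord, sh_ps, sh_pn, pa, pc, sh_ao, nao,
                    at_coord, at_chg):
    V = np.zeros((nao, nao))
    nsh = sh_l.shape[0]
    natm = at_chg.shape[0]
    for A in range(nsh):
        la = sh_l[A]
        for B in range(A, nsh):
            lb = sh_l[B]
            AB = sh_coord[A] - sh_coord[B]
            rab2 = AB[0] ** 2 + AB[1] ** 2 + AB[2] ** 2
            nca, ncb = _ncart(la), _ncart(lb)
            block = np.zeros((nca, ncb))
            L = la + lb
            for ip in range(sh_ps[A], sh_ps[A] + sh_pn[A]):
                a1 = pa[ip]
                for jp in range(sh_ps[B], sh_ps[B] + sh_pn[B]):
                    a2 = pa[jp]
                    p = a1 + a2
                    mu = a1 * a2 / p
                    cc = pc[ip] * pc[jp] * np.exp(-mu * rab2)
                    P = (a1 * sh_coord[A] + a2 * sh_coord[B]) / p
                    Es = []
                    for d in range(3):
                        PA = P[d] - sh_coord[A][d]
                        PB = P[d] - sh_coord[B][d]
                        Es.append(_e1d(la, lb, PA, PB, p, 1.0))
                    Ex, Ey, Ez = Es[0], Es[1], Es[2]
                    for ic in range(natm):
                        R = _rtensor(L, p, P[0] - at_coord[ic, 0],
                                     P[1] - at_coord[ic, 1],
                                     P[2] - at_coord[ic, 2])
                        pref = -at_chg[ic] * 2.0 * np.pi / p * cc
                        for ka in range(nca):
                            i1, j1, k1 = _comp(la, ka)
                            for kb in range(ncb):
                                i2, j2, k2 = _comp(lb, kb)
                                v = 0.0
                                for t in range(i1 + i2 + 1):
                                    for u in range(j1 + j2 + 1):
                                        for w in range(k1 + k2 + 1):
                                            v += Ex[i1, i2, t] * \
                                                Ey[j1, j2, u] * \
                                                Ez[k1, k2, w] * R[t, u, w]
                                block[ka, kb] += pref * v
            oa, ob = sh_ao[A], sh_ao[B]
            for ka in range(nca):
                for kb in range(ncb):
                    V[oa + ka, ob + kb] = block[ka, kb]
                    V[ob + kb, oa + ka] = block[ka, kb]
    return V


# ---------------------------------------------------------------------------
# electron repulsion integrals


@njit(cache=False)
def _hermite_ket(l3, l4, coordC, coordD, a3, a4):
    """Hermite expansion (with alternating sign) of a primitive ket pair."""
    q = a3 + a4
    CD = coordC - coordD
    rcd2 = CD[0] ** 2 + CD[1] ** 2 + CD[2] ** 2
    mu = a3 * a4 / q
    K = np.exp(-mu * rcd2)
    Q = (a3 * coordC + a4 * coordD) / q
    Es = np.zeros((3, l3 + 1, l4 + 1, l3 + l4 + 2))
    for d in range(3):
        QC = Q[d] - coordC[d]
        QD = Q[d] - coordD[d]
        Es[d] = _e1d(l3, l4, QC, QD, q, 1.0)
    return Es, Q, q, K


@njit(cache=False)
def _eri2c_kernel(sh_l, sh_coord, sh_ps, sh_pn, pa, pc, sh_ao, nao):
    V = np.zeros((nao, nao))
    nsh = sh_l.shape[0]
    for A in range(nsh):
        la = sh_l[A]
        nca = _ncart(la)
        for B in range(A, nsh):
            lb = sh_l[B]
            ncb = _ncart(lb)
            block = np.zeros((nca, ncb))
            L = la + lb
            for ip in range(sh_ps[A], sh_ps[A] + sh_pn[A]):
                a1 = pa[ip]
                Ea = _e1d(la, 0, 0.0, 0.0, a1, 1.0)
                for jp in range(sh_ps[B], sh_ps[B] + sh_pn[B]):
                    a2 = pa[jp]
                    Eb = _e1d(lb, 0, 0.0, 0.0, a2, 1.0)
                    al = a1 * a2 / (a1 + a2)
                    R = _rtensor(L, al,
                                 sh_coord[A][0] - sh_coord[B][0],
                                 sh_coord[A][1] - sh_coord[B][1],
                                 sh_coord[A][2] - sh_coord[B][2])
                    pref = 2.0 * np.pi ** 2.5 / (a1 * a2 * np.sqrt(a1 + a2)) \
                        * pc[ip] * pc[jp]
                    for ka in range(nca):
                        i1, j1, k1 = _comp(la, ka)
                        for kb in range(ncb):
                            i2, j2, k2 = _comp(lb, kb)
                            v = 0.0
                            for t in range(i1 + 1):
                                for u in range(j1 + 1):
                                    for w in range(k1 + 1):
                                        e1 = Ea[i1, 0, t] * Ea[j1, 0, u] * \
                                            Ea[k1, 0, w]
                                        if e1 == 0.0:
                                            continue
                                        for t2 in range(i2 + 1):
                                            for u2 in range(j2 + 1):
                                                for w2 in range(k2 + 1):
                                                    e2 = Eb[i2, 0, t2] * \
                                                        Eb[j2, 0, u2] * \
                                                        Eb[k2, 0, w2]
                                                    if e2 == 0.0:
                                                        continue
                                                    sgn = 1.0 if (t2 + u2 + w2) % 2 == 0 else -1.0
                                                    v += e1 * e2 * sgn * \
                                                        R[t + t2, u + u2, w + w2]
                            block[ka, kb] += pref * v
            oa, ob = sh_ao[A], sh_ao[B]
            for ka in range(nca):
                for kb in range(ncb):
                    V[oa + ka, ob + kb] = block[ka, kb]
                    V[ob + kb, oa + ka] = block[ka, kb]
    return V


@njit(cache=False)
def _eri3c_kernel(sh_l, sh_coord, sh_ps, sh_pn, pa, pc, sh_ao, nao,
                  xl, xcoord, xps, xpn, xpa, xpc, xao, naux):
    T3 = np.zeros((nao, nao, naux))
    nsh = sh_l.shape[0]
    nxsh = xl.shape[0]
    for A in range(nsh):
        la = sh_l[A]
        nca = _ncart(la)
        for B in range(A, nsh):
            lb = sh_l[B]
            ncb = _ncart(lb)
            AB = sh_coord[A] - sh_coord[B]
            rab2 = AB[0] ** 2 + AB[1] ** 2 + AB[2] ** 2
            for C in range(nxsh):
                lc = xl[C]
                ncc = _ncart(lc)
                L = la + lb + lc
                block = np.zeros((nca, ncb, ncc))
                for ip in range(sh_ps[A], sh_ps[A] + sh_pn[A]):
                    a1 = pa[ip]
                    for jp in range(sh_ps[B], sh_ps[B] + sh_pn[B]):
                        a2 = pa[jp]
                        p = a1 + a2
                        mu = a1 * a2 / p
                        Kab = np.exp(-mu * rab2)
                        if Kab < 1e-16:
                            continue
                        P = (a1 * sh_coord[A] + a2 * sh_coord[B]) / p
                        Ex = _e1d(la, lb, P[0] - sh_coord[A][0],
                                  P[0] - sh_coord[B][0], p, 1.0)
                        Ey = _e1d(la, lb, P[1] - sh_coord[A][1],
                                  P[1] - sh_coord[B][1], p, 1.0)
                        Ez = _e1d(la, lb, P[2] - sh_coord[A][2],
                                  P[2] - sh_coord[B][2], p, 1.0)
                        for kp in range(xps[C], xps[C] + xpn[C]):
                            a3 = xpa[kp]
                            Ec = _e1d(lc, 0, 0.0, 0.0, a3, 1.0)
                            al = p * a3 / (p + a3)
                            R = _rtensor(L, al,
                                         P[0] - xcoord[C][0],
                                         P[1] - xcoord[C][1],
                                         P[2] - xcoord[C][2])
                            pref = 2.0 * np.pi ** 2.5 / \
                                (p * a3 * np.sqrt(p + a3)) * \
                                pc[ip] * pc[jp] * xpc[kp] * Kab
                            for kc in range(ncc):
                                i3, j3, k3 = _comp(lc, kc)
                                for ka in range(nca):
                                    i1, j1, k1 = _comp(la, ka)
                                    for kb in range(ncb):
                                        i2, j2, k2 = _comp(lb, kb)
                                        v = 0.0
                                        for t2 in range(i3 + 1):
                                            for u2 in range(j3 + 1):
                                                for w2 in range(k3 + 1):
                                                    e2 = Ec[i3, 0, t2] * \
                                                        Ec[j3, 0, u2] * \
                                                        Ec[k3, 0, w2]
                                                    if e2 == 0.0:
                                                        continue
                                                    if (t2 + u2 + w2) % 2 == 1:
                                                        e2 = -e2
                                                    for t in range(i1 + i2 + 1):
                                                        ex = Ex[i1, i2, t]
                                                        for u in range(j1 + j2 + 1):
                                                            exy = ex * Ey[j1, j2, u]
                                                            for w in range(k1 + k2 + 1):
                                                                v += exy * \
                                                                    Ez[k1, k2, w] * e2 * \
                                                                    R[t + t2, u + u2, w + w2]
                                        block[ka, kb, kc] += pref * v
                oa, ob, oc = sh_ao[A], sh_ao[B], xao[C]
                for ka in range(nca):
                    for kb in range(ncb):
                        for kc in range(ncc):
                            T3[oa + ka, ob + kb, oc + kc] = block[ka, kb, kc]
                            T3[ob + kb, oa + ka, oc + kc] = block[ka, kb, kc]
    return T3


@njit(cache=False)
def _eri4c_kernel(sh_l, sh_coord, sh_ps, sh_pn, pa, pc, sh_ao, nao):
    eri = np.zeros((nao, nao, nao, nao))
    nsh = sh_l.shape[0]
    for A in range(nsh):
        la = sh_l[A]
        nca = _ncart(la)
        for B in range(nsh):
            lb = sh_l[B]
            ncb = _ncart(lb)
            AB = sh_coord[A] - sh_coord[B]
            rab2 = AB[0] ** 2 + AB[1] ** 2 + AB[2] ** 2
            for C in range(nsh):
                lc = sh_l[C]
                ncc = _ncart(lc)
                for D in range(nsh):
                    ld = sh_l[D]
                    ncd = _ncart(ld)
                    CD = sh_coord[C] - sh_coord[D]
                    rcd2 = CD[0] ** 2 + CD[1] ** 2 + CD[2] ** 2
                    L = la + lb + lc + ld
                    block = np.zeros((nca, ncb, ncc, ncd))
                    for ip in range(sh_ps[A], sh_ps[A] + sh_pn[A]):
                        a1 = pa[ip]
                        for jp in range(sh_ps[B], sh_ps[B] + sh_pn[B]):
                            a2 = pa[jp]
                            p = a1 + a2
                            Kab = np.exp(-a1 * a2 / p * rab2)
                            P = (a1 * sh_coord[A] + a2 * sh_coord[B]) / p
                            E1x = _e1d(la, lb, P[0] - sh_coord[A][0],
                                       P[0] - sh_coord[B][0], p, 1.0)
                            E1y = _e1d(la, lb, P[1] - sh_coord[A][1],
                                       P[1] - sh_coord[B][1], p, 1.0)
                            E1z = _e1d(la, lb, P[2] - sh_coord[A][2],
                                       P[2] - sh_coord[B][2], p, 1.0)
                            for kp in range(sh_ps[C], sh_ps[C] + sh_pn[C]):
                                a3 = pa[kp]
                                for lp in range(sh_ps[D], sh_ps[D] + sh_pn[D]):
                                    a4 = pa[lp]
                                    q = a3 + a4
                                    Kcd = np.exp(-a3 * a4 / q * rcd2)
                                    Q = (a3 * sh_coord[C] + a4 * sh_coord[D]) / q
                                    E2x = _e1d(lc, ld, Q[0] - sh_coord[C][0],
                                               Q[0] - sh_coord[D][0], q, 1.0)
                                    E2y = _e1d(lc, ld, Q[1] - sh_coord[C][1],
                                               Q[1] - sh_coord[D][1], q, 1.0)
                                    E2z = _e1d(lc, ld, Q[2] - sh_coord[C][2],
                                               Q[2] - sh_coord[D][2], q, 1.0)
                                    al = p * q / (p + q)
                                    R = _rtensor(L, al, P[0] - Q[0],
                                                 P[1] - Q[1], P[2] - Q[2])
                                    pref = 2.0 * np.pi ** 2.5 / \
                                        (p * q * np.sqrt(p + q)) * Kab * Kcd * \
                                        pc[ip] * pc[jp] * pc[kp] * pc[lp]
                                    for ka in range(nca):
                                        i1, j1, k1 = _comp(la, ka)
                                        for kb in range(ncb):
                                            i2, j2, k2 = _comp(lb, kb)
                                            for kc in range(ncc):
                                                i3, j3, k3 = _comp(lc, kc)
                                                for kd in range(ncd):
                                                    i4, j4, k4 = _comp(ld, kd)
                                                    v = 0.0
                                                    for t in range(i1 + i2 + 1):
                                                        for u in range(j1 + j2 + 1):
                                                            for w in range(k1 + k2 + 1):
                                                                e1 = E1x[i1, i2, t] * \
                                                                    E1y[j1, j2, u] * \
                                                                    E1z[k1, k2, w]
                                                                if e1 == 0.0:
                                                                    continue
                                                                for t2 in range(i3 + i4 + 1):
                                                                    for u2 in range(j3 + j4 + 1):
                                                                        for w2 in range(k3 + k4 + 1):
                                                                            e2 = E2x[i3, i4, t2] * \
                                                                                E2y[j3, j4, u2] * \
                                                                                E2z[k3, k4, w2]
                                                                            if e2 == 0.0:
                                                                                continue
                                                                            if (t2 + u2 + w2) % 2 == 1:
                                                                                e2 = -e2
                                                                            v += e1 * e2 * R[t + t2, u + u2, w + w2]
                                                    block[ka, kb, kc, kd] += pref * v
                    oa, ob, oc, od = sh_ao[A], sh_ao[B], sh_ao[C], sh_ao[D]
                    for ka in range(nca):
                        for kb in range(ncb):
                            for kc in range(ncc):
                                for kd in range(ncd):
                                    eri[oa + ka, ob + kb, oc + kc, od + kd] = \
                                        block[ka, kb, kc, kd]
    return eri


# ---------------------------------------------------------------------------
# Python wrappers (apply per-AO normalization)


def _ensure_norm(basis: BasisSet):
    if getattr(basis, "_normalized", False):
        return
    S = _overlap_kinetic_kernel(*basis.packed(), basis.nao)[0]
    basis.ao_norm = 1.0 / np.sqrt(np.diag(S))
    basis._normalized = True


def overlap_kinetic(basis: BasisSet):
    _ensure_norm(basis)
    S, T = _overlap_kinetic_kernel(*basis.packed(), basis.nao)
    n = basis.ao_norm
    return S * np.outer(n, n), T * np.outer(n, n)


def nuclear(basis: BasisSet, atom_coords, atom_charges):
    _ensure_norm(basis)
    V = _nuclear_kernel(*basis.packed(), basis.nao,
                        np.asarray(atom_coords, float),
                        np.asarray(atom_charges, float))
    n = basis.ao_norm
    return V * np.outer(n, n)


def moments(basis: BasisSet, center, emax: int):
    """Stacked moment matrices; component k of order e is (r-C)^(lx,ly,lz)."""
    _ensure_norm(basis)
    ncomp = sum((e + 1) * (e + 2) // 2 for e in range(emax + 1))
    M = _moments_kernel(*basis.packed(), basis.nao,
                        np.asarray(center, float), emax, ncomp)
    n = basis.ao_norm
    return M * np.outer(n, n)[None, :, :]


def moment_components(emax: int):
    """(order, (lx,ly,lz)) labels matching the stacking of :func:`moments`."""
    out = []
    for e in range(emax + 1):
        for lx in range(e, -1, -1):
            for ly in range(e - lx, -1, -1):
                out.append((e, (lx, ly, e - lx - ly)))
    return out


def eri2c(auxbasis: BasisSet):
    _ensure_norm(auxbasis)
    V = _eri2c_kernel(*auxbasis.packed(), auxbasis.nao)
    n = auxbasis.ao_norm
    return V * np.outer(n, n)


def eri3c(basis: BasisSet, auxbasis: BasisSet):
    _ensure_norm(basis)
    _ensure_norm(auxbasis)
    T3 = _eri3c_kernel(*basis.packed(), basis.nao,
                       *auxbasis.packed(), auxbasis.nao)
    n = basis.ao_norm
    T3 *= np.outer(n, n)[:, :, None]
    T3 *= auxbasis.ao_norm[None, None, :]
    return T3


def eri4c(basis: BasisSet):
    _ensure_norm(basis)
    eri = _eri4c_kernel(*basis.packed(), basis.nao)
    n = basis.ao_norm
    return eri * (n[:, None, None, None] * n[None, :, None, None] *
                  n[None, None, :, None] * n[None, None, None, :])
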
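"""Integral engine validated against closed forms, symbolic integration and
finite-difference derivative relations."""

import numpy as np
import pytest
from scipy.special import gamma, gammainc

from rolmp2 import integrals as I
from rolmp2.basis import BasisSet, Shell, _prim_norm


def raw_shell(l, center, alpha):
    """Single unnormalized primitive shell (unit raw coefficient)."""
    return Shell(l, np.array(center, float), np.array([alpha]),
                 np.array([1.0 / _prim_norm(alpha, l)]), atom=0)


def raw_basis(shells):
    b = BasisSet(shells)
    b.ao_norm = np.ones(b.nao)
    b._normalized = True
    return b


def test_boys_function_against_incomplete_gamma():
    Ts = np.array([1e-14, 1e-6, 0.1, 1.0, 8.0, 30.0, 34.9, 35.1, 80.0, 400.0])
    for m in (0, 3, 7, 12):
        out = np.zeros(m + 1)
        for T in Ts:
            I._boys(m, T, out)
            if T < 1e-12:
                ref = 1.0 / (2 * m + 1)
            else:
                a = m + 0.5
                ref = gamma(a) * gammainc(a, T) / (2.0 * T ** a)
            assert abs(out[m] - ref) < 1e-13 * max(1.0, ref)


def test_ssss_eri_closed_form():
    a1, a2, a3, a4 = 0.9, 1.3, 0.7, 1.9
    A = np.array([0.1, 0.2, 0.3])
    B = np.array([0.8, -0.3, 0.5])
    C = np.array([-0.4, 0.6, -0.2])
    D = np.array([0.3, 0.3, 0.9])
    b = raw_basis([raw_shell(0, A, a1), raw_shell(0, B, a2),
                   raw_shell(0, C, a3), raw_shell(0, D, a4)])
    eri = I._eri4c_kernel(*b.packed(), b.nao)
    p, q = a1 + a2, a3 + a4
    P = (a1 * A + a2 * B) / p
    Q = (a3 * C + a4 * D) / q
    boys = np.zeros(1)
    I._boys(0, p * q / (p + q) * np.sum((P - Q) ** 2), boys)
    ref = (2 * np.pi ** 2.5 / (p * q * np.sqrt(p + q))
           * np.exp(-a1 * a2 / p * np.sum((A - B) ** 2))
           * np.exp(-a3 * a4 / q * np.sum((C - D) ** 2)) * boys[0])
    assert abs(eri[0, 1, 2, 3] - ref) < 1e-13


def _quad1d(f):
    x = np.linspace(-9.0, 9.0, 6001)
    return np.trapezoid(f(x), x)


def test_one_electron_integrals_against_quadrature():
    """Overlap, kinetic and moment of a (p_x, d_xz) primitive pair by
    dense separable 1-D quadrature."""
    a1, a2 = 0.8, 1.1
    A = np.array([0.0, 0.1, -0.2])
    B = np.array([0.7, -0.3, 0.4])
    Cm = np.array([0.2, 0.0, 0.1])
    b = raw_basis([raw_shell(1, A, a1), raw_shell(2, B, a2)])
    S, T = I._overlap_kinetic_kernel(*b.packed(), b.nao)
    M = I._moments_kernel(*b.packed(), b.nao, Cm, 2, 10)

    def pair1d(d, i, j, extra=0, csh=None):
        # 1D integral of (x-A)^i (x-B)^j (x-C)^extra exp(-a1(x-A)^2-a2(x-B)^2)
        def f(x):
            v = (x - A[d]) ** i * (x - B[d]) ** j * \
                np.exp(-a1 * (x - A[d]) ** 2 - a2 * (x - B[d]) ** 2)
            if extra:
                v = v * (x - csh[d]) ** extra
            return v
        return _quad1d(f)

    # bra p_x (AO 0); ket d_xz is lexicographic component 2 (xx, xy, xz, ...)
    s_ref = pair1d(0, 1, 1) * pair1d(1, 0, 0) * pair1d(2, 0, 1)
    assert abs(S[0, 3 + 2] - s_ref) < 1e-12

    # kinetic: Laplacian of the ket expanded per dimension
    ket_pows = (1, 0, 1)   # d_xz
    bra_pows = (1, 0, 0)   # p_x
    t_ref = 0.0
    for d in range(3):
        parts = []
        for dd in range(3):
            if dd == d:
                def f(x, dd=dd):
                    xb = x - B[dd]
                    j = ket_pows[dd]
                    poly = (j * (j - 1) * xb ** (j - 2) if j >= 2 else 0.0)
                    poly = poly - 2 * a2 * (2 * j + 1) * xb ** j + \
                        4 * a2 ** 2 * xb ** (j + 2)
                    return (x - A[dd]) ** bra_pows[dd] * poly * \
                        np.exp(-a1 * (x - A[dd]) ** 2 - a2 * xb ** 2)
                parts.append(_quad1d(f))
            else:
                parts.append(pair1d(dd, bra_pows[dd], ket_pows[dd]))
        t_ref += parts[0] * parts[1] * parts[2]
    t_ref *= -0.5
    assert abs(T[0, 3 + 2] - t_ref) < 1e-12

    # moment component (x-Cx)(y-Cy): order-2 lexicographic index 4 + 1
    m_ref = pair1d(0, 1, 1, 1, Cm) * pair1d(1, 0, 0, 1, Cm) * pair1d(2, 0, 1)
    assert abs(M[4 + 1, 0, 3 + 2] - m_ref) < 1e-12


def test_three_center_eri_derivative_relation():
    """(p s|s) equals the center derivative of (s s|s) divided by 2 alpha."""
    aA, aB, aC = 0.9, 1.3, 0.7
    A = [0.1, 0.2, 0.3]
    B = [0.8, -0.3, 0.5]
    C = [-0.4, 0.6, -0.2]
    h = 1e-5

    def e3(Ax):
        bb = raw_basis([raw_shell(0, [Ax, A[1], A[2]], aA),
                        raw_shell(0, B, aB)])
        bx = raw_basis([raw_shell(0, C, aC)])
        return I._eri3c_kernel(*bb.packed(), bb.nao, *bx.packed(), bx.nao)[0, 1, 0]

    num = (e3(A[0] + h) - e3(A[0] - h)) / (2 * h) / (2 * aA)
    bb = raw_basis([raw_shell(1, A, aA), raw_shell(0, B, aB)])
    bx = raw_basis([raw_shell(0, C, aC)])
    T3 = I._eri3c_kernel(*bb.packed(), bb.nao, *bx.packed(), bx.nao)
    assert abs(T3[0, 3, 0] - num) < 1e-8


def test_translation_invariance_of_integrals():
    shells = [raw_shell(0, [0.0, 0.0, 0.0], 1.1),
              raw_shell(1, [0.9, -0.2, 0.4], 0.7),
              raw_shell(2, [-0.5, 0.8, 0.1], 0.5)]
    shift = np.array([3.3, -1.7, 2.9])
    shifted = [raw_shell(sh.l, sh.center + shift, sh.exps[0] * 1.0)
               for sh in shells]
    b1, b2 = raw_basis(shells), raw_basis(list(shifted))
    S1, T1 = I._overlap_kinetic_kernel(*b1.packed(), b1.nao)
    S2, T2 = I._overlap_kinetic_kernel(*b2.packed(), b2.nao)
    assert np.abs(S1 - S2).max() < 1e-13
    assert np.abs(T1 - T2).max() < 1e-13
    E1 = I._eri2c_kernel(*b1.packed(), b1.nao)
    E2 = I._eri2c_kernel(*b2.packed(), b2.nao)
    assert np.abs(E1 - E2).max() < 1e-11


def test_moment_center_shift_relation():
    """Dipole matrices about two centers differ by the overlap times the
    center displacement, componentwise."""
    b = raw_basis([raw_shell(0, [0.0, 0.0, 0.0], 1.0),
                   raw_shell(1, [0.5, 0.5, -0.5], 0.8)])
    C1 = np.zeros(3)
    C2 = np.array([0.3, -0.4, 0.2])
    M1 = I._moments_kernel(*b.packed(), b.nao, C1, 1, 4)
    M2 = I._moments_kernel(*b.packed(), b.nao, C2, 1, 4)
    S = M1[0]
    for k in range(3):
        assert np.abs(M1[1 + k] - M2[1 + k] - (C2 - C1)[k] * S).max() < 1e-12
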
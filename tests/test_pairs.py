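"""Multipole-approximated pair energies and strong/distant classification."""

import numpy as np
import pytest

from rolmp2 import (MolecularSystem, RunConfig, build_local_basis,
                    build_primary_domain, build_reference, classify_pairs,
                    distant_pair_sum, generate_fixture, multipole_interaction,
                    pair_energy, product_moments)
from rolmp2.domains import BPCache
from rolmp2.pairs import OrbitalPair, interaction_kernel


def _pair_list(ref, lb, eps_w=1e-5):
    cache = BPCache(ref.ao_overlap, ref.integrals.basis.ao_atom)
    pds = [build_primary_domain(i, lb, ref, bp_cache=cache)
           for i in range(lb.n_lmo)]
    moms = [product_moments(pd, lb, ref) for pd in pds]
    pairs = []
    for i in range(lb.n_lmo):
        for j in range(i + 1, lb.n_lmo):
            pairs.append(pair_energy(pds[i], pds[j], moms[i], moms[j],
                                     lb, ref))
    return classify_pairs(pairs, eps_w), pds, moms


def test_head_to_tail_unit_dipoles():
    """Two unit z-dipoles separated along z interact as -2/R^3."""
    m1 = np.zeros((1, 20))
    m2 = np.zeros((1, 20))
    m1[0, 3] = 1.0  # order-1 component (0,0,1)
    m2[0, 3] = 1.0
    for R in (5.0, 12.0):
        val = multipole_interaction(m1, m2, np.array([0.0, 0.0, R]))
        assert abs(val[0, 0] - (-2.0 / R ** 3)) < 1e-12


def test_zero_moments_zero_interaction():
    m = np.zeros((3, 20))
    out = multipole_interaction(m, m, np.array([4.0, 0.0, 0.0]))
    assert np.all(out == 0.0)


def test_interaction_invariant_under_rigid_translation():
    """The kernel depends only on the centroid displacement."""
    rng = np.random.default_rng(7)
    m1 = rng.normal(size=(4, 20))
    m2 = rng.normal(size=(5, 20))
    R = np.array([3.0, -2.0, 5.0])
    a = multipole_interaction(m1, m2, R)
    # translating both centers rigidly leaves R and the moments unchanged
    b = m1 @ interaction_kernel(R) @ m2.T
    assert np.abs(a - b).max() < 1e-14


def test_pair_energies_invariant_under_system_translation():
    base = generate_fixture("separated_diradical", basis_name="minimal",
                            separation=6.0, fragment="methyl")
    shift = np.array([3.1, -2.7, 1.9])
    moved = MolecularSystem(
        [(s, tuple(np.asarray(x) + shift)) for s, x in base.atoms],
        base.charge, base.multiplicity, base.basis_name)
    energies = {}
    for tag, sys_ in (("base", base), ("moved", moved)):
        ref = build_reference(sys_, RunConfig())
        lb = build_local_basis(ref)
        pairs, _, _ = _pair_list(ref, lb)
        energies[tag] = np.sort([p.pair_energy for p in pairs])
    assert np.abs(energies["base"] - energies["moved"]).max() <= 1e-10


def test_multipole_vs_exact_integrals_far_h2_dimer():
    """At 15 bohr the multipole (i a|j b) integrals agree with the exact
    density-fitted ones to a few percent."""
    d = 15.0 / 1.8897261254578281
    sys_ = MolecularSystem(
        [("H", (0.0, 0.0, 0.0)), ("H", (0.0, 0.0, 0.741)),
         ("H", (d, 0.0, 0.0)), ("H", (d, 0.0, 0.741))],
        basis_name="minimal", name="h2-dimer")
    ref = build_reference(sys_, RunConfig())
    lb = build_local_basis(ref)
    pairs, pds, moms = _pair_list(ref, lb)
    (p,) = [q for q in pairs if q.distance_angstrom > 4.0]
    i, j = p.i, p.j
    approx = multipole_interaction(moms[i].moments["up"],
                                   moms[j].moments["up"],
                                   moms[i].center - moms[j].center)
    # exact integrals over the same PD orbitals through the fitting tensor
    W = ref.integrals.W
    nao = ref.integrals.nao

    def embed(pd, col):
        v = np.zeros(nao)
        v[pd.ao_idx] = col
        return v

    exact = np.zeros_like(approx)
    for a in range(pds[i].virt_up.shape[1]):
        for b in range(pds[j].virt_up.shape[1]):
            di = np.outer(embed(pds[i], pds[i].occ_lmo[:, 0]),
                          embed(pds[i], pds[i].virt_up[:, a]))
            dj = np.outer(embed(pds[j], pds[j].occ_lmo[:, 0]),
                          embed(pds[j], pds[j].virt_up[:, b]))
            wi = np.tensordot(W, di, axes=([0, 1], [0, 1]))
            wj = np.tensordot(W, dj, axes=([0, 1], [0, 1]))
            exact[a, b] = wi @ wj
    scale = np.abs(exact).max()
    assert scale > 0
    assert np.abs(approx - exact).max() / scale <= 0.05


def test_pair_energy_against_canonical_far_fragments():
    """Interfragment multipole pair energies of a stretched H2...H2 system
    agree with the canonical pair-resolved oracle within 20%."""
    from rolmp2 import reference_pair_energies
    d = 10.0 / 1.8897261254578281
    sys_ = MolecularSystem(
        [("H", (0.0, 0.0, 0.0)), ("H", (0.0, 0.0, 0.741)),
         ("H", (d, 0.0, 0.0)), ("H", (d, 0.0, 0.741))],
        basis_name="minimal", name="h2-dimer")
    ref = build_reference(sys_, RunConfig())
    lb = build_local_basis(ref)
    pairs, _, _ = _pair_list(ref, lb)
    (p,) = [q for q in pairs if q.distance_angstrom > 3.0]
    exact = reference_pair_energies(ref, lb)[p.i, p.j]
    assert p.pair_energy < 0
    assert abs(p.pair_energy - exact) / abs(exact) <= 0.20


def test_spin_block_structure(chain6):
    """SO-SO pairs keep only the up-up block; closed-shell DO-DO pairs
    have equal same- and opposite-spin block sums."""
    sys_, ref = chain6
    lb = build_local_basis(ref)
    pairs, _, _ = _pair_list(ref, lb)
    soso = [p for p in pairs if p.pair_type == "SO-SO"
            and not p.multipole_unreliable]
    assert soso
    for p in soso:
        assert p.e_opposite_spin == 0.0
        assert p.pair_energy == p.e_same_spin <= 0.0
    # closed-shell molecule: all four spin channels identical
    eth = generate_fixture("chain", basis_name="minimal", n=3,
                           closed_shell=True)
    refc = build_reference(eth, RunConfig())
    lbc = build_local_basis(refc)
    cpairs, _, _ = _pair_list(refc, lbc)
    far = [p for p in cpairs if not p.multipole_unreliable]
    assert far
    for p in far:
        assert abs(p.e_same_spin - p.e_opposite_spin) <= 1e-12


def test_classification_thresholds():
    def mk(ptype, e):
        return OrbitalPair(0, 1, ptype, 5.0, e,
                           {"DO-DO": 1.0, "DO-SO": 0.5, "SO-SO": 0.25}[ptype])

    eps = 1e-5
    pairs = classify_pairs([mk("DO-SO", -0.7e-5), mk("DO-DO", -0.7e-5),
                            mk("SO-SO", -0.3e-5)], eps)
    assert pairs[0].classification == "strong"      # 0.7 eps >= eps/2
    assert pairs[1].classification == "distant"     # 0.7 eps < eps
    assert pairs[2].classification == "strong"      # 0.3 eps >= eps/4
    # zero threshold: everything is strong, distant sum vanishes
    allstrong = classify_pairs([mk("DO-DO", -1e-12)], 0.0)
    assert allstrong[0].classification == "strong"
    assert distant_pair_sum(pairs) == pairs[1].pair_energy


def test_distant_sum_monotone_in_threshold(chain6):
    sys_, ref = chain6
    lb = build_local_basis(ref)
    pairs, _, _ = _pair_list(ref, lb)
    sums = []
    for eps in (1e-4, 1e-5, 1e-6):
        classify_pairs(pairs, eps)
        sums.append(abs(distant_pair_sum(pairs)))
    assert sums[0] >= sums[1] >= sums[2]


def test_pair_energy_symmetric(chain6):
    sys_, ref = chain6
    lb = build_local_basis(ref)
    cache = BPCache(ref.ao_overlap, ref.integrals.basis.ao_atom)
    pds = [build_primary_domain(i, lb, ref, bp_cache=cache)
           for i in range(lb.n_lmo)]
    moms = [product_moments(pd, lb, ref) for pd in pds]
    for (i, j) in ((0, 5), (2, 9), (1, 12)):
        a = pair_energy(pds[i], pds[j], moms[i], moms[j], lb, ref)
        b = pair_energy(pds[j], pds[i], moms[j], moms[i], lb, ref)
        assert abs(a.pair_energy - b.pair_energy) <= 1e-12
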
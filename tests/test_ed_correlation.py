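"""Extended-domain integral transformation and correlation energies."""

import numpy as np
import pytest

from rolmp2 import (MolecularSystem, RunConfig, assemble_total,
                    build_extended_domain, build_local_basis,
                    build_reference, canonical_romp2,
                    closed_shell_contribution, ed_energy_contribution,
                    factorize_denominators, generate_fixture, run_lmp2,
                    transform_integrals)
from rolmp2.ed_correlation import PerLMORecord


def _full_ed(ref, lb, cmo=0):
    one = 1.0 - 1e-12
    others = [i for i in range(lb.n_lmo) if i != cmo]
    return build_extended_domain(cmo, others, lb, ref,
                                 ref.integrals.aux.ao_atom, T_EDo=one, T_o=one)


def test_transform_reconstructs_df_integrals(h2o_ref):
    ref = h2o_ref
    lb = build_local_basis(ref)
    ed = _full_ed(ref, lb)
    fit = transform_integrals(ed, ref.integrals)
    # closed shell: both spin tensors identical
    assert np.abs(fit.J_up - fit.J_dn).max() <= 1e-10
    # against an independent dense transformation through the full metric
    W = ref.integrals.W
    nao = ref.integrals.nao
    Cv = np.zeros((nao, ed.virt_up.shape[1]))
    Cv[ed.ao_idx] = ed.virt_up
    Co = np.zeros((nao, len(ed.members)))
    Co[ed.ao_idx] = ed.occ_up
    Bref = np.einsum("mnP,na,mi->aiP", W, Cv, Co, optimize=True)
    K_fit = np.einsum("aiP,bjP->aibj", fit.J_up, fit.J_up)
    K_ref = np.einsum("aiP,bjP->aibj", Bref, Bref)
    assert np.abs(K_fit - K_ref).max() <= 1e-9
    # permutational symmetry of the reconstructed integrals
    assert np.abs(K_fit - K_fit.transpose(2, 3, 0, 1)).max() <= 1e-10


def test_monomer_integrals_are_local():
    """Three-center integrals restricted to one far-separated monomer's
    AO and auxiliary lists equal those of the isolated monomer."""
    from rolmp2.engine import MoleculeIntegrals
    h2o = [("O", (0.0, 0.0, 0.1173)), ("H", (0.0, 0.7572, -0.4692)),
           ("H", (0.0, -0.7572, -0.4692))]
    far = [("He", (30.0, 0.0, 0.0))]
    dimer = MolecularSystem(h2o + far, 0, 1, "minimal", name="dimer")
    mono = MolecularSystem(h2o, 0, 1, "minimal", name="mono")
    mid = MoleculeIntegrals(dimer)
    mim = MoleculeIntegrals(mono)
    nao, naux = mim.nao, mim.naux
    assert np.abs(mid.T3[:nao, :nao, :naux] - mim.T3).max() <= 1e-10
    assert np.abs(mid.V2[:naux, :naux] - mim.V2).max() <= 1e-10


def test_open_shell_full_domain_matches_canonical_components(oh_ref):
    """Per-term check of the six-term ED energy in the untruncated limit."""
    ref = oh_ref
    lb = build_local_basis(ref)
    can = canonical_romp2(ref)
    recs = []
    for c in range(lb.n_lmo):
        ed = _full_ed(ref, lb, c)
        fit = transform_integrals(ed, ref.integrals)
        denom = factorize_denominators([ed.occ_e_up, ed.occ_e_dn],
                                       [ed.virt_e_up, ed.virt_e_dn],
                                       "exact", 0.0)
        recs.append(ed_energy_contribution(ed, fit, denom, ref))
    singles = sum(r.singles for r in recs)
    same = sum(r.same_spin for r in recs)
    opp = sum(r.opposite_spin for r in recs)
    assert abs(singles - can.singles) <= 1e-8
    assert abs(same - can.same_spin) <= 1e-8
    assert abs(opp - can.opposite_spin) <= 1e-8
    # SOMO records carry no spin-down half
    for r in recs:
        if r.is_somo:
            assert r.singles_dn == r.ss_dn == r.os_dn == 0.0


def test_closed_shell_singles_vanish(h2o_ref):
    lb = build_local_basis(h2o_ref)
    ed = _full_ed(h2o_ref, lb)
    fit = transform_integrals(ed, h2o_ref.integrals)
    denom = factorize_denominators([ed.occ_e_up], [ed.virt_e_up], "exact", 0.0)
    rec = ed_energy_contribution(ed, fit, denom, h2o_ref)
    assert abs(rec.singles) <= 1e-12


def test_closed_shell_path_matches_open_shell_per_domain(h2o_ref):
    """On a closed-shell molecule the spin-averaged closed-shell route must
    reproduce the open-shell route ED by ED."""
    ref = h2o_ref
    lb = build_local_basis(ref)
    factory = lambda occ, virt: factorize_denominators(occ, virt,
                                                       "cholesky", 1e-4)
    for c in range(lb.n_lmo):
        ed = _full_ed(ref, lb, c)
        fit = transform_integrals(ed, ref.integrals)
        denom = factorize_denominators([ed.occ_e_up, ed.occ_e_dn],
                                       [ed.virt_e_up, ed.virt_e_dn],
                                       "cholesky", 1e-4)
        open_rec = ed_energy_contribution(ed, fit, denom, ref)
        cs_rec = closed_shell_contribution(ed, ref.integrals, factory, ref)
        assert cs_rec.treated_closed_shell
        assert abs(open_rec.total - cs_rec.total) <= 1e-10


def test_closed_shell_path_rejects_somo_domain(oh_ref):
    lb = build_local_basis(oh_ref)
    ed = _full_ed(oh_ref, lb)
    assert ed.contains_somo
    factory = lambda occ, virt: factorize_denominators(occ, virt,
                                                       "cholesky", 1e-4)
    with pytest.raises(RuntimeError):
        closed_shell_contribution(ed, oh_ref.integrals, factory, oh_ref)


def test_laplace_and_cholesky_paths_agree(radical_refs, radical_systems):
    sys_ = radical_systems["NH2"]
    ref = radical_refs["NH2"]
    a = run_lmp2(sys_, RunConfig(denom_method="cholesky"), reference=ref)
    b = run_lmp2(sys_, RunConfig(denom_method="laplace"), reference=ref)
    assert abs(a.total - b.total) <= 1e-4


def test_closed_shell_ed_fraction_grows_with_chain_length():
    """In a terminal diradical chain the middle of a longer chain is
    farther from both radical ends, so more EDs qualify for the
    closed-shell (spin-polarization) shortcut."""
    fracs = []
    for n in (6, 12):
        sys_ = generate_fixture("chain", basis_name="minimal", n=n)
        res = run_lmp2(sys_, RunConfig())
        fracs.append(res.n_closed_shell_eds / len(res.records))
    assert fracs[1] > fracs[0]


def test_assemble_total_bookkeeping():
    r1 = PerLMORecord(0, False, ss_up=-0.01, ss_dn=-0.01, os_up=-0.02,
                      os_dn=-0.02, singles_up=-0.001)
    r2 = PerLMORecord(1, True, ss_up=-0.005, os_up=-0.007)
    res = assemble_total([r1, r2], [], scs_coefficients=(1.0, 1.0))
    assert abs(res.scs_total - res.total) <= 1e-15
    assert abs(res.total - (r1.total + r2.total)) <= 1e-15
    res2 = assemble_total([r1, r2], [], include_singles=False)
    assert abs(res2.total - (res.total - r1.singles)) <= 1e-15
    with pytest.raises(RuntimeError, match="duplicate"):
        assemble_total([r1, r1], [])


def test_all_frozen_system_has_zero_correlation():
    h2 = MolecularSystem([("H", (0, 0, 0)), ("H", (0, 0, 0.741))],
                         basis_name="minimal", n_frozen_core=1, name="H2")
    res = run_lmp2(h2, RunConfig())
    assert res.total == 0.0
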
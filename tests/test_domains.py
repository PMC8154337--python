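"""Boughton-Pulay lists, primary domains and extended domains."""

import numpy as np
import pytest

from rolmp2 import (MolecularSystem, RunConfig, bp_atom_list,
                    build_extended_domain, build_local_basis,
                    build_primary_domain, build_reference, generate_fixture)


@pytest.fixture(scope="module")
def mixed_doublet():
    """A water molecule and a distant methyl radical in one doublet system:
    LMOs with and without a SOMO in their neighborhood."""
    atoms = [("O", (0.0, 0.0, 0.1173)), ("H", (0.0, 0.7572, -0.4692)),
             ("H", (0.0, -0.7572, -0.4692)),
             ("C", (20.0, 0.0, 0.0)), ("H", (20.0, 1.079, 0.0)),
             ("H", (20.934, -0.539, 0.0)), ("H", (19.066, -0.539, 0.0))]
    sys_ = MolecularSystem(atoms, 0, 2, "svp", name="h2o+ch3")
    ref = build_reference(sys_, RunConfig())
    return sys_, ref, build_local_basis(ref)


def _completeness(orbital, atoms, S, ao_atom):
    idx = np.nonzero(np.isin(ao_atom, list(atoms)))[0]
    Sc = S @ orbital
    x = np.linalg.solve(S[np.ix_(idx, idx)], Sc[idx])
    return float(x @ Sc[idx]) / float(orbital @ Sc)


def test_bp_list_core_orbital_single_atom(oh_ref):
    core = oh_ref.restricted_mos[:, 0]
    bp = bp_atom_list(core, 0.999, oh_ref.ao_overlap,
                      oh_ref.integrals.basis.ao_atom)
    assert bp.atoms == [0]
    assert bp.completeness >= 0.999


def test_bp_list_greedy_minimality_and_nesting():
    """On ethane C-H bond orbitals the looser list nests inside the tighter
    one, the achieved completeness matches an independent evaluation, and
    dropping the last atom falls below the threshold."""
    eth = generate_fixture("chain", basis_name="svp", n=2, closed_shell=True)
    ref = build_reference(eth, RunConfig())
    lb = build_local_basis(ref)
    S, ao_atom = ref.ao_overlap, ref.integrals.basis.ao_atom
    for i in range(lb.n_lmo):
        lo = bp_atom_list(lb.lmo_coeffs[:, i], 0.985, S, ao_atom)
        hi = bp_atom_list(lb.lmo_coeffs[:, i], 0.9999, S, ao_atom)
        assert set(lo.atoms) <= set(hi.atoms)
        for bp, T in ((lo, 0.985), (hi, 0.9999)):
            comp = _completeness(lb.lmo_coeffs[:, i], bp.atoms, S, ao_atom)
            assert abs(comp - bp.completeness) < 1e-10
            assert comp >= T
            if len(bp.atoms) < len(set(ao_atom)):
                # minimality of the greedy prefix
                pops = np.zeros(int(ao_atom.max()) + 1)
                Sc = S @ lb.lmo_coeffs[:, i]
                np.add.at(pops, ao_atom, lb.lmo_coeffs[:, i] * Sc)
                order = list(np.argsort(-pops, kind="stable"))
                prefix = order[:len(bp.atoms) - 1]
                if prefix:
                    assert _completeness(lb.lmo_coeffs[:, i], prefix, S,
                                         ao_atom) < T


def test_bp_threshold_validation(oh_ref):
    with pytest.raises(ValueError):
        bp_atom_list(oh_ref.restricted_mos[:, 0], 1.5, oh_ref.ao_overlap,
                     oh_ref.integrals.basis.ao_atom)


def test_primary_domain_closed_shell_spin_symmetric(h2o_ref):
    lb = build_local_basis(h2o_ref)
    for i in range(lb.n_lmo):
        pd = build_primary_domain(i, lb, h2o_ref)
        assert pd.virt_up.shape == pd.virt_dn.shape
        assert np.abs(pd.virt_e_up - pd.virt_e_dn).max() <= 1e-8


def test_somo_appended_only_when_bp_lists_touch(mixed_doublet):
    _, ref, lb = mixed_doublet
    somo = int(np.nonzero(lb.lmo_is_somo)[0][0])
    water_atoms = {0, 1, 2}
    for i in range(lb.n_lmo):
        if i == somo:
            continue
        pd = build_primary_domain(i, lb, ref)
        on_water = set(pd.atoms) <= water_atoms or \
            (not set(pd.atoms) & {3, 4, 5, 6})
        if on_water:
            assert not pd.somo_members
            assert pd.virt_up.shape[1] == pd.virt_dn.shape[1]
        else:
            assert pd.somo_members == [somo]
            assert pd.virt_dn.shape[1] == pd.virt_up.shape[1] + 1


def test_extended_domain_of_isolated_fragment(mixed_doublet):
    _, ref, lb = mixed_doublet
    water_atoms = {0, 1, 2}
    water_lmos = [i for i in range(lb.n_lmo)
                  if lb.lmo_centers[i, 0] < 10.0 * 1.8897261254578281]
    ed = build_extended_domain(water_lmos[0], water_lmos[1:], lb, ref)
    assert set(ed.atoms) <= water_atoms
    assert not ed.contains_somo


def test_full_molecule_ed_reproduces_semicanonical_energies(oh_ref):
    lb = build_local_basis(oh_ref)
    one = 1.0 - 1e-12
    ed = build_extended_domain(0, list(range(1, lb.n_lmo)), lb, oh_ref,
                               T_EDo=one, T_o=one)
    nfc = oh_ref.n_frozen
    assert np.abs(np.sort(ed.occ_e_up)
                  - np.sort(oh_ref.orb_energies_up[nfc:oh_ref.n_up])).max() \
        <= 1e-8
    assert np.abs(np.sort(ed.virt_e_up)
                  - np.sort(oh_ref.orb_energies_up[oh_ref.n_up:])).max() <= 1e-8
    # spin-down virtual set = PAO span plus the SOMO
    assert ed.virt_dn.shape[1] == ed.virt_up.shape[1] + 1
    assert np.abs(np.sort(ed.virt_e_dn)
                  - np.sort(oh_ref.orb_energies_dn[oh_ref.n_dn:])).max() <= 1e-8


def test_ed_atom_lists_monotone_in_threshold(chain6):
    sys_, ref = chain6
    lb = build_local_basis(ref)
    lo = build_extended_domain(4, [3, 5], lb, ref, T_EDo=0.985, T_o=0.98)
    hi = build_extended_domain(4, [3, 5], lb, ref, T_EDo=0.999, T_o=0.985)
    assert set(lo.atoms) <= set(hi.atoms)
    assert set(lo.pcd_atoms) <= set(hi.pcd_atoms)


def test_truncated_lmos_keep_fidelity(chain6):
    sys_, ref = chain6
    lb = build_local_basis(ref)
    T = 0.9999
    ed = build_extended_domain(4, [3, 5], lb, ref, T_EDo=T, T_o=0.985)
    S = ref.ao_overlap
    for k, m in enumerate(ed.members):
        fid = ed.occ_lmo[:, k] @ (S @ lb.lmo_coeffs[:, m])[ed.ao_idx]
        assert fid ** 2 >= T - 5e-4  # reorthogonalization may cost a little
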
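"""End-to-end driver behavior, fixture generation, CLI and scaling."""

import json
import time

import numpy as np
import pytest
from click.testing import CliRunner

from rolmp2 import (MolecularSystem, RunConfig, build_reference,
                    canonical_romp2, generate_fixture, read_xyz, run_lmp2)
from rolmp2.cli import main as cli_main
from rolmp2.engine import MoleculeIntegrals
from rolmp2.system import InputError


def test_defaults_close_to_tight_limit(radical_systems, radical_refs):
    """Default thresholds deviate from the no-approximation limit by less
    than 0.05% relative on a small doublet."""
    sys_ = radical_systems["CH3"]
    ref = radical_refs["CH3"]
    loose = run_lmp2(sys_, RunConfig(), reference=ref)
    tight = run_lmp2(sys_, RunConfig().tight(), reference=ref)
    assert abs(loose.total - tight.total) / abs(tight.total) < 5e-4


def test_rerun_is_bitwise_deterministic():
    sys_ = generate_fixture("radical_set")[0]  # OH
    totals = []
    for _ in range(2):
        res = run_lmp2(sys_, RunConfig())  # fresh integrals and SCF each time
        totals.append((res.total, res.singles, res.same_spin,
                       res.opposite_spin, res.metadata["scf_energy"]))
    assert totals[0] == totals[1]


def test_report_contains_stage_statistics(oh_ref, radical_systems):
    from rolmp2 import report_lines
    res = run_lmp2(radical_systems["OH"], RunConfig(run_oracle=True),
                   reference=oh_ref)
    m = res.metadata
    assert set(m["times"]) >= {"localization", "pair_energies",
                               "integral_transformation",
                               "amplitudes_energy"}
    assert 0.0 < m["strong_pairs_percent"] <= 100.0
    assert "oracle" in m
    text = "\n".join(report_lines(res))
    assert "corr_total" in text and "strong_pairs_pc" in text


def test_fixture_determinism_and_jitter():
    a = generate_fixture("chain", n=4, seed=3, jitter=0.02)
    b = generate_fixture("chain", n=4, seed=3, jitter=0.02)
    c = generate_fixture("chain", n=4, seed=4, jitter=0.02)
    assert a.to_xyz() == b.to_xyz()
    assert a.to_xyz() != c.to_xyz()


def test_chain_ao_count_grows_linearly():
    naos = []
    for n in (4, 6, 8):
        sys_ = generate_fixture("chain", basis_name="minimal", n=n)
        naos.append(MoleculeIntegrals(sys_).nao)
    assert naos[1] - naos[0] == naos[2] - naos[1]


def test_invalid_fixture_parameters():
    with pytest.raises(InputError):
        generate_fixture("separated_diradical", separation=-1.0)
    with pytest.raises(InputError):
        generate_fixture("nonsense")


def test_xyz_roundtrip(tmp_path):
    sys_ = generate_fixture("radical_set")[2]  # CH3
    p = tmp_path / "mol.xyz"
    p.write_text(sys_.to_xyz())
    back = read_xyz(p, charge=0, multiplicity=2, basis_name="svp")
    assert back.symbols == sys_.symbols
    assert np.abs(back.coords - sys_.coords).max() < 1e-7


def test_cli_end_to_end(tmp_path):
    sys_ = MolecularSystem([("O", (0, 0, 0.1173)),
                            ("H", (0, 0.7572, -0.4692)),
                            ("H", (0, -0.7572, -0.4692))],
                           basis_name="minimal", name="water")
    xyz = tmp_path / "h2o.xyz"
    xyz.write_text(sys_.to_xyz())
    out = tmp_path / "result.json"
    runner = CliRunner()
    r = runner.invoke(cli_main, [str(xyz), "--basis", "minimal", "--oracle",
                                 "--output", str(out)])
    assert r.exit_code == 0, r.output
    assert "corr_total" in r.output
    payload = json.loads(out.read_text())
    assert payload["correlation_energy"] < 0
    assert abs(payload["metadata"]["oracle"]["deviation"]) < 1e-4


def test_near_linear_scaling_on_chains():
    """With domain thresholds commensurate with the minimal basis, the
    LMP2-stage time grows sub-quadratically with chain length."""
    cfg = RunConfig(eps_w=1e-4, T_PDo=0.985, T_PDv=0.97, T_EDo=0.985,
                    T_o=0.98)
    ns, ts = [], []
    # warm-up run so compilation and BLAS initialization are excluded
    warm = generate_fixture("chain", basis_name="minimal", n=3)
    run_lmp2(warm, cfg, reference=build_reference(warm, RunConfig()))
    for n in (4, 8, 12):
        sys_ = generate_fixture("chain", basis_name="minimal", n=n)
        ref = build_reference(sys_, RunConfig())
        stage = []
        for _ in range(2):  # best of two, to damp scheduler noise
            res = run_lmp2(sys_, cfg, reference=ref)
            stage.append(sum(v for k, v in res.metadata["times"].items()
                             if k != "scf_reference"))
        ns.append(n)
        ts.append(min(stage))
    slope = np.polyfit(np.log(ns), np.log(ts), 1)[0]
    assert slope < 1.5, (ns, ts, slope)


def test_threshold_convergence_toward_oracle(chain6):
    """Tightening the ED completeness threshold converges the corrected
    total monotonically; tightening the pair threshold shrinks both the
    raw domain-truncation error and the distant-pair estimate, and the
    estimate always improves the total."""
    from dataclasses import replace
    sys_, ref = chain6
    can = canonical_romp2(ref).total
    tight = RunConfig().tight()
    errs_T = []
    for tedo in (1 - 1e-3, 1 - 1e-4, 1 - 1e-5):
        r = run_lmp2(sys_, replace(tight, T_EDo=tedo, T_o=tedo, eps_w=0.0),
                     reference=ref)
        errs_T.append(abs(r.total - can))
    assert errs_T[0] >= errs_T[1] >= errs_T[2]
    raw_errs, cor_errs, dsums = [], [], []
    for ew in (1e-4, 1e-5, 1e-6):
        r = run_lmp2(sys_, replace(tight, eps_w=ew), reference=ref)
        raw_errs.append(abs(r.total - r.distant_pair_sum - can))
        cor_errs.append(abs(r.total - can))
        dsums.append(abs(r.distant_pair_sum))
    assert raw_errs[0] >= raw_errs[1] >= raw_errs[2]
    assert dsums[0] >= dsums[1] >= dsums[2]
    for raw, cor in zip(raw_errs, cor_errs):
        assert cor <= raw
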
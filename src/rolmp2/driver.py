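"""End-to-end orchestration of an open-shell local MP2 calculation."""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np

from .denominators import factorize_denominators
from .domains import build_extended_domain, build_primary_domain
from .ed_correlation import (CorrelationResult, assemble_total,
                             closed_shell_contribution,
                             ed_energy_contribution, transform_integrals)
from .engine import MoleculeIntegrals
from .localization import build_local_basis
from .oracle import canonical_romp2
from .pairs import (OrbitalPair, classify_pairs, distant_pair_sum,
                    pair_energy, product_moments)
from .reference import (RestrictedReference, build_qro_reference,
                        build_rohf_reference)
from .scf import uhf
from .system import MolecularSystem


@dataclass
class RunConfig:
    """Thresholds and toggles; the defaults are the Normal settings."""

    eps_w: float = 1e-5        # strong-pair threshold, E_h
    T_PDo: float = 0.999       # BP completeness, PD occupied
    T_PDv: float = 0.98        # BP completeness, PD virtual (PAOs, SOMOs)
    T_EDo: float = 0.9999      # BP completeness, ED occupied
    T_o: float = 0.985         # BP completeness, PAO center domain
    denom_method: str = "cholesky"   # cholesky | laplace | exact
    denom_tol: float = 1e-4
    lindep: float = 1e-6
    spinpol_approx: bool = True      # closed-shell formulas in SOMO-free EDs
    scs: tuple = (6.0 / 5.0, 1.0 / 3.0)
    include_singles: bool = True
    reference_kind: str = "ROHF"     # ROHF | QRO
    run_oracle: bool = False

    def tight(self) -> "RunConfig":
        """The no-approximation limit of every local threshold."""
        one = 1.0 - 1e-12
        return replace(self, eps_w=0.0, T_PDo=one, T_PDv=one, T_EDo=one,
                       T_o=one, denom_method="exact", spinpol_approx=False)


def build_reference(system: MolecularSystem, config: RunConfig,
                    mi: MoleculeIntegrals | None = None) -> RestrictedReference:
    mi = mi or MoleculeIntegrals(system)
    if config.reference_kind.upper() == "QRO":
        u = uhf(mi)
        return build_qro_reference(system, u.dm_up + u.dm_dn, mi)
    return build_rohf_reference(system, mi)


def run_lmp2(system: MolecularSystem, config: RunConfig | None = None,
             reference: RestrictedReference | None = None) -> CorrelationResult:
    """SCF/reference -> localization -> PAOs -> PDs & pair energies ->
    classification -> EDs -> per-ED energies -> assembly."""
    config = config or RunConfig()
    times = {}
    t0 = time.perf_counter()
    ref = reference or build_reference(system, config)
    mi = ref.integrals
    times["scf_reference"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    lb = build_local_basis(ref)
    times["localization"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    from .domains import BPCache
    bp_cache = BPCache(mi.S, mi.basis.ao_atom)
    n = lb.n_lmo
    pds = [build_primary_domain(i, lb, ref, config.T_PDo, config.T_PDv,
                                config.lindep, bp_cache) for i in range(n)]
    moms = [product_moments(pd, lb, ref) for pd in pds]
    pairs: list[OrbitalPair] = []
    for i in range(n):
        for j in range(i + 1, n):
            pairs.append(pair_energy(pds[i], pds[j], moms[i], moms[j], lb, ref))
    classify_pairs(pairs, config.eps_w)
    times["pair_energies"] = time.perf_counter() - t0

    strong_partners = {i: [] for i in range(n)}
    for p in pairs:
        if p.classification == "strong":
            strong_partners[p.i].append(p.j)
            strong_partners[p.j].append(p.i)

    t0 = time.perf_counter()
    aux_atom = mi.aux.ao_atom
    records = []
    ed_sizes = []
    t_int = 0.0
    for i in range(n):
        ed = build_extended_domain(i, strong_partners[i], lb, ref, aux_atom,
                                   config.T_EDo, config.T_o, config.lindep,
                                   bp_cache)
        ed_sizes.append((len(ed.atoms), len(ed.ao_idx), len(ed.aux_idx),
                         ed.virt_up.shape[1]))
        if config.spinpol_approx and not ed.contains_somo:
            factory = lambda occ, virt: factorize_denominators(
                occ, virt, config.denom_method, config.denom_tol)
            records.append(closed_shell_contribution(ed, mi, factory, ref))
        else:
            t1 = time.perf_counter()
            fit = transform_integrals(ed, mi)
            t_int += time.perf_counter() - t1
            denom = factorize_denominators(
                [ed.occ_e_up, ed.occ_e_dn], [ed.virt_e_up, ed.virt_e_dn],
                config.denom_method, config.denom_tol)
            records.append(ed_energy_contribution(ed, fit, denom, ref))
    times["integral_transformation"] = t_int
    times["amplitudes_energy"] = time.perf_counter() - t0 - t_int

    n_strong = sum(p.classification == "strong" for p in pairs)
    meta = {
        "system": system.name or "",
        "reference": ref.summary(),
        "n_lmo": n,
        "n_pairs": len(pairs),
        "strong_pairs_percent":
            100.0 * (n_strong + n) / (len(pairs) + n) if pairs else 100.0,
        "pair_counts": {
            t: sum(1 for p in pairs if p.pair_type == t)
            for t in ("DO-DO", "DO-SO", "SO-SO")},
        "distant_pair_sum": distant_pair_sum(pairs),
        "ed_stats": {
            "atoms_avg": float(np.mean([s[0] for s in ed_sizes])),
            "atoms_max": int(max(s[0] for s in ed_sizes)),
            "aos_avg": float(np.mean([s[1] for s in ed_sizes])),
            "aux_avg": float(np.mean([s[2] for s in ed_sizes])),
            "paos_avg": float(np.mean([s[3] for s in ed_sizes])),
        } if ed_sizes else {},
        "times": times,
        "scf_energy": ref.scf_energy,
    }
    result = assemble_total(records, pairs, config.scs,
                            config.include_singles, meta)
    result.metadata["lmp2_energy"] = ref.scf_energy + result.total
    if config.run_oracle:
        t0 = time.perf_counter()
        can = canonical_romp2(ref)
        times["oracle"] = time.perf_counter() - t0
        result.metadata["oracle"] = {
            "singles": can.singles, "same_spin": can.same_spin,
            "opposite_spin": can.opposite_spin, "total": can.total,
            "deviation": result.total - can.total,
            "relative_deviation_percent":
                100.0 * (result.total - can.total) / can.total,
        }
    return result


def report_lines(result: CorrelationResult) -> list[str]:
    """Human-readable run summary (machine data lives in the metadata)."""
    m = result.metadata
    ref = m.get("reference", {})
    lines = [
        f"reference_kind   {ref.get('reference_kind', '?')}",
        f"scf_energy       {m.get('scf_energy', float('nan')):.10f}",
        f"n_lmo            {m.get('n_lmo', 0)}",
        f"n_somo           {ref.get('n_somo', 0)}",
        f"strong_pairs_pc  {m.get('strong_pairs_percent', 0.0):.1f}",
        f"closed_shell_eds {result.n_closed_shell_eds}",
        f"distant_pair_sum {result.distant_pair_sum:.10f}",
        f"singles          {result.singles:.10f}",
        f"same_spin        {result.same_spin:.10f}",
        f"opposite_spin    {result.opposite_spin:.10f}",
        f"corr_total       {result.total:.10f}",
        f"scs_total        {result.scs_total:.10f}",
        f"lmp2_energy      {m.get('lmp2_energy', float('nan')):.10f}",
    ]
    if "oracle" in m:
        o = m["oracle"]
        lines += [
            f"oracle_total     {o['total']:.10f}",
            f"oracle_dev       {o['deviation']:.3e}",
            f"oracle_dev_pc    {o['relative_deviation_percent']:.5f}",
        ]
    for stage, t in m.get("times", {}).items():
        lines.append(f"time_{stage:<24s} {t:8.2f} s")
    return lines
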
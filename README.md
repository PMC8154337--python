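# rolmp2 — local MP2 for high-spin open-shell molecules

`rolmp2` computes second-order Møller–Plesset (MP2) correlation energies
for radicals, diradicals and other high-spin open-shell molecules from a
restricted open-shell (ROHF or quasi-restricted-orbital) reference, using
local-correlation approximations.  It is aimed at method developers and
computational chemists who want a transparent, fully self-contained
implementation of the restricted open-shell local MP2 machinery — localized
orbitals, projected atomic orbitals, orbital domains, multipole-screened
pair energies, density fitting, factorized energy denominators, and a
long-range spin-polarization shortcut — together with a brute-force
canonical oracle to validate every approximation against.

## The model

A high-spin restricted determinant with doubly occupied orbitals (DOMOs)
and singly occupied orbitals (SOMOs) defines spin-up and spin-down Fock
matrices (the spin-down one lacks the SOMO exchange).  After diagonalizing
the occupied and virtual blocks of each spin separately (semicanonical
orbitals, energies ε), the correlation energy is the unrestricted MP2
expression

E_c = Σ_{ia} |f_i^a|²/(ε_i−ε_a) + Σ_{IA} |f_I^A|²/(ε_I−ε_A)
    + ¼ Σ |⟨ab‖ij⟩|²/Δ + ¼ Σ |⟨AB‖IJ⟩|²/Δ + Σ |⟨aB|iJ⟩|²/Δ,

with lower/upper case for spin-up/down and Δ the positive orbital-energy
denominator.  The singles terms are nonzero because an ROHF reference does
not satisfy the unrestricted Brillouin condition.  The expression is
invariant under separate unitary rotations of occupied and virtual spaces,
so one occupied index of every term can be transformed to Boys-localized
restricted orbitals and the energy splits into per-LMO contributions

E_c = Σ_ī δE_ī(extended domain) + Σ_{distant pairs} δε_{īj̄}(multipole),

each δE evaluated in a compact extended domain (the LMO, its strong pairs,
and local projected atomic orbitals) with density-fitted integrals and
Cholesky/Laplace-factorized denominators; pairs are classified strong or
distant by multipole-estimated pair energies against the threshold
f_w·ε_w, where f_w = 1, ½, ¼ for DO–DO, DO–SO, SO–SO pairs compensates the
reduced term count of SOMO pairs.  Extended domains containing no SOMO can
be evaluated with closed-shell formulas after spin-averaged Fock
canonicalization (long-range spin-polarization approximation).  See
`docs/methods.md` for the full account.

Everything is self-contained: Gaussian basis sets are generated
programmatically (minimal, split-valence `sv`, polarized `svp`, plus
automatic even-tempered auxiliary sets), and molecular integrals come from
a numba-compiled McMurchie–Davidson engine.  Supported elements: H–Ne.

## Worked example

```python
from rolmp2 import MolecularSystem, RunConfig, report_lines, run_lmp2

oh = MolecularSystem([("O", (0, 0, 0)), ("H", (0, 0, 0.97))],
                     multiplicity=2, basis_name="svp", name="OH")
result = run_lmp2(oh, RunConfig(run_oracle=True))
print("\n".join(report_lines(result)))
```

prints (`examples/run_radical.py`):

```
reference_kind   ROHF
scf_energy       -74.4474483376
n_lmo            4
n_somo           1
strong_pairs_pc  100.0
...
singles          -0.0030527260
same_spin        -0.0364579856
opposite_spin    -0.1012368297
corr_total       -0.1407475413
scs_total        -0.1366895835
lmp2_energy      -74.5881958789
oracle_total     -0.1407490406
oracle_dev       1.499e-06
oracle_dev_pc    -0.00107
```

The hydroxyl radical's correlation energy (−0.14075 E_h) splits into the
singles contribution driven by the ROHF occupied–virtual Fock coupling and
separately bookkept same-/opposite-spin doubles (ready for spin-component
scaling); `oracle_dev` shows the local result sitting 1.5×10⁻⁶ E_h
(0.001%) from the approximation-free canonical RO-MP2 energy computed by
the built-in brute-force oracle.  For a molecule this small every pair is
strong, so the deviation is pure domain-truncation and denominator-
factorization error.

A thin command-line interface wraps the same pipeline:

```sh
rolmp2 molecule.xyz --charge 0 --mult 2 --basis svp --oracle --scs
```

The `examples/` directory holds one short script per capability (radical
energies vs. the oracle, closed-shell equivalence, pair classification,
the spin-polarization shortcut, quasi-restricted orbitals, denominator
factorization).

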
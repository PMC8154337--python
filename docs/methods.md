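# Methods

`rolmp2` computes second-order Møller–Plesset (MP2) correlation energies for
high-spin open-shell molecules from a restricted open-shell reference, using
local-correlation approximations that make the cost of each orbital's
contribution asymptotically independent of system size.  This note records
the model, the numerical choices, and what the bundled synthetic fixtures do
and do not demonstrate.

## Reference and canonical energy expression

A restricted open-shell determinant with doubly occupied MOs (DOMOs) and
singly occupied MOs (SOMOs, conventionally spin-up) defines two Fock
matrices: the spin-up one sees the DOMO+SOMO density in its exchange term,
the spin-down one only the DOMO density.  Diagonalizing the occupied and
virtual blocks of each spin's Fock matrix separately ("semicanonical"
orbitals) enables a non-iterative, unrestricted MP2 energy with five term
groups: two singles sums Σ |f_i^a|²/(ε_i−ε_a) per spin (nonzero because an
ROHF reference does not satisfy the unrestricted Brillouin condition), two
same-spin doubles sums with antisymmetrized integrals ⟨ab||ij⟩, and one
opposite-spin doubles sum.  For a closed-shell molecule this reduces exactly
to closed-shell MP2.  The expression is invariant under separate unitary
rotations of the occupied and virtual sets, which is what permits localized
occupied orbitals.

When a restricted SCF solution is hard to converge, quasi-restricted
orbitals (QROs) are built as eigenvectors of the spin-summed unrestricted
density; the top n_domo by occupation become doubly, the next n_somo singly
occupied.  The QRO determinant is an exact S² eigenfunction and is used
exactly like an ROHF reference; its energy lies at or above the variational
restricted energy.

## Local decomposition

The energy is decomposed into per-LMO contributions by transforming one
occupied index of every term to Boys-localized restricted orbitals (DOMOs
and SOMOs localized separately; the correlated DOMOs never mix with frozen
cores or SOMOs).  Because only one occupied index is localized, the full
permutational symmetry of the amplitudes is lost and a doubly occupied LMO
carries six terms (two singles, two same-spin, two opposite-spin); a SOMO
carries only the spin-up half.

The virtual space is spanned redundantly by projected atomic orbitals
(PAOs), one per AO, projected against everything occupied in the spin-up
determinant.  SOMOs play a dual role: occupied in spin-up, and appended to
the PAO set to complete the spin-down unoccupied space.

* **Primary domains (PDs)** provide cheap multipole estimates of all pair
  correlation energies.  Coulomb integrals (ia|jb) between two LMO–virtual
  product densities are expanded about the LMO Boys centroids in interaction
  orders R⁻³–R⁻⁵ (dipole–dipole through quadrupole–quadrupole and
  dipole–octopole); the product monopoles vanish because PD virtuals are
  orthogonalized against their LMO.  The pair energy sums Coulomb-only spin
  blocks with denominators ε_a+ε_b−F_ii−F_jj; blocks involving the
  spin-down channel of a SOMO are absent, so SOMO pairs carry fewer terms.
  Pairs closer than 1 Å are classified strong unconditionally (the
  expansion is invalid at overlap).
* **Classification.**  A pair is strong when |δε| ≥ f_w·ε_w with
  f_w = 1, 1/2, 1/4 for DO–DO, DO–SO, SO–SO pairs, compensating the reduced
  term count; distant pairs contribute their multipole estimate directly to
  the total.  Default ε_w = 10⁻⁵ E_h.
* **Extended domains (EDs)** host the main contribution of each LMO.  The
  occupied set is the central LMO plus its strong pairs, each truncated to
  its Boughton–Pulay (BP) atom list at completeness T_EDo = 0.9999 and
  reorthogonalized; the virtual set is the PAOs of the PAO-center domain
  (BP lists at T_o = 0.985), projected onto the ED AO basis, orthogonalized
  and pseudocanonicalized per spin.  Auxiliary functions live on the
  PAO-center atoms.  PD construction uses T_PDo = 0.999 / T_PDv = 0.98.

BP lists are built greedily over atoms ranked by *absolute* Mulliken
population (signed populations can rank a genuinely participating atom with
a small negative charge below zero-weight distant atoms, stalling the
greedy); completeness is measured as the metric overlap of the projected
orbital with the original.

### Virtual-space orthogonalization

Truncated PAOs of boundary atoms can linearly combine into directions with
large weight on occupied orbitals that straddle the domain boundary; after
symmetric orthonormalization such directions acquire occupied-range Fock
eigenvalues and break the positivity of MP2 denominators.  The virtual
candidates are therefore Gram–Schmidt-orthogonalized against (i) the
domain's own occupied set and (ii) a local guard: the in-domain projections
of every orbital occupied in the relevant spin (plus SOMOs excluded from
that spin's virtual set) carrying more than 2% of their norm inside the
domain, excluding the small truncation tails of the domain's own occupied
members (projecting against normalized tails would destroy genuine virtual
dimensions).  A symmetric orthonormalization with elimination of
near-null combinations (overlap eigenvalues < 10⁻⁶) follows.  This is one
concrete realization of the combined Gram–Schmidt/Löwdin scheme; in the
untruncated limit it is exact and inactive.

## Amplitudes and denominators

Within an ED, three-center integrals are generated over the ED's AO and
auxiliary lists only and half-transformed first to the *restricted* LMO
basis (shared by both spins — the cost-critical step), then to the
per-spin virtual and pseudocanonical occupied bases; the two-center metric
is Cholesky-decomposed (eigenvalue filtering on near-singular auxiliary
sets).  Energy denominators are factorized into separable weights over a
single spin-merged gap range so all four spin cases share one set:

* `cholesky` (default): pivoted Cholesky of the kernel 1/(x+y) on the grid
  of occurring gaps, stopped at a diagonal residual below 10⁻⁴; for a PSD
  kernel the off-diagonal residuals obey the same bound.
* `laplace`: non-negative least-squares exponential quadrature of 1/D on a
  logarithmic grid of the merged denominator range, to the same tolerance.
* `exact`: explicit denominators, used for no-approximation-limit checks.

Singles are evaluated exclusively from the off-diagonal part F^OD of the
semicanonical Fock matrices (F minus the AO back-transform of the diagonal
orbital energies, precomputed for the whole molecule).  Inside a truncated
ED the projected orbitals are slightly contaminated by the complementary
space, and the dominant diagonal Fock elements would convert that
contamination into a spurious singles energy; F^OD removes the diagonal and
with it the bulk of the artifact while leaving the exact limit intact.

## Long-range spin polarization

EDs without any SOMO member feel the SOMOs only through the slightly split
spin Fock matrices.  By default such EDs are evaluated with closed-shell
formulas after canonicalizing with the spin-averaged Fock matrix — one
orbital set, one integral tensor, and roughly a third of the doubles
operations.  The spin-resolved F^OD blocks are kept for the singles, so the
approximation touches only the orbital-energy splitting.  On the bundled
separated-diradical fixture the relative error is ~10⁻⁶ %, and for closed-
shell molecules the path is exact (the averaging is a no-op), which is also
how the closed-shell equivalence of the whole method is verified.

Spin-component scaling is bookkept per LMO (up–up and down–down doubles are
same-spin, the two mixed terms opposite-spin; distant-pair estimates carry
the same split), with SCS defaults c_os = 6/5, c_ss = 1/3; singles are never
scaled and can be excluded altogether for double-hybrid-style use.

## Basis sets and integrals

No external basis-set data is shipped.  Orbital bases are generated
programmatically from Slater-rule exponents (hydrogen 1s scaled by the
standard molecular factor 1.24) and the universal three-Gaussian expansion
of Slater 1s/2s/2p orbitals: `minimal`, split-valence `sv`, and polarized
`svp` (+p on H with exponent 1.1, +d on heavy atoms with 0.8 — the
customary first-row polarization exponents).  Auxiliary sets are
even-tempered (ratio 2.6) spans of twice the orbital exponent range per
element, with angular momenta up to d; on a minimal-basis H₂ the density-
fitted MP2 energy agrees with explicit four-index integrals to ~2×10⁻⁹ E_h.
All integrals (overlap, kinetic, nuclear, Cartesian moments to third order,
and two-/three-/four-center repulsion integrals) come from a numba-compiled
McMurchie–Davidson engine validated against closed forms, quadrature and
derivative relations.  The SCF backend (RHF/UHF/ROHF with density fitting,
Roothaan effective-Fock coupling and DIIS) is part of the package.

## Fixtures: what they show and what they do not

The synthetic generator produces (i) a set of six small radicals (OH, NH₂,
CH₃, triplet CH₂, HCO, vinyl) and four singlets at fixed standard
geometries, in `svp` by default — matching the polarized double-zeta
conditions under which the local thresholds were designed; (ii) separated
alkyl diradicals (one SOMO per fragment, high-spin coupled) with the
fragment length and separation as parameters — hexyl at 10 Å by default, so
that both SOMO-containing and SOMO-free extended domains occur; (iii)
quasi-linear terminal-diradical alkane chains of scalable length.  A seeded
Gaussian jitter decorrelates conformers deterministically.

Passing the bundled checks demonstrates internal consistency of the local
approximations against the package's own canonical oracle at desk scale
(≤ ~45 atoms, ≤ ~250 AOs); it does not demonstrate accuracy with large
polarized basis sets, diffuse functions, transition metals, or the
multi-hundred-atom regime where the approximations operate at full
strength.  Two scale effects deserve explicit mention:

* **Domain saturation.**  At the default thresholds the BP lists of these
  small systems legitimately span most of the molecule (the method only
  truncates aggressively beyond ~100 atoms), and in the `minimal` basis
  completeness beyond ~0.99 is unreachable on local atom subsets at all (a
  representational cliff of the basis).  The near-linear-scaling
  demonstration therefore uses thresholds commensurate with that basis
  (T_PDo = T_EDo = 0.985, T_PDv = 0.97, T_o = 0.98, ε_w = 10⁻⁴) on chains
  of 4–12 carbons, where stage costs saturate and the fitted log–log slope
  falls below 1.5.
* **Error cancellation.**  The distant-pair estimate recovers most of the
  energy of the pairs it replaces, so the *corrected* total error is not a
  monotone function of ε_w at this scale, while the raw domain-truncation
  error and the magnitude of the distant-pair sum are; the convergence test
  asserts exactly that, plus monotone convergence in T_EDo.

## Numerical choices

* Boys localization by Jacobi 2×2 sweeps in input order, convergence when
  the largest rotation angle < 10⁻⁸ rad; orbital phases fixed by making the
  largest-magnitude coefficient positive.  Eigenvector phases of every
  (pseudo)canonicalization are fixed the same way, and for closed-shell
  references the spin-down quantities reuse the spin-up computation, so
  reruns are bitwise identical and the spin channels exactly coincide.
* Linear-dependence cutoff 10⁻⁶ in all Löwdin eliminations; fitting-metric
  eigenvalue screening at 10⁻¹⁰ relative.
* Frozen cores: the chemical core (1s for Li–Ne); frozen orbitals are
  excluded from localization and correlation but included in the PAO
  projector, and never mix with correlated orbitals during
  semicanonicalization.
* Everything internal is in atomic units; XYZ input is in Å.

## Known limitations

Elements H–Ne only (no effective cores, no third row); no point-group
symmetry, checkpointing, or shared-memory parallelism; the brute-force
canonical reference scales as the fifth power of system size and is meant
for ≤ ~25 atoms; restricted open-shell Kohn–Sham references are accepted
in principle by the same code path but no density functionals are
implemented, so in practice the reference is ROHF or QRO(UHF).
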
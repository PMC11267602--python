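# Methods

## The measure

`csmeasure` computes continuous symmetry measures (CSM) and the continuous
chirality measure (CCM) of molecular structures.  Given centered Cartesian
coordinates P₁…P_N (Å) and a cyclic point group G, the CSM is

    S(G) = 100 · min  Σᵢ ‖Pᵢ − Qᵢ‖² / Σᵢ ‖Pᵢ‖²

where the minimum runs over all structures Q that are exactly G-symmetric
under some admissible atom permutation.  S is dimensionless: 0 means the
structure already has the symmetry, 100 corresponds to the maximal
reference distortion (the symmetrization collapsing every atom to the
origin).  The CCM is the minimum of S over the achiral cyclic groups
S1 (= Cs), S2 (= Ci), S4, S6, … up to a cutoff `sn_max`; it vanishes iff
the structure is achiral.

Supported groups are the cyclic ones: Cn (proper n-fold rotation, n ≥ 2),
Sn (rotoreflection, even n ≥ 4), Cs (mirror) and Ci (inversion).  Cs and
Ci are handled internally as S1 and S2, so a single improper-generator
code path serves all reflective groups.  Non-cyclic groups (Cnv, Dn, Td,
…) are out of scope; a cyclic subgroup plus a user-supplied permutation
covers the common practical cases.

## Fixed permutation: projection and the nearest structure

For a permutation σ whose cycle lengths divide the group order h, the
operator T : P ↦ G⁻¹P_σ is orthogonal on ℝ^{3N} with T^h = I.  The
nearest σ-compatible G-symmetric structure is the orthogonal projection
of P onto the fixed subspace of T, i.e. the group average

    Qᵢ = (1/h) Σ_{k=0}^{h−1} G^{−k} P_{σᵏ(i)} .

Projection gives Σ‖P−Q‖² = Σ‖P‖² − Σ‖Q‖², hence

    S/100 = 1 − f(m) / (h Σ‖P‖²),   f(m) = Σ_k Σ_i ⟨Pᵢ, G(m)^{−k} P_{σᵏ(i)}⟩,

with m the unit axis of the generator.  Because every power of the
generator has the Rodrigues form c·I + s·[m]ₓ + t·mmᵀ (t differing
between proper and improper powers), f is a quadratic-plus-linear form

    f(m) = const + B·m + mᵀC m .

## Axis optimization

Maximizing f over the unit sphere is the classic trust-region subproblem:
the stationary condition 2Cm + B = 2λm with λ ≥ λ_max(C) identifies the
global maximum.  In the eigenbasis of C the secular equation
Σ bᵢ²/(2(λ−λᵢ))² = 1 is solved by bracketed root finding
(`scipy.optimize.brentq`, bracket [λ_max + ‖b_top‖/2, λ_max + ‖b‖/2]);
the degenerate "hard case" (B orthogonal to the top eigenspace) is solved
explicitly in the complementary subspace.  When B and C both vanish (pure
inversion) the axis is immaterial and ẑ is reported.  Axes are reported
with the first non-negligible component positive; for n > 2 a sign flip
replaces the generator by its inverse, which pairs with the inverse
permutation — the pair (σ, −m) ≡ (σ⁻¹, m) is adjusted jointly so that
value, permutation, operation and nearest structure stay mutually
consistent.  The test suite cross-checks this analytic path against an
independent dense-grid + Nelder-Mead sphere search to 10⁻⁶.

## Exact search

`exact_csm` enumerates permutations class-by-class as products of cycles
whose lengths divide h, in a fixed order (classes ascending by smallest
atom index; cycle lengths ascending; cycle members lexicographic), so
ties between equal-valued permutations always resolve to the first found.
Equivalence classes are element-based by default; `ignore_sym` collapses
them to one class (a pure shape descriptor).  With `keep_structure` only
bond-graph automorphisms are admitted: a partial cycle is abandoned as
soon as an already-assigned bonded pair maps to a non-bonded pair (or
vice versa), and the classes are pre-refined by iterative neighbour-colour
(Weisfeiler–Lehman style) propagation — sound, because an automorphism
can never exchange atoms with different stable colours.  The scan carries
a configurable time budget (default 300 s) and reports the number of
permutations examined when it gives up.

## Approximate search

`approx_csm` alternates two steps from each start direction: (1) build a
permutation by assigning every rotated atom G·Pᵢ to a nearest atom of the
same equivalence class — minimum-cost assignment
(`scipy.optimize.linear_sum_assignment`), plain greedy pairing, or a
bond-aware greedy (`structure_priority`) that rejects pairings breaking
bond preservation against committed pairs; (2) re-optimize the axis
analytically for that permutation.  Raw assignments may contain cycles
whose length does not divide h; such cycles are collapsed to fixed points
(a conservative repair that always yields an admissible permutation)
before scoring.  Iteration stops when the value stops improving by `tol`
(default 10⁻¹⁰, `max_iter` 50); the best state visited is returned, so
the recorded value trace is non-increasing.  Start directions default to
the three Cartesian axes; `fibonacci_sphere(n)` provides n near-uniform
deterministic directions, and for Cn with n > 2 both orientations of each
start are tried.  Because every candidate is admissible and scored with
the same functional, the approximate value is always an upper bound on
the exact minimum — the suite asserts this on every oracle-sized fixture.
If the bond-aware greedy dead-ends (every remaining pairing for an atom
violates the bond rule), leftovers are matched by plain distance and the
cycle repair applies.

## Protein homomers

Homo-oligomers are prepared from PDB-derived structures by dropping
HETATM records, applying chain / residue-serial / backbone selections
(backbone = N, CA, C, O; OXT is excluded because it exists only at
termini and would break per-chain equality), and verifying that all
chains share the same (residue ordinal, residue name, atom name, element)
signature.  Sequence-based equivalence puts one atom per chain in each
class, so a chain permutation fully dictates the sequence-paired atom
permutation.  `chain_permutation_search` enumerates chain permutations
with cycle lengths dividing h exhaustively for ≤ 8 chains (Hungarian
matching of rotated chain centroids above that) and refines the axis
analytically for each.  In `assignment` mode atoms are additionally
re-matched between mapped chain pairs by Hungarian assignment within
(residue name, atom name, element) key groups — freedom that matters only
when a residue type repeats; an inadmissible outcome falls back to the
sequence-dictated pairing.  The trivial approach scores the identity
permutation (or, with `use_chains`, searches only the chain permutation).
Files with alternate locations, insertion codes or sequence gaps must be
cleaned beforehand; the reader rejects altloc codes other than blank/A.

## Input handling

Formats: XYZ, PDB (ATOM/HETATM/MODEL/ENDMDL/TER/CONECT), MDL MOL/SDF
V2000, and an internal `csm` dialect (line 1: atom count; N lines
`element x y z`; N adjacency lines `i j k …`, 1-based).  MOL/SDF parsing
and writing go through RDKit (no sanitization, hydrogens kept), PDB
parsing through gemmi; XYZ and the csm dialect are trivial enough to
format directly.  Connectivity comes from the file, from an external
1-based adjacency file, or from the covalent-radius rule
d(i,j) ≤ tol·(rᵢ+rⱼ) with Cordero radii (RDKit periodic table; unknown
elements fall back to 0.77 Å with a warning).  The default tolerance 1.15
is the common perception heuristic for organic molecules.  Atom indices
are 0-based internally and 1-based in every user-facing file
(permutation, connectivity, selections).  Round-trip precision is
format-limited: full double for xyz/csm, 4 decimals for mol/sdf, 3 for
pdb — so nearest-structure files written as PDB carry ~10⁻³ Å quantization.

## Centering

Structures are centered at the uniform (geometric) centroid by default,
although the center of mass is the conventional phrase: the measure is a
pure-geometry descriptor and element masses would make it
isotope-dependent.  Mass weighting is available (`weights="mass"`).
Degenerate all-coincident input is rejected.  Note one consequence used
by the tests: the two-atom pair (1,0,0), (−1,0.2,0) evaluated *in the
given frame* has the hand-derivable inversion value 100·0.02/2.04 ≈
0.98039, while the same pair after centering is an exact antipodal pair
and scores 0; `geometry_from_coords(..., recenter=False)` exposes the
frame-fixed evaluation.

## Synthetic data

`fixtures.make_symmetric` closes seeded random orbits under the group
generator, giving exactly symmetric molecules with a known symmetry
permutation (`orbit_permutation`); `perturb` adds seeded i.i.d. Gaussian
noise; `make_homomer` replicates one seeded alanine-like chain (5 atoms
per residue) by the group rotation into chains A, B, … with proper PDB
metadata.  These geometries exercise every code path deterministically
but are not force-field realistic: bond lengths, angles and sterics are
arbitrary, so passing tests demonstrate the mathematics of the measure,
not chemical plausibility of any particular structure.  Real-data effects
deliberately absent from the generators include crystallographic
disorder, missing atoms, alternate conformations and sequence gaps.

## Problem sizes and numerical choices

The oracle-equivalence suite uses 200 random molecules of 4–7 atoms
(groups of order ≤ 6), where the N!-scan oracle is affordable; the
acceptance script repeats the same comparisons at 60 molecules.  The
brute-force axis oracle uses a 600-direction Fibonacci grid polished by
Nelder–Mead.  Zero-symmetry assertions use 10⁻⁸ (constructed fixtures
reach 10⁻²⁹); oracle agreement uses 10⁻⁶; bound orderings allow 10⁻⁸
slack.  Enumeration tie-breaks, the assignment repair, the refinement
tolerance and the axis sign convention are this package's own choices
where the literature leaves them open; each is described above where it
arises.

## Known limitations

- Exact enumeration without `keep_structure` grows factorially; beyond
  ~8 atoms per equivalence class use `keep_structure`, `remove_hy`, or
  the approximate approach.
- The approximate search is a local alternation: it can miss the global
  permutation on strongly distorted structures with few start directions
  (mitigated by `fibonacci n`).
- Only cyclic groups; heteromers and non-cyclic protein symmetries are
  not treated.
- PDB handling is deliberately minimal (no insertion codes, occupancies
  or gap repair); pre-clean files with a dedicated tool.
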
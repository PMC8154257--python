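# Methods

## Promolecular density model

The density of a molecule at a point **r** is the sum of isolated-atom
densities (promolecule approximation — no charge relaxation, no angular
structure):

ρ(**r**) = Σ_A Σ_s occ_{A,s} · |R_{n,ζ}(|**r**−**R**_A|)|² / 4π,

with R_{n,ζ}(r) = (2ζ)^{n+1/2}/√((2n)!) · r^{n−1} e^{−ζr} the normalized
radial Slater function (atomic units internally; the public API takes Å
and returns e/Å³). Each subshell is treated as a spherically averaged
s-type radial density; this keeps ln ρ asymptotically linear in distance,
which is the mechanism behind the complementarity regression. By
construction the radial integral of each atom's density equals its
electron count, independent of the exponents chosen.

The shipped exponents are Clementi–Raimondi single-zeta values per
occupied subshell for H–Ca, with neutral-atom Aufbau occupancies, in
`src/edcomplement/data/slater_params.txt` (whitespace table: element, n,
ζ in bohr⁻¹, occupancy). The file is deliberately editable so an
alternative parameterization can be dropped in; elements outside the
table raise an unsupported-element error rather than silently falling
back.

Key parameters (defaults chosen once, stated with units):

| parameter | default | meaning |
|---|---|---|
| grid spacing | 0.1 Å | 1000 grid points per Å³ in the overlap region |
| grid margin | 3.0 Å | box extension beyond the ligand bounding box per side; contact distances of interest extend to ~8 Å total |
| rho_min | 0.001 e/Å³ | a grid point is an overlap point only if *both* molecules contribute at least this density |
| cutoff | 10 Å | atomic contributions beyond this distance are treated as zero; single-zeta tails there are < 1e−9 of center values |
| include_hydrogens | true | hydrogens present in the input contribute to density sums (heavy-atom-only mode available) |
| center_mode | molecular | ρ_LC/ρ_EC are the whole molecule's density at the atom center (neighbor tails included); an isolated-atom mode is available |
| cluster threshold | 0.1 Å | friends-of-friends linkage distance = grid spacing, i.e. 6-neighborhood components; diagonal (26) connectivity available as a flag |

## The complementarity regression

At every overlap point, with N_L/N_E the atomic numbers of the
top-contributing ligand/receptor atoms and ρ_LC/ρ_EC the densities at
those atoms' centers:

- SUMDLE = dist_ligand + dist_enzyme (Å),
- ρN = ln(N_L·N_E/(ρ_LC·ρ_EC)),
- y = ln(ρ_ligand·ρ_enzyme) + ρN = σ_ligand + σ_enzyme, with
  σ_ligand = ln(ρ_ligand·N_L/ρ_LC).

This is the unique form in which the regressand splits exactly into a
ligand and a receptor contributor and is dimensionless (logarithm
arguments are implicitly divided by 1 e/Å³). The per-point identity
y = σ_ligand + σ_enzyme is asserted to 1e−10 in tests. Ordinary least
squares of y on SUMDLE yields slope a (Å⁻¹), intercept b, R² and the
adjusted R² = 1 − (1−R²)(n−1)/(n−2). Weighted or robust regression is
deliberately out of scope.

The overlap-inclusion rule is the dual rho_min threshold; it is the
minimal assumption consistent with "points where both electron clouds
contribute". No additional geometric exclusion (e.g. of points inside
atomic cores) is applied; the ρN construction is isolated in one code
path so an alternative form can be swapped in.

Deterministic conventions: top-contributor ties break to the lower atom
serial; overlap points are ordered grid-index lexicographically; exported
floats use 6 significant digits, making reruns byte-identical.

## Analytic limit and what the toys test

For atoms carrying a single 1s shell with one common exponent ζ, each
molecule's log density is exactly linear in the distance to its atom, so
y = ln(Z_L·Z_E) − 2ζ·SUMDLE *exactly*: the pipeline must recover
a = −2ζ (≈ −3.7794 Å⁻¹ for ζ = 1 bohr⁻¹ after the bohr→Å conversion),
b = ln(Z_L·Z_E) and R² = 1 regardless of geometry. This closed form is
the primary end-to-end oracle. It also implies a deliberate limitation of
the toys: a single-exponential atom's slope carries no geometric
information, so pose-corruption sensitivity cannot be probed with them.

The displacement ensemble therefore gives carbon two 1s shells (a steep
"core", ζ = 2.2 bohr⁻¹ with 5 electrons, and a diffuse "valence",
ζ = 0.9 bohr⁻¹ with 1 electron; occupancies still sum to 6). The log
density is then convex in distance — steep near contact, shallow further
out — so pulling the ligand out of contact raises the fitted slope
monotonically. Displacements are limited to ≤ 1 Å: beyond that the
overlap region collapses onto the inclusion threshold and the fit
degenerates, which mirrors the physical statement that a pose with no
cloud overlap has no contacts to score. Reference poses straddle the
optimum with ±0.05 Å offsets along the displacement axis (plus 0.02 Å
lateral jitter), so the min–max envelope brackets the optimal slope and
excludes every displaced pose.

What the synthetic fixtures do *not* emulate: real ligand chemistry
(bond topology, conformational strain), crystallographic noise,
protonation, or the density of a real binding pocket with dozens of
residues. Passing tests establish the correctness of the machinery and
its qualitative response to pose corruption, not quantitative agreement
with any particular receptor family; slopes for real complexes will
depend on the density parameterization used.

## Contact clustering

Friends-of-friends = single linkage: connected components of the graph
linking points within threshold + ε (ε = 1e−9 Å absorbs float error in
grid steps). On grid-aligned points with threshold = spacing this equals
6-connected component labelling, which an independent `scipy.ndimage`
oracle confirms in tests. Clusters are ordered by descending size with
ties broken by smallest grid index; each is summarized by its size, its
strongest overlap (max ln(ρ_L·ρ_E)), its closest approach (min SUMDLE)
and the modal (ligand atom, receptor atom) top-contributor pair (ties to
the lower serial pair). An optional strength floor restricts clustering
to points above a minimum ln(ρ_L·ρ_E); no minimum cluster size is
imposed, so 1-point components are counted.

## Symmetry-corrected RMSD

Poses are compared in the frame they come in (docked and reference poses
share the receptor frame); no superposition is performed anywhere in the
toolkit. The Hungarian variant solves a minimum-cost assignment
(`scipy.optimize.linear_sum_assignment`) on squared distances within each
element class; the naive variant pairs atoms in input order. Element
classes — not bond-topology automorphisms — define allowed matchings;
this over-permits chemically inequivalent swaps of same-element atoms,
which is accepted as the standard per-element Hungarian formulation.
Hydrogens are excluded by default (ligand hydrogen positions in PDB files
are unreliable); atom-serial exclusion sets support substituent-free
comparisons. An exhaustive within-element permutation search (n ≤ 8)
serves as the oracle in tests.

## Ranking and envelope

The reference envelope is the min–max box of the reference fits' (a, b)
(means and standard deviations are also reported). Classification uses
the closed slope interval only: across poses a and b are nearly
collinear (the intercept-vs-slope line fit reports adjusted R² ≈ 1 on
collinear toy families), so the slope suffices; b remains diagnostic.
A pose inside the envelope but far from the reference by RMSD is
reported as a candidate alternative/metastable pose, not an error.
Ranking is ascending in a (most negative slope = strongest contacts),
ties broken by higher R², then label. Converting a into an absolute
binding constant is out of scope.

## Structure I/O choices

PDB reading/writing goes through gemmi. Waters (HOH/WAT/DOD) are dropped
by default — configurable, since receptor-site waters can be genuine
density contributors. Alternate locations default to the
highest-occupancy conformer (ties by altloc letter); each altloc can
instead be extracted as its own pose, treating alternate conformations
as separate complexes. Blank element columns fall back to an atom-name
heuristic (two-letter symbols only when the name starts in the element
column), cross-checked against an independent parser in tests. mmCIF,
MOL2/SDF, protonation assignment and structure repair are out of scope.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic
fixtures: toy grids of ~2×10⁵–10⁶ points, clustering oracles on 200-point
sets, RMSD oracles on 8-atom poses, and a 5-pose displacement ensemble —
sizes at which every oracle (closed form, brute-force enumeration,
quadrature) is exact and fast. Real complexes at 0.1 Å spacing are
substantially heavier (the ligand-first evaluation order and the 10 Å
cutoff keep receptor work proportional to the overlap candidates); the
toolkit targets in-depth analysis of individual complexes, not
virtual-screening throughput.
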
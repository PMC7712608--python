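# Methods

`rdcfold` determines protein backbone conformations from residual dipolar
couplings (RDCs) by a two-stage torsion-space search, and ships the full
simulation/evaluation loop needed to validate the method without any
external data.

## Model

A coupling between nuclei *i* and *j* in alignment medium *m* is modeled in
the static-structure form

    D_ij = Dmax(type) * v_ij · S_m · v_ij^T ,
    Dmax  = −μ0 γ_i γ_j h / (2π r)^3 ,

with `v_ij` the unit internuclear vector, `S_m` the 3×3 symmetric traceless
Saupe order matrix of the medium, and `r` the internuclear distance,
treated as fixed for each supported backbone atom pair.  Time-averaging
over internal dynamics is deliberately out of scope: structures are scored
as single rigid conformers.

Constants: `h` is the full Planck constant (6.62607015e-34 J s).  With the
gyromagnetic ratios in `constants.GAMMA` and r(N–H) = 1.02 Å this puts
Dmax(N–H) at ≈ 22.9 kHz, the scale standard in order-tensor software; a
reader who prefers ħ in the prefactor can treat the difference as a uniform
2π rescaling of all order parameters.

Because mixed vector types share one tensor per medium, Dmax is kept
explicit in the design matrix (one row per coupling,
`Dmax·[x²−z², y²−z², 2xy, 2xz, 2yz]` against the five independent tensor
components) rather than absorbed into `S`.

Supported vector types: N–H, Cα–Hα, Cα–C′, N–Cα, C′–O, C′(i)–N(i+1) and
C′(i)–H(i+1) (the C′–H distance, 2.032 Å, follows from the rigid peptide
plane).  The C′–O column exists for compatibility with the pinned legacy
table layout and for simulation benchmarks only: ¹⁶O is not magnetically
active, so the registry assigns γ(¹⁷O) to make the type mathematically
well-defined.  Remap the legacy columns in `constants.LEGACY_COLUMNS` if
your historical files differ.

## Fitness

For a candidate structure, each medium's tensor is re-estimated by
least squares from that medium's couplings (minimum-norm solution via a
singular-value pseudo-inverse, relative cutoff 1e-10, when fewer than five
independent rows exist).  The score is the RMS deviation in Hz between
measured and back-calculated couplings pooled over all media and couplings
actually resolvable in the structure — equivalent to the usual
`sqrt(ΣΣ(D−D′)²/(M·N))` when media are balanced.  Couplings whose atoms are
not yet built (growing fragments) are skipped and counted.  Measurement
uncertainties are stored but unweighted by default; a `weighted=True` flag
enables 1/σ² weighting.

Useful identities, all enforced by tests: the score of the generating
structure on its own noise-free data is 0; the score is invariant under
rigid motion (the refit absorbs rotations); with ±E Hz uniform noise the
fitted score cannot exceed the raw residual and concentrates near the
E/√3 noise floor.  The floor comparison doubles as a run diagnostic: a
final score far above E/√3 means the search lost the true branch.

## Backbone geometry

Chains are built residue-by-residue with ideal covalent geometry
(Engh–Huber-style bond lengths/angles, see `constants`), ω fixed at 180°
(trans; cis-proline is not modeled), and only backbone atoms N, H, Cα, Hα,
C′, O.  Glycine gets a single Hα on the L-side; proline has no amide H and
N–H couplings on proline are rejected at parse time.  Hα sits along the
fixed L-chirality combination of the bisector and normal of the N/C′ bonds
at Cα (coefficients from ideal L-alanine).  Atom placement uses the
standard three-reference-atom (NeRF) construction; bonded distances are
exact to machine precision with no accumulation drift.

Torsion conventions: φ(1) has no geometric role and ψ(L) only orients the
terminal O; neither is searched.  The builder substitutes fixed caps
(φ=−120°, ψ=140°) for `None`, and the simulator's ground-truth fixtures use
the same caps, so search and truth share one convention.

Backbone RMSD uses atoms N, Cα, C′ after Kabsch superposition with
reflections forbidden.

## Stage I — candidate lists

For each junction (interior residue; its φ/ψ joins two adjoining peptide
planes) the torsion grid over (−180, 180]² (default step 10°, 5° in the
evaluation protocol so that the fixtures' torsions lie on the grid) is
filtered by Ramachandran class and ranked by local RDC fitness over the
couplings whose atoms all lie in the junction's two planes — a quantity
that depends only on (φ, ψ).

The shipped Ramachandran regions are deliberately permissive envelopes
(general and pre-proline: the negative-φ half plane; proline: its ring
band φ∈[−112.5°, −32.5°]; glycine: unrestricted): helical proteins sample
atypical torsion space, and the RDC score does the fine discrimination.
The table is data — pass a stricter polygon set via the `regions` argument
if wanted.

A mined dihedral restraint replaces the grid with the prediction varied by
±25° in 5° steps (121 candidates); the Ramachandran filter is not
re-applied, since predictions derive from observed structures.

Local mirror degeneracy: the local score of (−φ, −ψ) is *exactly* the
score of (φ, ψ), because reflecting the fragment maps the best-fit tensor
to an equally good reflected tensor in every medium.  Wherever the filter
admits both (glycine), local ranking can only say the true pair attains
the minimum; the global Stage-II accumulation breaks the tie.

## Stage II — elongation with decimation

The beam starts from the first two peptide planes.  At each junction every
beam fragment is combined with every candidate pair; children are scored
on all couplings their atoms determine (a coupling enters at the first
step at which both its atoms are fixed by chosen torsions — C′/O/Hα of the
newest residue wait one step), pruned, and the best `depth` survivors
carry forward.  Ties are broken lexicographically on the full torsion
sequence, making runs bit-reproducible.

Scoring is incremental: fragments carry per-medium normal-equation
accumulators (AᵀA, AᵀD, DᵀD), so each child costs one 5×5 eigen-solve
regardless of length (`A⁺ = (AᵀA)⁺Aᵀ` keeps the minimum-norm semantics;
eigenvalues below 1e-12 of the largest are treated as null).  Residual
cancellation is clamped at zero.  Every step the winner's incremental
score is audited against a from-scratch recomputation on its rebuilt
structure (tolerance 1e-6 Hz); the final reported score is always the
from-scratch value.

**Dynamic decimation** keeps children scoring below `best·(1 + n/100)`
("+n %" is read multiplicatively; an additive reading `best + n/100 Hz` is
selectable by flag).  When the best score is exactly zero (under-determined
early steps) an absolute guard of 0.01 Hz takes over; the best child always
survives, so the pool is never empty.  **Static decimation** (kept for
comparison) selects one representative per terminal-(φ,ψ) bucket and
applies a fixed absolute threshold; it may empty the pool, in which case
the search falls back to plain best-`depth` with a warning.

Defaults: depth 1000, tolerance 20 %.  The evaluation protocol in the
tests and `scripts/acceptance.py` uses depth 100 (depth has little effect
beyond ~100 on these 12–20-residue problems) and tolerance 50 %: with
noisy couplings the under-determined early steps have best scores far
below the noise floor, and a narrow relative band around them prunes the
true path on some noise realizations.  Fifty percent folded every probed
±1 Hz realization of the helix fixture below 0.1 Å; twenty percent lost
one in five.

## Simulation and fixtures

`simulate_rdcs` back-calculates every resolvable (residue, type, medium)
coupling under specified tensors; `add_noise` adds seeded i.i.d.
Uniform(−E, E) Hz.  The default tensors are two magnitudes-typical order
matrices (principal values −3e-4/−5e-4/8e-4 and −4e-4/−6e-4/1e-3, the
second rotated by intrinsic ZYZ Euler angles 40°/50°/60°) — experimental
studies rarely publish theirs, so these are pinned and documented rather
than fitted to anything.

Three deterministic fixtures (hard-coded torsion tables; datasets at
E ∈ {0, 1, 2, 4} Hz with fixed seeds): `helix15` (α-helix), `hairpin12`
(β-hairpin with a two-glycine turn), `helix_turn_helix20` (two helices
joined by a four-residue turn with two glycines).

What the simulator does **not** emulate about real data: non-ideal and
variable covalent geometry, internal dynamics (time-averaged couplings),
missing assignments/incomplete coverage, systematic (non-uniform) errors,
and tensor uncertainty.  Passing the synthetic recovery suite therefore
demonstrates correctness of the search and scoring machinery under the
model's own assumptions, not performance on experimental depositions.

## Mining

`mine_fragments` cuts every corpus chain into k-mers (rolling window,
default 6) and stores each window's (φ, ψ) series.  For a query sequence,
all fragments matching any window covering a residue pool their
observation at that residue; the prediction is the center of the modal
10°×10° histogram bin, ties resolved toward the lexicographically smallest
(φ, ψ).  The histogram mode was chosen over a circular mean because pooled
Ramachandran distributions are multi-modal.  Pooling is per position (all
window offsets contribute equally), not per amino-acid type.  The corpus
is local PDB files; no external service is contacted.

## Degenerate inputs and numerical edges

Collinear atoms make a dihedral undefined → `DataError`.  Non-unit vectors
and non-divisor grid steps → `ValidationError`.  Unknown atom pairs in
restraint files are skipped with a logged count (no silent loss); malformed
rows and wrong column counts fail with the line number.  PDB files missing
amide H/Hα get them rebuilt from ideal geometry.  Exact score ties in the
beam and in candidate ranking are ordered lexicographically.

## Known limitations

* ψ(1) and φ(L) are never searched; couplings touching the affected atoms
  are evaluated under the cap convention.
* ±4 Hz noise on the turn-containing 20-residue fixture is seed-dependent:
  the glycine-turn mirror branch can capture the beam, folding to several
  Å — always flagged by a final fitness far above the E/√3 floor.  Deeper
  beams help only marginally; multi-start or mirror-aware post-selection
  would be the next step.
* Single chain, single model, backbone only; no steric or energetic terms
  beyond the Ramachandran envelopes.
* Reproduction of published per-protein numbers depends on order tensors
  the original study did not print; `scripts/reproduce_1a1z.py` documents
  the protocol with the package's default tensors and expects agreement in
  regime only.
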
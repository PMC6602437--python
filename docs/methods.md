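# Methods

## Geometric model

Every protein heavy atom is a ball `(c_i, r_i)`; hydrogens, waters,
ligands and nucleic acids are excluded on read.  Space is partitioned by
the **radical (power) tessellation**: the cell of ball *i* is the set of
points whose power distance `|x − c_i|² − r_i²` is minimal.  We chose
the power diagram over the additively weighted (Apollonius) diagram
because its bisectors are planes, so every cell face is a clipped planar
region and face areas can be computed essentially exactly; the contract
— symmetric areas, a space partition, SAS constraint — is the same, and
with protein-like radii (1.46–1.88 Å, spread ≪ inter-atomic distances)
the two diagrams are close.  The validation oracle uses the same power
distance rule, so all cross-checks are internally consistent.

Cells are constrained to the **solvent-accessible surface**: the union
of spheres of radius `r_i + p` with probe `p` (default 1.4 Å, a water
probe; exposed as a parameter).  The area of the face between cells *i*
and *j*, clipped to the SAS union, is their contact area; the part of
sphere `(c_i, r_i + p)` that lies in cell *i* and on the boundary of the
SAS union is atom *i*'s solvent contact area.

### Face areas (exact clipping)

For each candidate pair the face is built on the radical plane: a
bounding square (from the provable support bound below), cut by the
half-plane of every competing ball (Sutherland–Hodgman on exact line
clips), then intersected with the union of the SAS-sphere cross-section
disks (shapely booleans; disks are polygonized at 96 segments per
quarter circle, a relative area error of ~6·10⁻⁶).  When the clipped
polygon lies entirely inside the pair's own SAS disk the polygon area is
used directly (the common case for buried contacts).  Faces below
10⁻⁴ Å² are discarded.

Support bound: any point of cell *i* inside the SAS union has power
`≤ 2 r_max p + p²`, so it lies within `B_i = sqrt(r_i² + 2 r_max p + p²)`
of `c_i`.  Candidate pairs and competitors are gathered from a k-d tree
with these radii.  With unequal radii `B_i` can slightly exceed the
naive `r_i + p` reach, so the locality guarantee is: no face between
atoms farther apart than `B_i + B_j`.

### Solvent areas (deterministic quadrature)

On each SAS sphere, every other ball excludes a spherical cap (the
larger of its occlusion cap and its power-bisector cap).  The remaining
fraction is integrated with a deterministic Fibonacci-lattice quadrature
(default 60 000 points per sphere).  Measured against closed-form cap
areas and an 8·10⁵-point reference, the quadrature error is ~0.02 Å² —
an order of magnitude below the Monte-Carlo oracle's standard error at
10⁵ samples, which is the resolution at which the areas are validated.
The point count is a parameter (`sphere_points`).

### Rigid-motion invariance

All geometry is computed after transforming coordinates to an internal
canonical frame (principal axes of the center cloud, signs fixed by
coordinate skewness, right-handed).  Areas are mathematically invariant
under rigid motion; the canonical frame makes them invariant *numerically*
(observed ≤ 10⁻¹⁴ relative on random 20-ball systems), which also gives
bit-identical outputs across runs.  Configurations with degenerate
principal axes (exactly symmetric point clouds) fall back to the input
frame; for such inputs invariance holds only to the discretization
error.

### Monte-Carlo oracle

`mc_area_oracle` is an independent validation path: uniform sampling on
the pair's radical plane (inside the provable bounding disk) or on an
atom's SAS sphere, with brute-force point classification against *all*
balls (no neighbor lists, no clipping code shared with the deterministic
path).  It returns an unbiased estimate with its standard error; the
deterministic areas agree within 3 standard errors on random systems.

### Degenerate input

Ball centers closer than 0.01 Å are an error, not a silent perturbation
— reproducibility over permissiveness.  Atoms with zero total contact
area (possible only in degenerate inputs) are left unscored and excluded
from residue and global means rather than imputed.

### Occlusion monotonicity

Removing a ball can only enlarge the faces between the remaining balls
*at probe 0*, where every face point lies inside one of its own two
balls.  With a positive probe the removed ball's SAS sphere also leaves
the union, which can clip a neighboring face by a sliver (observed
~2·10⁻³ Å² on 4-ball systems); the property is therefore guaranteed, and
tested, at probe 0 only.

## Statistical potential

Contact categories: `seq_near` (same chain, residue separation ≤ 1 by
residue numbering), `seq_far` (separation ≥ 2 or inter-chain),
`solvent`.  Atom types are one per (standard residue, heavy-atom name) —
167 types plus a reserved solvent type; the van der Waals radii (ProtOr
united-atom conventions: N 1.64, O 1.46, S 1.77, sp² C 1.76, sp³ C
1.88 Å) and the non-standard residue remaps (MSE→MET, etc.) live in a
human-editable YAML config shipped with the package.

Energies are natural-log ratios `E = ln(P_expected / P_observed)` of
area-weighted type probabilities, so over-represented (favorable) types
are negative.  The log base only rescales `(E, μ, σ)` jointly and
cancels in the quality score.  `P_expected` is an independence null
chosen to normalize exactly over the realizable type space: with
endpoint atom-type marginals `f` (each pair contact counts both
endpoints, each solvent contact its protein endpoint) and category
marginals `g`,

    P_exp(a, b, c) = g(c) · f(a) · f(b) · (2 − δ_ab)   for sequence categories
    P_exp(a, solvent) = g(solvent) · f(a)

A product-form observation table is an exact fixed point of this null
(all energies zero), which the tests exploit as an analytic oracle.

A pseudocount (default 1 Å² per type) keeps unobserved types finite.
Training normally runs over the full realizable registry space; a
`type_space="observed"` mode restricts to the observed types for
simulation studies where the pseudocount mass of ~35 000 unobserved
types would swamp a deliberately small table.

The calibration `(μ, σ)` per atom type is the sample mean and standard
deviation of per-atom normalized energies over the training structures
scored with the freshly trained energies (self-calibration; no separate
calibration set is required).  Types with fewer than two observations or
zero spread inherit the global statistics.  Potentials carry a category
scheme id and scorers refuse to mix schemes.

## Scores

`E_n` is the area-weighted mean energy over an atom's contacts, solvent
contacts included on equal footing.  `Q_a = ½(1 + erf((μ − E_n)/(σ√2)))`
— the standardized energy is negated so favorable atoms score near 1;
`Q_a = 0.5` exactly at `E_n = μ` and a ±1σ offset gives the standard
normal CDF values 0.8413/0.1587.  Residue scores are unweighted means of
their atoms; smoothing is a centered moving average (default window 5,
must be odd) that shrinks at termini and never crosses chain breaks or
residue-numbering gaps > 1.  The global score weights each atom by its
integer burial depth: depth 1 for atoms with positive solvent area, else
1 + breadth-first distance to the exposed layer on the contact graph
(atoms cut off from any exposed atom get weight 1 with a warning).

`reference_band` is generic machinery for score-versus-size context: it
returns running quantiles (default 5/50/95%) over log-spaced size bins
of a user-supplied collection of (n_residues, score) pairs.  No
precomputed reference band ships with the package.

## Interfaces and ranking

Interface atoms are those with ≥ 1 inter-chain contact.  The interface
score is the unweighted mean of their `Q_a` (atom-level averaging, not
residue-level); per-residue interface quality averages only that
residue's interface atoms.  The interface energy is `Σ area · E` over
inter-chain contacts; all chain pairs are pooled into one interface.
Separated chains yield a zero-contact summary with an undefined
interface score.  `tournament_rank` plays a round-robin in which model X
beats Y when it wins at least two of {higher global score, higher
interface score, lower interface energy}; ranking is by wins, ties by
global score then label.  The 2-of-3 majority rule is this package's
concretization (the rule id `majority-2of3/v1` is recorded); the default
ordering is simply by global score.

## Structure input

The PDB reader is bespoke fixed-column parsing for dialect control:
MODEL blocks are read as separate structures (`plain`) or combined into
one assembly with chain-id collisions disambiguated by a model-ordinal
suffix (`assembly`); altloc records other than ' '/'A' are dropped
(single-conformer scoring, occupancy ignored); malformed records are
skipped with a warning and only an all-malformed input is an error.
Optional sequence-guided truncation aligns the concatenated chain
sequence to a user sequence (global alignment, match +1, mismatch −1,
gap open −2, gap extend −1 — a deterministic standard choice; the
alignment is only used to cut and renumber, never in scoring), discards
unaligned residues, renumbers kept residues by target position and
clears insertion codes.  An alignment with no identical aligned position
is rejected as having no alignable region.

## What the synthetic generators emulate — and what they don't

`make_ball_system` produces packed random balls for geometry validation.
`make_toy_polypeptide` builds chains from idealized internal-coordinate
templates: correct residue/atom naming, connectivity-consistent bond
distances, no steric collapse, deterministic in (sequence, geometry,
seed) — but no Ramachandran validity, no hydrogen-bond geometry, no
realistic packing density.  `make_toy_dimer` places two such chains at a
controlled surface-to-surface gap.  Tests passing on these inputs
demonstrate that the geometry, typing, training and scoring machinery is
correct and deterministic; they say nothing about discriminative power
on real models, which depends entirely on training the potential on a
set of high-quality experimental structures.

## Problem sizes and defaults

The shipped tests and the acceptance script run on 3–31 ball systems,
toy chains of 2–20 residues and Monte-Carlo checks at 10⁵ samples per
query — sizes chosen so the whole validation suite recomputes from
scratch in a couple of minutes while every check retains its stated
statistical resolution.  Scoring a real ~300-residue protein with
default settings takes on the order of tens of seconds, dominated by the
solvent quadrature; `sphere_points` trades solvent-area resolution for
time.

## Known limitations

- The power diagram deviates from the additively weighted diagram for
  strongly unequal radii; with the shipped radii set the difference is
  small but absolute areas are not interchangeable between the two
  definitions.
- Absolute score values depend on the category scheme, the null model
  and the training set; scores from different potentials are not
  comparable (the scheme id guards against accidental mixing).
- No secondary-structure assignment, no mmCIF input, no nucleic-acid or
  ligand scoring.
- Solvent areas are quadrature-based; their error floor (~0.02 Å² at the
  default resolution) is negligible for scoring but means solvent areas
  are not exact to machine precision, unlike face areas.
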
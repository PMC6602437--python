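# tessqa

Tessellation-based quality assessment of protein structures and
protein–protein interfaces.

## The problem

Given a structural model of a protein — a computational prediction or an
experimental structure — how realistic is it, overall and region by
region?  Single-model quality assessment answers this without a native
reference structure.  `tessqa` does it geometrically: every heavy atom is
a ball with a van der Waals radius, space is partitioned into cells by a
tessellation of the balls, and the area of the face shared by two cells
is the *contact area* of the two atoms.  Cells are constrained by the
solvent-accessible surface (SAS), so the part of a cell boundary on the
SAS is the atom's *solvent contact area*.  Interactions are thus
described by areas rather than distances, which also makes inter-chain
interfaces directly scoreable as sets of inter-chain contact faces.

The package is aimed at structural bioinformaticians who want a
transparent, trainable, fully deterministic area-based scoring pipeline:
a library first, plus a thin `tessqa` command-line tool.

## The model

A contact type `(a_i, a_j, c_k)` couples two atom types with a contact
category (sequence-near: same or adjacent residue; sequence-far:
separation ≥ 2 or inter-chain; solvent).  A knowledge-based potential is
trained from area-weighted contact frequencies of a structure set:

    E(a_i, a_j, c_k) = ln( P_expected(a_i, a_j, c_k) / P_observed(a_i, a_j, c_k) )

with `P_expected` an independence null built from endpoint atom-type and
category marginals.  For a single atom φ with contact set Ω_φ, the
normalized energy is the area-weighted mean

    E_n(Ω_φ) = Σ_{ω∈Ω_φ} E(type_ω)·area_ω / Σ_{ω∈Ω_φ} area_ω

and the atom quality score is the error-function transform

    Q_a(Ω_φ) = ½ (1 + erf( (μ_type − E_n(Ω_φ)) / (σ_type √2) ))  ∈ (0, 1)

with per-atom-type calibration (μ, σ); the standardized energy is
negated so that favorable (low-energy) atoms score near 1.  Residue
scores are means of their atoms' `Q_a`; the global score is a weighted
mean with integer burial-depth weights (solvent-exposed atoms depth 1,
one more per contact-graph layer inward).  For complexes, the interface
score is the mean `Q_a` of all atoms with inter-chain contacts and the
interface energy is `Σ area·E` over inter-chain contacts.

No pre-trained potential ships with the package: you train your own
(`tessqa train`) or load one from a file.

## Worked example

Contact areas have closed forms on small systems
(`python examples/01_contact_areas.py`):

```
two-ball face area   :  27.1421 A^2
closed form          :  27.1434 A^2
solvent area ball 0  :  99.5271 A^2
```

Two balls of radius 1.9 Å, 3 Å apart, probe 1.4 Å: the contact face is
the mid-plane disk clipped to the SAS, area `π((1.9+1.4)² − 1.5²)`; the
deterministic computation reproduces it to 5·10⁻⁵ relative.

Training on three synthetic polypeptides and scoring one of them
(`python examples/03_score_structure.py`):

```
structure: toy-extended-ACDEFGHI(seed=1)
global score: 0.4021  (167 atoms, 20 residues)

chain res  raw    smoothed
A     1    0.5526 0.4224
A     2    0.2147 0.4780
...
held-out toy peptide global score: 0.0832
```

Raw residue scores are means of atom qualities; the smoothed column is a
5-residue sliding window.  The held-out chain scores much lower because
its contact environments are atypical of the (tiny) training set — with
a toy potential the numbers demonstrate the machinery, not real model
quality.

The same pipeline from the shell:

```sh
tessqa train structures/ --out potential.tsv
tessqa score model1.pdb model2.pdb --potential potential.tsv \
    --interfaces --out scores/
tessqa validate-geometry --seed 1
```

`score` writes a global summary (sorted by score), per-residue and
per-atom tables, contact tables, scored PDB files (quality in the
B-factor column), and — with `--interfaces` — interface tables plus a
tournament ranking.  Reruns are byte-identical.

## Layout

- `src/tessqa/structure.py` — PDB I/O, atom typing/radii, sequence-guided
  truncation and renumbering
- `src/tessqa/geometry.py` — power-tessellation contact areas with SAS
  constraint, Monte-Carlo oracle, burial weights
- `src/tessqa/potential.py` — contact categories, training, (μ, σ)
  calibration, potential files
- `src/tessqa/scoring.py` — normalized energies, erf transform, residue /
  global scores, reference quantile bands
- `src/tessqa/interfaces.py` — interface summaries and model ranking
- `src/tessqa/fixtures.py` — deterministic synthetic inputs
- `src/tessqa/cli.py` — the `tessqa` command
- `docs/methods.md` — model details, numerical choices, limitations
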
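"""Score a toy polypeptide: per-atom, per-residue and global quality.

Each atom's contacts give a normalized energy E_n (area-weighted mean of
contact-type energies); the erf transform turns E_n into a quality score
in (0, 1); residues average their atoms and the global score is the
burial-weighted mean over all atoms.
"""

import logging

from tessqa.fixtures import make_toy_dimer, make_toy_polypeptide
from tessqa.pipeline import train_from_structures
from tessqa.scoring import score_structure

logging.basicConfig(level=logging.ERROR)

training = [
    make_toy_polypeptide("ACDEFGHIKLMNPQRSTVWY", "extended", seed=1),
    make_toy_polypeptide("KLMNPQRSTVWA", "helix", seed=2),
    make_toy_dimer("ADE", "KNQ", gap=1.0, seed=3),
]
potential = train_from_structures(training)

target = training[0]  # self-scoring: environments resemble the training set
profile = score_structure(target, potential, window=5)

print(f"structure: {target.label}")
print(f"global score: {profile.global_score:.4f}  "
      f"({profile.n_atoms} atoms, {profile.n_residues} residues)")
print("\nchain res  raw    smoothed")
for (chain, seq, icode), raw in list(profile.residue_raw.items())[:10]:
    print(f"{chain}     {seq:<4d} {raw:.4f} "
          f"{profile.residue_smoothed[(chain, seq, icode)]:.4f}")

held_out = make_toy_polypeptide("AGSVKLNQT", "extended", seed=9)
held_profile = score_structure(held_out, potential, window=5)
print(f"\nheld-out toy peptide global score: {held_profile.global_score:.4f}")
print("\nScores near 1 mean contact environments typical of the training "
      "set;\nnear 0, atypical ones.  The held-out chain scores lower than "
      "the\nself-scored one - with a toy potential the numbers demonstrate "
      "the\nmachinery, not real model quality.")
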
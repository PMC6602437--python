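"""Train a contact-type potential on synthetic polypeptides.

Pools area-weighted contact observations from a few toy structures,
estimates pseudo-energies E = ln(P_expected / P_observed) for every
realizable contact type, self-calibrates the per-atom-type (mu, sigma)
of the quality transform, and writes the potential file.
"""

from pathlib import Path

import logging

from tessqa.fixtures import make_toy_dimer, make_toy_polypeptide
from tessqa.pipeline import train_from_structures
from tessqa.potential import ContactCategory, save_potential
from tessqa.structure import default_registry

logging.basicConfig(level=logging.ERROR)

structures = [
    make_toy_polypeptide("ACDEFGHIKLMNPQRSTVWY", "extended", seed=1),
    make_toy_polypeptide("KLMNPQRSTVWA", "helix", seed=2),
    make_toy_dimer("ADE", "KNQ", gap=1.0, seed=3),
]
potential = train_from_structures(structures)

out = Path("scratch")
out.mkdir(exist_ok=True)
save_potential(potential, out / "toy_potential.tsv")

registry = default_registry()
print(f"trained on {len(structures)} structures; "
      f"{len(potential.energies)} contact types "
      f"({potential.metadata['n_observed_types']} observed)")
print(f"potential file: {out / 'toy_potential.tsv'}")
print("\nexample energies (negative = over-represented = favorable):")
shown = 0
for (a, b, cat), e in sorted(potential.energies.items(),
                             key=lambda kv: kv[1]):
    if cat == ContactCategory.SOLVENT or shown >= 5:
        continue
    print(f"  {registry.type_name(a):<10s} {registry.type_name(b):<10s} "
          f"{ContactCategory(cat).label:<9s} E = {e:+.3f}")
    shown += 1
print(f"\nglobal calibration: mu = {potential.global_mu:+.3f}, "
      f"sigma = {potential.global_sigma:.3f}")
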
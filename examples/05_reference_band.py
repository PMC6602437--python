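"""Quantile bands of global scores versus structure size.

Given a collection of (n_residues, global_score) observations, running
5% / 50% / 95% quantiles over log-spaced size bins give the reference
band against which a new structure's score can be judged: a score below
the 5% curve for its size flags a suspicious structure.
"""

import numpy as np

from tessqa.scoring import reference_band

# Synthetic stand-in for a scored reference set: scores drift up with
# size and carry noise, as score collections over structure sets do.
rng = np.random.default_rng(0)
sizes = rng.integers(30, 600, 2000)
scores = np.clip(0.45 + 0.05 * np.log10(sizes) + rng.normal(0, 0.06, 2000),
                 0, 1)

band = reference_band(zip(sizes, scores), quantiles=(0.05, 0.5, 0.95),
                      n_bins=6)
print("size-bin center   q05     q50     q95")
for (x, q05), (_, q50), (_, q95) in zip(band[0.05], band[0.5], band[0.95]):
    print(f"{x:12.1f}    {q05:.4f}  {q50:.4f}  {q95:.4f}")
print("\n90% of scores fall between the q05 and q95 curves; a structure "
      "scoring\nbelow q05 for its size deserves scrutiny.")
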
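"""Tessellation-derived contact areas on small ball systems.

Builds a two-ball system with a known closed-form contact area, then a
random five-ball system cross-checked against the Monte-Carlo oracle.
"""

import math

import numpy as np

from tessqa.fixtures import make_ball_system
from tessqa.geometry import BallCloud, compute_contacts, mc_area_oracle

probe = 1.4

# Two equal balls: the face is the mid-plane disk clipped to the SAS union,
# area = pi * ((r + probe)^2 - (d/2)^2).
pair = BallCloud(np.array([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0]]),
                 np.array([1.9, 1.9]))
contacts = compute_contacts(pair, probe)
closed = math.pi * ((1.9 + probe) ** 2 - 1.5**2)
print(f"two-ball face area   : {contacts.area(0, 1):8.4f} A^2")
print(f"closed form          : {closed:8.4f} A^2")
print(f"solvent area ball 0  : {contacts.solvent_areas[0]:8.4f} A^2")

# Random five-ball system: every deterministic area should sit within the
# Monte-Carlo oracle's sampling noise.
balls = make_ball_system(5, seed=12)
contacts = compute_contacts(balls, probe)
print("\npair   deterministic   mc_estimate   mc_se      z")
for q_i, (i, j) in enumerate(sorted(contacts.pair_areas)):
    mc, se = mc_area_oracle(balls, probe, ("pair", i, j), 100_000, seed=q_i)
    z = (contacts.area(i, j) - mc) / se if se > 0 else 0.0
    print(f"{i}-{j}    {contacts.area(i, j):10.4f}    {mc:10.4f}  {se:7.4f}  {z:+5.2f}")
print("\n|z| <~ 3 means the exact clipping and the sampling oracle agree.")
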
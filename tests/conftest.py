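"""Shared fixtures: synthetic structures and a session-trained potential.

Contact computation dominates runtime, so structures, contact sets and
the trained potential are session-scoped and reused across test modules.
"""

from __future__ import annotations

import pytest

from tessqa import fixtures
from tessqa.geometry import compute_contacts
from tessqa.pipeline import train_from_structures
from tessqa.structure import default_registry


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def peptide():
    """Extended 20-mer covering all standard residue types."""
    return fixtures.make_toy_polypeptide("ACDEFGHIKLMNPQRSTVWY", "extended", seed=1)


@pytest.fixture(scope="session")
def helix():
    return fixtures.make_toy_polypeptide("KLMNPQRSTVWA", "helix", seed=2)


@pytest.fixture(scope="session")
def small_peptide():
    return fixtures.make_toy_polypeptide("AGSVKL", "extended", seed=4)


@pytest.fixture(scope="session")
def dimer():
    return fixtures.make_toy_dimer("ADE", "KNQ", gap=1.0, seed=3)


@pytest.fixture(scope="session")
def far_dimer():
    return fixtures.make_toy_dimer("AD", "KN", gap=50.0, seed=6)


@pytest.fixture(scope="session")
def peptide_contacts(peptide):
    return compute_contacts(peptide)


@pytest.fixture(scope="session")
def dimer_contacts(dimer):
    return compute_contacts(dimer)


@pytest.fixture(scope="session")
def potential(peptide, helix, dimer):
    """Potential trained on the toy set with self-calibrated (mu, sigma)."""
    return train_from_structures([peptide, helix, dimer])
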
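"""High-level workflows: train a potential from structures, score models."""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

from .geometry import ContactSet, compute_contacts
from .potential import (
    ObservationTable,
    PotentialTable,
    estimate_quality_params,
    train_potential,
)
from .scoring import ScoreProfile, atom_normalized_energies, score_structure
from .structure import Structure

logger = logging.getLogger(__name__)

__all__ = ["train_from_structures", "score_structures"]


def train_from_structures(
    structures: Sequence[Structure],
    probe_radius: float = 1.4,
    pseudocount: float = 1.0,
    description: str = "",
    **contact_kwargs,
) -> PotentialTable:
    """Train energies and calibrate (mu, sigma) on a set of structures.

    Contact observations from all structures are pooled for the energy
    estimate; the same structures, scored with the fresh energies, then
    calibrate the per-atom-type (mu, sigma) of the quality transform
    (self-calibration).
    """
    if not structures:
        raise ValueError("no training structures")
    contact_sets: list[ContactSet] = []
    obs = ObservationTable()
    for s in structures:
        contacts = compute_contacts(s, probe_radius=probe_radius, **contact_kwargs)
        contact_sets.append(contacts)
        obs.add_contact_set(s, contacts)
    potential = train_potential(obs, pseudocount=pseudocount)

    en_by_type: dict[int, list[float]] = {}
    for s, contacts in zip(structures, contact_sets):
        energies = atom_normalized_energies(s, contacts, potential)
        for i, e in energies.items():
            en_by_type.setdefault(s.atoms[i].atom_type, []).append(e)
    mu, sigma, gmu, gsigma = estimate_quality_params(en_by_type)
    potential.mu = mu
    potential.sigma = sigma
    potential.global_mu = gmu
    potential.global_sigma = gsigma
    potential.metadata["training_set"] = (
        description or f"{len(structures)} structure(s), self-calibrated"
    )
    potential.validate()
    return potential


def score_structures(
    structures: Iterable[Structure],
    potential: PotentialTable,
    **kwargs,
) -> list[tuple[Structure, ScoreProfile]]:
    """Score several structures; parse/score failures are logged and skipped."""
    out = []
    for s in structures:
        try:
            out.append((s, score_structure(s, potential, **kwargs)))
        except Exception:
            logger.exception("failed to score %r; skipping", s.label)
    return out
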
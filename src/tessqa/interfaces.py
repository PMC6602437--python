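"""Inter-chain interface scoring and multi-model ranking.

The interface of a complex is the set of contacts between atoms of
different chains.  Its quality score is the unweighted mean quality of
all atoms participating in inter-chain contacts; its pseudo-energy is
the sum over inter-chain contacts of contact area times the contact
type's pseudo-energy (more negative = more favorable).  A round-robin
tournament combining whole-structure score, interface score and
interface energy ranks competing models of the same complex.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .geometry import ContactSet, restrict_to_interchain
from .potential import PotentialTable, categorize_contact
from .structure import Structure

__all__ = [
    "InterfaceSummary",
    "assess_interface",
    "tournament_rank",
    "default_sort",
    "write_interface_tsv",
    "TOURNAMENT_RULE",
]

TOURNAMENT_RULE = "majority-2of3/v1"

ResidueKey = tuple[str, int, str]


@dataclass
class InterfaceSummary:
    """Bookkeeping and scores of the pooled inter-chain interface."""

    n_interface_atoms: int
    n_interface_residues: int
    total_area: float
    interface_score: float | None  # None when there are no inter-chain contacts
    interface_energy: float
    per_interface_atom_quality: dict[int, float] = field(default_factory=dict)
    per_interface_residue_quality: dict[ResidueKey, float] = field(default_factory=dict)
    per_residue_interchain_area: dict[ResidueKey, float] = field(default_factory=dict)

    def validate(self) -> None:
        assert self.n_interface_atoms == len(self.per_interface_atom_quality)
        assert self.n_interface_residues == len(self.per_interface_residue_quality)


def assess_interface(
    structure: Structure,
    contacts: ContactSet,
    atom_quality: Mapping[int, float],
    potential: PotentialTable,
) -> InterfaceSummary:
    """Score the pooled inter-chain interface of a multi-chain structure.

    Interface atoms are those with at least one inter-chain contact; the
    interface score is the plain mean of their quality scores, and the
    per-residue interface quality averages only that residue's interface
    atoms.  Separated chains yield a zero-contact summary with an
    undefined (None) interface score.
    """
    inter = restrict_to_interchain(contacts, structure)
    atoms = structure.atoms

    iface_atoms: set[int] = set()
    energy = 0.0
    res_area: dict[ResidueKey, float] = {}
    for (i, j), area in inter.pair_areas.items():
        iface_atoms.update((i, j))
        energy += area * potential.energies[categorize_contact(atoms[i], atoms[j])]
        for k in (i, j):
            key = atoms[k].residue_key
            res_area[key] = res_area.get(key, 0.0) + area

    atom_q = {
        i: atom_quality[i] for i in sorted(iface_atoms) if i in atom_quality
    }
    res_q: dict[ResidueKey, list[float]] = {}
    for i, q in atom_q.items():
        res_q.setdefault(atoms[i].residue_key, []).append(q)

    total_area = sum(inter.pair_areas.values())
    score = float(np.mean(list(atom_q.values()))) if atom_q else None
    summary = InterfaceSummary(
        n_interface_atoms=len(atom_q),
        n_interface_residues=len(res_q),
        total_area=total_area,
        interface_score=score,
        interface_energy=energy,
        per_interface_atom_quality=atom_q,
        per_interface_residue_quality={
            k: float(np.mean(v)) for k, v in res_q.items()
        },
        per_residue_interchain_area=res_area,
    )
    summary.validate()
    return summary


@dataclass(frozen=True)
class RankedModel:
    label: str
    wins: int
    global_score: float


def _beats(x, y) -> bool:
    """Model x beats y when it wins at least 2 of 3 criteria."""
    gx, ix, ex = x
    gy, iy, ey = y
    wins = 0
    wins += gx > gy
    wins += (ix is not None and (iy is None or ix > iy))
    wins += ex < ey
    return wins >= 2


def tournament_rank(
    models: Sequence[tuple[str, float, InterfaceSummary]],
) -> list[RankedModel]:
    """Round-robin ranking over (global score, interface score, interface energy).

    Each pair of models is compared on three criteria — higher global
    score, higher interface score, lower interface energy — and the model
    winning at least two criteria takes the pairwise win.  Models are
    ranked by win count; ties break by global score, then label.
    """
    if not models:
        raise ValueError("need at least one model to rank")
    labels = [m[0] for m in models]
    if len(set(labels)) != len(labels):
        raise ValueError("model labels must be unique")
    crit = {
        label: (g, s.interface_score, s.interface_energy)
        for label, g, s in models
    }
    wins = {label: 0 for label in labels}
    for a in labels:
        for b in labels:
            if a < b:
                if _beats(crit[a], crit[b]):
                    wins[a] += 1
                elif _beats(crit[b], crit[a]):
                    wins[b] += 1
    order = sorted(labels, key=lambda l: (-wins[l], -crit[l][0], l))
    return [RankedModel(l, wins[l], crit[l][0]) for l in order]


def default_sort(models: Iterable[tuple[str, float]]) -> list[str]:
    """Labels ordered by descending global score; ties lexicographic."""
    return [l for l, _ in sorted(models, key=lambda m: (-m[1], m[0]))]


def write_interface_tsv(label: str, summary: InterfaceSummary) -> str:
    score = "NA" if summary.interface_score is None else f"{summary.interface_score:.6f}"
    return (
        f"{label}\t{summary.n_interface_atoms}\t{summary.n_interface_residues}\t"
        f"{summary.total_area:.4f}\t{score}\t{summary.interface_energy:.4f}"
    )


def write_interface_residue_tsv(structure: Structure,
                                summary: InterfaceSummary) -> str:
    lines = ["chain\tresidue\tresidue_name\tinterface_quality\tinterchain_area"]
    name_of = {a.residue_key: a.residue_name for a in structure.atoms}
    for key in sorted(summary.per_residue_interchain_area):
        chain, seq, icode = key
        q = summary.per_interface_residue_quality.get(key)
        lines.append(
            f"{chain}\t{seq}{icode}\t{name_of[key]}\t"
            f"{'NA' if q is None else format(q, '.6f')}\t"
            f"{summary.per_residue_interchain_area[key]:.4f}"
        )
    return "\n".join(lines) + "\n"
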
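"""Contact-type statistical potential.

A contact type is a canonical triple ``(type_a, type_b, category)`` of two
atom types and a contact category; the solvent pseudo-partner is a
reserved type.  The pseudo-energy of a type is the natural-log ratio of
its expected probability under an independence null to its observed,
area-weighted probability in a training set:

    E(a, b, c) = ln( P_expected(a, b, c) / P_observed(a, b, c) )

so over-represented (favorable) contact types get negative energies.
The null factorizes observed mass into endpoint atom-type marginals ``f``
and category marginals ``g``:

    P_expected(a, b, c) = g(c) * f(a) * f(b) * (2 - delta_ab)   (sequence categories)
    P_expected(a, solvent)  = g(solvent) * f(a)

which sums to one over the realizable type space, so no renormalization
is needed.  The per-atom-type mean and standard deviation of normalized
atomic energies, estimated on the training set itself, parameterize the
erf transform to quality scores.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .structure import AtomBall, AtomTypeRegistry, Structure, default_registry
from .geometry import ContactSet

logger = logging.getLogger(__name__)

__all__ = [
    "ContactCategory",
    "ObservationTable",
    "PotentialTable",
    "categorize_contact",
    "category_of",
    "independence_null",
    "realizable_types",
    "train_potential",
    "estimate_quality_params",
    "save_potential",
    "load_potential",
    "SCHEME_ID",
]

SCHEME_ID = "seqsep3/v1"  # 3-way category scheme; recorded in every potential
FILE_VERSION = 1

SOLVENT_TYPE = 0


class ContactCategory(enum.IntEnum):
    """Discrete contact context: sequence-near, sequence-far, or solvent."""

    SEQ_NEAR = 0   # same residue or |sequence separation| <= 1 within a chain
    SEQ_FAR = 1    # separation >= 2, or inter-chain
    SOLVENT = 2

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def from_label(cls, text: str) -> "ContactCategory":
        return cls[text.strip().upper()]


TypeKey = tuple[int, int, ContactCategory]


def category_of(same_chain: bool, seq_separation: int) -> ContactCategory:
    """Category of an atom-atom contact from its chain/sequence context."""
    if same_chain and abs(seq_separation) <= 1:
        return ContactCategory.SEQ_NEAR
    return ContactCategory.SEQ_FAR


def categorize_contact(atom_i: AtomBall, atom_j: AtomBall | None = None) -> TypeKey:
    """Canonical contact type of a pair, or of a solvent contact (j=None)."""
    if atom_j is None:
        return (SOLVENT_TYPE, atom_i.atom_type, ContactCategory.SOLVENT)
    cat = category_of(
        atom_i.chain_id == atom_j.chain_id,
        atom_i.residue_seq - atom_j.residue_seq,
    )
    a, b = sorted((atom_i.atom_type, atom_j.atom_type))
    return (a, b, cat)


def _canonical(ta: int, tb: int, cat: ContactCategory) -> TypeKey:
    a, b = sorted((ta, tb))
    return (a, b, ContactCategory(cat))


@dataclass
class ObservationTable:
    """Area-weighted contact-type totals accumulated over structures."""

    areas: dict[TypeKey, float] = field(default_factory=dict)

    def add(self, ta: int, tb: int, cat: ContactCategory, area: float) -> None:
        if area < 0:
            raise ValueError("contact area must be non-negative")
        key = _canonical(ta, tb, cat)
        self.areas[key] = self.areas.get(key, 0.0) + area

    @property
    def grand_total(self) -> float:
        return sum(self.areas.values())

    def add_contact_set(self, structure: Structure, contacts: ContactSet) -> None:
        """Accumulate every contact of a structure into the table."""
        atoms = structure.atoms
        for (i, j), area in contacts.pair_areas.items():
            ta, tb, cat = categorize_contact(atoms[i], atoms[j])
            self.add(ta, tb, cat, area)
        for i, area in contacts.solvent_areas.items():
            ta, tb, cat = categorize_contact(atoms[i])
            self.add(ta, tb, cat, area)

    def merge(self, other: "ObservationTable") -> None:
        for (ta, tb, cat), area in other.areas.items():
            self.add(ta, tb, cat, area)


@dataclass
class PotentialTable:
    """Trained pseudo-energies plus per-atom-type (mu, sigma)."""

    energies: dict[TypeKey, float]
    mu: dict[int, float] = field(default_factory=dict)
    sigma: dict[int, float] = field(default_factory=dict)
    global_mu: float = 0.0
    global_sigma: float = 1.0
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.metadata.setdefault("scheme", SCHEME_ID)
        self.metadata.setdefault("log_base", "natural")

    def energy(self, ta: int, tb: int, cat: ContactCategory) -> float:
        return self.energies[_canonical(ta, tb, cat)]

    def quality_params(self, atom_type: int) -> tuple[float, float]:
        """(mu, sigma) for an atom type, falling back to the global pair."""
        if atom_type in self.mu:
            return self.mu[atom_type], self.sigma[atom_type]
        logger.warning("atom type %d has no calibration; using global (mu, sigma)",
                       atom_type)
        return self.global_mu, self.global_sigma

    def validate(self) -> None:
        for key, e in self.energies.items():
            if not math.isfinite(e):
                raise ValueError(f"non-finite energy for type {key}")
        for t, s in self.sigma.items():
            if not (s > 0):
                raise ValueError(f"sigma must be positive for atom type {t}")
        if not (self.global_sigma > 0):
            raise ValueError("global sigma must be positive")


def realizable_types(registry: AtomTypeRegistry | None = None) -> list[TypeKey]:
    """All contact types the category scheme allows, in canonical order."""
    registry = registry or default_registry()
    types = registry.protein_types
    keys: list[TypeKey] = []
    for cat in (ContactCategory.SEQ_NEAR, ContactCategory.SEQ_FAR):
        for ai, a in enumerate(types):
            for b in types[ai:]:
                keys.append((a, b, cat))
    for a in types:
        keys.append((SOLVENT_TYPE, a, ContactCategory.SOLVENT))
    return keys


def independence_null(probs: Mapping[TypeKey, float]) -> dict[TypeKey, float]:
    """Expected probability of each type under the independence null.

    Marginals are taken from ``probs``; the returned values follow the
    factorized formula on the same keys (already normalized over the full
    realizable space).
    """
    endpoint: dict[int, float] = {}
    g: dict[ContactCategory, float] = {}
    for (a, b, cat), p in probs.items():
        g[cat] = g.get(cat, 0.0) + p
        if cat == ContactCategory.SOLVENT:
            endpoint[b] = endpoint.get(b, 0.0) + p
        else:
            endpoint[a] = endpoint.get(a, 0.0) + p
            endpoint[b] = endpoint.get(b, 0.0) + p
    total = sum(endpoint.values())
    if total <= 0:
        raise ValueError("no observed mass to build the null from")
    f = {t: m / total for t, m in endpoint.items()}

    null: dict[TypeKey, float] = {}
    for (a, b, cat) in probs:
        if cat == ContactCategory.SOLVENT:
            null[(a, b, cat)] = g.get(cat, 0.0) * f.get(b, 0.0)
        else:
            mult = 1.0 if a == b else 2.0
            null[(a, b, cat)] = g.get(cat, 0.0) * f.get(a, 0.0) * f.get(b, 0.0) * mult
    return null


def train_potential(
    obs: ObservationTable,
    pseudocount: float = 1.0,
    registry: AtomTypeRegistry | None = None,
    type_space: str = "registry",
) -> PotentialTable:
    """Pseudo-energies ``ln(P_expected / P_observed)`` over a contact-type space.

    ``pseudocount`` (in A^2) is added to every type's area so unobserved
    types stay finite; it must be positive whenever any type in the space
    has zero observed area.  ``type_space='registry'`` trains over every
    realizable type of the atom-type registry (the scoring default);
    ``type_space='observed'`` restricts to the types present in the
    table, which keeps the estimate undistorted when the table covers a
    deliberately small type space (e.g. simulation studies).
    """
    registry = registry or default_registry()
    if obs.grand_total <= 0:
        raise ValueError("observation table is empty")
    if type_space == "registry":
        keys = realizable_types(registry)
        unknown = set(obs.areas) - set(keys)
        if unknown:
            raise ValueError(
                f"observations contain non-realizable types: {sorted(unknown)[:3]}"
            )
    elif type_space == "observed":
        keys = sorted(obs.areas)
    else:
        raise ValueError("type_space must be 'registry' or 'observed'")
    raw = np.array([obs.areas.get(k, 0.0) for k in keys], dtype=float)
    if pseudocount <= 0 and (raw <= 0).any():
        raise ValueError(
            "zero-area contact types present: a positive pseudocount is required"
        )
    areas = raw + pseudocount
    p_obs = areas / areas.sum()
    null = independence_null(dict(zip(keys, p_obs)))
    energies = {
        k: math.log(null[k] / p) if null[k] > 0 else math.inf
        for k, p in zip(keys, p_obs)
    }
    bad = [k for k, e in energies.items() if not math.isfinite(e)]
    if bad:
        raise ValueError(f"non-finite energies for types {bad[:3]}")
    return PotentialTable(
        energies,
        metadata={
            "scheme": SCHEME_ID,
            "log_base": "natural",
            "pseudocount": repr(float(pseudocount)),
            "n_observed_types": str(int((raw > 0).sum())),
            "grand_total_area": f"{obs.grand_total:.4f}",
        },
    )


def estimate_quality_params(
    en_by_type: Mapping[int, Sequence[float]],
) -> tuple[dict[int, float], dict[int, float], float, float]:
    """Per-atom-type (mu, sigma) of normalized atomic energies.

    Types with fewer than two observations, or zero spread, inherit the
    global statistics (with a warning).  Returns
    ``(mu, sigma, global_mu, global_sigma)``.
    """
    pooled = [e for values in en_by_type.values() for e in values]
    if len(pooled) < 2:
        raise ValueError("need at least two atomic energies to calibrate")
    global_mu = float(np.mean(pooled))
    global_sigma = float(np.std(pooled, ddof=1))
    if global_sigma <= 0:
        raise ValueError("all atomic energies identical: sigma would be zero")

    mu: dict[int, float] = {}
    sigma: dict[int, float] = {}
    for t, values in en_by_type.items():
        arr = np.asarray(list(values), dtype=float)
        if len(arr) >= 2 and float(np.std(arr, ddof=1)) > 0:
            mu[t] = float(np.mean(arr))
            sigma[t] = float(np.std(arr, ddof=1))
        else:
            logger.warning(
                "atom type %d: %d observation(s); inheriting global (mu, sigma)",
                t, len(arr),
            )
            mu[t] = global_mu
            sigma[t] = global_sigma
    return mu, sigma, global_mu, global_sigma


# ---------------------------------------------------------------------------
# Serialization: versioned, human-readable TSV


def save_potential(potential: PotentialTable, path: str | Path,
                   registry: AtomTypeRegistry | None = None) -> None:
    potential.validate()
    registry = registry or default_registry()
    lines = [f"#version {FILE_VERSION}"]
    for k in sorted(potential.metadata):
        lines.append(f"#{k} {potential.metadata[k]}")
    lines.append("[energies]")
    lines.append("type_a\ttype_b\tcategory\tE")
    for (a, b, cat) in sorted(potential.energies):
        lines.append(
            f"{registry.type_name(a)}\t{registry.type_name(b)}\t"
            f"{ContactCategory(cat).label}\t{potential.energies[(a, b, cat)]:.8f}"
        )
    lines.append("[quality_params]")
    lines.append("atom_type\tmu\tsigma")
    lines.append(f"GLOBAL\t{potential.global_mu:.8f}\t{potential.global_sigma:.8f}")
    for t in sorted(potential.mu):
        lines.append(
            f"{registry.type_name(t)}\t{potential.mu[t]:.8f}\t{potential.sigma[t]:.8f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


class PotentialFormatError(ValueError):
    pass


def load_potential(path: str | Path,
                   registry: AtomTypeRegistry | None = None) -> PotentialTable:
    registry = registry or default_registry()
    text = Path(path).read_text()
    lines = text.splitlines()
    if not lines or not lines[0].startswith("#version"):
        raise PotentialFormatError(f"{path}: missing #version header")
    version = int(lines[0].split()[1])
    if version != FILE_VERSION:
        raise PotentialFormatError(
            f"{path}: unsupported potential file version {version}"
        )
    metadata: dict[str, str] = {}
    section = None
    energies: dict[TypeKey, float] = {}
    mu: dict[int, float] = {}
    sigma: dict[int, float] = {}
    global_mu = None
    global_sigma = None
    saw_energy_section = False
    saw_quality_section = False
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        if line.startswith("#"):
            key, _, value = line[1:].partition(" ")
            metadata[key] = value
            continue
        if line.startswith("["):
            section = line.strip()
            saw_energy_section |= section == "[energies]"
            saw_quality_section |= section == "[quality_params]"
            continue
        fields = line.split("\t")
        if section == "[energies]":
            if fields[0] == "type_a":
                continue
            if len(fields) != 4:
                raise PotentialFormatError(f"{path}:{lineno}: bad energy row")
            try:
                a = registry.type_from_name(fields[0])
                b = registry.type_from_name(fields[1])
                cat = ContactCategory.from_label(fields[2])
                e = float(fields[3])
            except (KeyError, ValueError) as exc:
                raise PotentialFormatError(f"{path}:{lineno}: {exc}") from exc
            if not math.isfinite(e):
                raise PotentialFormatError(
                    f"{path}:{lineno}: non-finite energy for {fields[0]}/{fields[1]}"
                )
            energies[_canonical(a, b, cat)] = e
        elif section == "[quality_params]":
            if fields[0] == "atom_type":
                continue
            if len(fields) != 3:
                raise PotentialFormatError(f"{path}:{lineno}: bad quality row")
            try:
                m, s = float(fields[1]), float(fields[2])
            except ValueError as exc:
                raise PotentialFormatError(f"{path}:{lineno}: {exc}") from exc
            if not (s > 0) or not math.isfinite(m):
                raise PotentialFormatError(
                    f"{path}:{lineno}: invalid (mu, sigma) for {fields[0]}"
                )
            if fields[0] == "GLOBAL":
                global_mu, global_sigma = m, s
            else:
                t = registry.type_from_name(fields[0])
                mu[t] = m
                sigma[t] = s
        else:
            raise PotentialFormatError(f"{path}:{lineno}: row outside any section")
    if not saw_energy_section or not energies:
        raise PotentialFormatError(f"{path}: no [energies] section (truncated file?)")
    if not saw_quality_section or global_sigma is None:
        raise PotentialFormatError(
            f"{path}: no [quality_params] section with a GLOBAL row (missing sigma)"
        )
    pot = PotentialTable(
        energies, mu, sigma,
        global_mu=global_mu, global_sigma=global_sigma, metadata=metadata,
    )
    pot.validate()
    return pot
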
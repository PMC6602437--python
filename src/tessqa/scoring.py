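"""Quality scores from contacts and a trained potential.

Each atom's contacts are reduced to a normalized pseudo-energy — the
area-weighted mean of the contact-type energies, solvent contacts
included:

    E_n = sum(E(type_w) * area_w) / sum(area_w)

and transformed to a quality score in (0, 1) with the Gauss error
function, standardized by the atom type's calibration (mu, sigma).
Because favorable contact types carry *negative* energies while a quality
score should be *high* for favorable atoms, the standardized energy is
negated inside the transform:

    Q_a = 1/2 * (1 + erf( (mu - E_n) / (sigma * sqrt(2)) ))

so Q_a = 0.5 exactly at E_n = mu and Q_a -> 1 as E_n falls below mu.
Residue scores are plain means of their atoms' Q_a; the global score is a
burial-weighted mean over all scored atoms.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import erf

from .geometry import BurialWeights, ContactSet, compute_burial_weights
from .potential import PotentialTable, SCHEME_ID, categorize_contact
from .structure import Structure

logger = logging.getLogger(__name__)

__all__ = [
    "ScoreProfile",
    "atom_normalized_energies",
    "atom_quality",
    "residue_scores",
    "smooth_residue_scores",
    "global_score",
    "reference_band",
    "score_structure",
]

ResidueKey = tuple[str, int, str]

DEFAULT_WINDOW = 5  # residues; sliding-window smoothing of the local profile


@dataclass
class ScoreProfile:
    """Per-atom, per-residue and global quality scores of one structure."""

    atom_energy: dict[int, float]
    atom_quality: dict[int, float]
    residue_raw: dict[ResidueKey, float]
    residue_smoothed: dict[ResidueKey, float]
    global_score: float
    n_atoms: int
    n_residues: int
    unscored_atoms: list[int] = field(default_factory=list)
    metadata: dict[str, str] = field(default_factory=dict)


def atom_normalized_energies(
    structure: Structure,
    contacts: ContactSet,
    potential: PotentialTable,
) -> dict[int, float]:
    """Area-weighted mean contact energy per atom (solvent included).

    Atoms with zero total contact area are absent from the result and
    must be reported as unscored by callers.
    """
    if potential.metadata.get("scheme", SCHEME_ID) != SCHEME_ID:
        raise ValueError(
            f"potential was trained with scheme "
            f"{potential.metadata.get('scheme')!r}, scorer uses {SCHEME_ID!r}"
        )
    atoms = structure.atoms
    num: dict[int, float] = {}
    den: dict[int, float] = {}
    for (i, j), area in contacts.pair_areas.items():
        e = potential.energies[categorize_contact(atoms[i], atoms[j])]
        for k in (i, j):
            num[k] = num.get(k, 0.0) + e * area
            den[k] = den.get(k, 0.0) + area
    for i, area in contacts.solvent_areas.items():
        e = potential.energies[categorize_contact(atoms[i])]
        num[i] = num.get(i, 0.0) + e * area
        den[i] = den.get(i, 0.0) + area
    return {i: num[i] / den[i] for i in num if den[i] > 0}


def atom_quality(e_n: float, atom_type: int, potential: PotentialTable) -> float:
    """erf-based quality score in (0, 1); 0.5 exactly at E_n = mu."""
    mu, sigma = potential.quality_params(atom_type)
    if not (sigma > 0):
        raise ValueError(f"sigma must be positive for atom type {atom_type}")
    return 0.5 * (1.0 + float(erf((mu - e_n) / (sigma * math.sqrt(2.0)))))


def residue_scores(
    quality: Mapping[int, float], structure: Structure
) -> dict[ResidueKey, float]:
    """Arithmetic mean of atom qualities per residue (unscored atoms excluded)."""
    out: dict[ResidueKey, float] = {}
    for key, atoms in structure.residues().items():
        vals = [quality[a.atom_index] for a in atoms if a.atom_index in quality]
        if vals:
            out[key] = float(np.mean(vals))
        else:
            logger.warning("residue %s has no scored atoms; omitted", key)
    return out


def smooth_residue_scores(
    raw: Mapping[ResidueKey, float],
    structure: Structure,
    window: int = DEFAULT_WINDOW,
) -> dict[ResidueKey, float]:
    """Centered moving average along each chain.

    The window must be odd; it shrinks at chain termini, and numbering
    gaps larger than one residue break the smoothing (no averaging across
    chain breaks).
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("smoothing window must be an odd positive integer")
    half = window // 2

    # Consecutive runs of residues per chain (ordered as in the structure).
    runs: list[list[ResidueKey]] = []
    prev: ResidueKey | None = None
    for key in structure.residues():
        if key not in raw:
            prev = None
            continue
        if (
            prev is not None
            and key[0] == prev[0]
            and key[1] - prev[1] <= 1
        ):
            runs[-1].append(key)
        else:
            runs.append([key])
        prev = key

    out: dict[ResidueKey, float] = {}
    for run in runs:
        vals = [raw[k] for k in run]
        for idx, key in enumerate(run):
            lo = max(0, idx - half)
            hi = min(len(run), idx + half + 1)
            out[key] = float(np.mean(vals[lo:hi]))
    return out


def global_score(
    quality: Mapping[int, float], weights: BurialWeights
) -> float:
    """Burial-weighted arithmetic mean of atomic quality scores."""
    if not quality:
        raise ValueError("no scored atoms: global score undefined")
    num = sum(weights[i] * q for i, q in quality.items())
    den = sum(weights[i] for i in quality)
    return num / den


def reference_band(
    observations: Iterable[tuple[int, float]],
    quantiles: Sequence[float] = (0.05, 0.5, 0.95),
    n_bins: int = 10,
) -> dict[float, list[tuple[float, float]]]:
    """Running quantiles of global scores over log-spaced size bins.

    ``observations`` are (n_residues, score) pairs.  Returns, per
    requested quantile, a list of (bin center, quantile value) points —
    the generic machinery behind score-versus-size reference bands.
    Requires at least 20 observations.
    """
    obs = sorted((int(n), float(s)) for n, s in observations)
    if len(obs) < 20:
        raise ValueError(f"need at least 20 observations, got {len(obs)}")
    sizes = np.array([n for n, _ in obs], dtype=float)
    scores = np.array([s for _, s in obs], dtype=float)
    lo, hi = sizes.min(), sizes.max()
    if lo <= 0:
        raise ValueError("sizes must be positive")
    edges = np.geomspace(lo, hi, n_bins + 1) if hi > lo else np.array([lo, hi + 1.0])
    edges[-1] = edges[-1] * (1 + 1e-12) + 1e-12
    out: dict[float, list[tuple[float, float]]] = {q: [] for q in quantiles}
    for b in range(len(edges) - 1):
        mask = (sizes >= edges[b]) & (sizes < edges[b + 1])
        if not mask.any():
            continue
        center = math.sqrt(edges[b] * min(edges[b + 1], hi if hi > lo else lo + 1))
        for q in quantiles:
            out[q].append((center, float(np.quantile(scores[mask], q))))
    return out


def score_structure(
    structure: Structure,
    potential: PotentialTable,
    contacts: ContactSet | None = None,
    weights: BurialWeights | None = None,
    window: int = DEFAULT_WINDOW,
    probe_radius: float | None = None,
    **contact_kwargs,
) -> ScoreProfile:
    """Full scoring pipeline for one structure.

    Computes contacts (unless given), per-atom energies and qualities,
    per-residue raw and smoothed scores, and the burial-weighted global
    score.  Deterministic: identical input and potential give identical
    output.
    """
    from .geometry import compute_contacts

    if contacts is None:
        kwargs = dict(contact_kwargs)
        if probe_radius is not None:
            kwargs["probe_radius"] = probe_radius
        contacts = compute_contacts(structure, **kwargs)
    if weights is None:
        weights = compute_burial_weights(structure, contacts)

    energies = atom_normalized_energies(structure, contacts, potential)
    quality = {
        i: atom_quality(e, structure.atoms[i].atom_type, potential)
        for i, e in energies.items()
    }
    unscored = sorted(set(range(len(structure))) - set(quality))
    if unscored:
        logger.warning("%d atom(s) with zero contact area left unscored", len(unscored))
    raw = residue_scores(quality, structure)
    smoothed = smooth_residue_scores(raw, structure, window)
    g = global_score(quality, weights)
    return ScoreProfile(
        atom_energy=energies,
        atom_quality=quality,
        residue_raw=raw,
        residue_smoothed=smoothed,
        global_score=g,
        n_atoms=len(structure),
        n_residues=len(structure.residues()),
        unscored_atoms=unscored,
        metadata={
            "scheme": SCHEME_ID,
            "orientation": "negated-standardized-energy",
            "solvent_in_atom_energy": "true",
            "smoothing_window": str(window),
            "probe_radius": repr(contacts.probe_radius),
        },
    )


# ---------------------------------------------------------------------------
# Tabular output


def write_residue_tsv(profile: ScoreProfile, structure: Structure,
                      contacts: ContactSet) -> str:
    solvent_by_res: dict[ResidueKey, float] = {}
    for i, area in contacts.solvent_areas.items():
        key = structure.atoms[i].residue_key
        solvent_by_res[key] = solvent_by_res.get(key, 0.0) + area
    lines = ["chain\tresidue\tresidue_name\traw_score\tsmoothed_score\tsolvent_area"]
    for key, atoms in structure.residues().items():
        if key not in profile.residue_raw:
            continue
        chain, seq, icode = key
        lines.append(
            f"{chain}\t{seq}{icode}\t{atoms[0].residue_name}\t"
            f"{profile.residue_raw[key]:.6f}\t{profile.residue_smoothed[key]:.6f}\t"
            f"{solvent_by_res.get(key, 0.0):.4f}"
        )
    return "\n".join(lines) + "\n"


def write_atom_tsv(profile: ScoreProfile, structure: Structure,
                   contacts: ContactSet) -> str:
    lines = ["chain\tresidue\tresidue_name\tatom\tenergy\tquality\tsolvent_area"]
    for a in structure.atoms:
        i = a.atom_index
        if i not in profile.atom_quality:
            continue
        lines.append(
            f"{a.chain_id}\t{a.residue_seq}{a.insertion_code}\t{a.residue_name}\t"
            f"{a.atom_name}\t{profile.atom_energy[i]:.6f}\t"
            f"{profile.atom_quality[i]:.6f}\t"
            f"{contacts.solvent_areas.get(i, 0.0):.4f}"
        )
    return "\n".join(lines) + "\n"


def global_summary_row(label: str, profile: ScoreProfile) -> str:
    return (f"{label}\t{profile.global_score:.6f}\t"
            f"{profile.n_atoms}\t{profile.n_residues}")
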
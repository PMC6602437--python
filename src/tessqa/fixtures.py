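"""Deterministic generators of synthetic inputs.

Every generator is a pure function of its parameters and seed.  The toy
polypeptides are chemically naive — idealized internal-coordinate
templates, not Ramachandran-valid conformers — but carry correct residue
and atom naming, connectivity-consistent distances and no steric
collapse, which is what the tessellation, typing and scoring paths need.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import brentq

from .geometry import BallCloud
from .potential import ContactCategory, ObservationTable, independence_null
from .residues import ONE_TO_THREE, SIDE_CHAIN_TEMPLATES
from .structure import AtomBall, Structure, default_registry

__all__ = [
    "make_ball_system",
    "make_toy_polypeptide",
    "make_toy_dimer",
    "make_synthetic_observations",
    "export_fixture",
]


def make_ball_system(
    n: int,
    box: float = 10.0,
    radius_range: tuple[float, float] = (1.5, 2.0),
    min_separation: float = 2.0,
    seed: int = 0,
    max_tries: int = 20_000,
) -> BallCloud:
    """Random ball packing in a cubic box with a minimum center separation."""
    if n < 1:
        raise ValueError("need at least one ball")
    rng = np.random.default_rng(seed)
    centers: list[np.ndarray] = []
    tries = 0
    while len(centers) < n:
        if tries > max_tries:
            raise RuntimeError(
                f"could not pack {n} balls with separation {min_separation} "
                f"in a box of {box} A after {max_tries} tries"
            )
        tries += 1
        p = rng.uniform(0.0, box, 3)
        if all(np.linalg.norm(p - q) >= min_separation for q in centers):
            centers.append(p)
    radii = rng.uniform(radius_range[0], radius_range[1], n)
    return BallCloud(np.array(centers), radii, label=f"balls(n={n},seed={seed})")


# ---------------------------------------------------------------------------
# Toy polypeptides

_BOND = 1.35       # generic heavy-atom bond step along a side chain
_CB_BOND = 1.53
_LATERAL = 1.4     # lateral slot spacing for branched side chains


def _backbone_extended(i: int) -> dict[str, np.ndarray]:
    s = 1.0 if i % 2 == 0 else -1.0
    ca = np.array([3.8 * i, 0.35 * s, 0.0])
    return {
        "N": ca + np.array([-1.25, 0.55 * s, 0.0]),
        "CA": ca,
        "C": ca + np.array([1.25, 0.55 * s, 0.0]),
        "O": ca + np.array([1.45, 0.55 * s, 1.15 * s]),
        "_side_dir": np.array([0.0, 0.0, -s]),   # unit: side-chain direction
        "_lat_dir": np.array([1.0, 0.0, 0.0]),
    }


def _backbone_helix(i: int) -> dict[str, np.ndarray]:
    theta = math.radians(100.0) * i
    axis_z = 1.5 * i
    r_ca = 2.3
    radial = np.array([math.cos(theta), math.sin(theta), 0.0])
    tangent = np.array([-math.sin(theta), math.cos(theta), 0.0])
    ca = r_ca * radial + np.array([0.0, 0.0, axis_z])
    return {
        "N": ca - 1.2 * tangent - 0.35 * radial,
        "CA": ca,
        "C": ca + 1.2 * tangent - 0.35 * radial,
        "O": ca + 1.35 * tangent - 1.35 * radial,
        "_side_dir": radial,
        "_lat_dir": tangent,
    }


def make_toy_polypeptide(
    sequence: str,
    geometry: str = "extended",
    seed: int = 0,
    chain_id: str = "A",
    start_res: int = 1,
    label: str | None = None,
) -> Structure:
    """Synthetic single-chain polypeptide with all standard heavy atoms.

    ``geometry`` is ``extended`` (pleated strand, side chains alternating
    up/down) or ``helix`` (side chains radially outward, bringing i/i+3
    side chains into sequence-distant contact).  A small seeded jitter
    (±0.05 A) breaks exact coplanarity; the result is deterministic in
    (sequence, geometry, seed).
    """
    sequence = sequence.strip().upper()
    if not sequence:
        raise ValueError("empty sequence")
    bad = [c for c in sequence if c not in ONE_TO_THREE]
    if bad:
        raise ValueError(f"invalid residue letter(s): {sorted(set(bad))}")
    if geometry not in ("extended", "helix"):
        raise ValueError("geometry must be 'extended' or 'helix'")
    backbone = _backbone_extended if geometry == "extended" else _backbone_helix

    registry = default_registry()
    rng = np.random.default_rng(seed)
    atoms: list[AtomBall] = []
    idx = 0
    for i, letter in enumerate(sequence):
        res = ONE_TO_THREE[letter]
        frame = backbone(i)
        side_dir, lat_dir = frame["_side_dir"], frame["_lat_dir"]
        up = np.cross(side_dir, lat_dir)
        placed: dict[str, np.ndarray] = {
            name: frame[name] for name in ("N", "CA", "C", "O")
        }
        cb_base = frame["CA"] + _CB_BOND * side_dir
        for name, depth, lateral in SIDE_CHAIN_TEMPLATES[res]:
            pos = (cb_base + _BOND * depth * side_dir
                   + _LATERAL * lateral * lat_dir
                   + 0.25 * (depth % 2) * up)
            placed[name] = pos
        for name in placed:
            placed[name] = placed[name] + rng.uniform(-0.05, 0.05, 3)
        for name, pos in placed.items():
            tid, radius, canonical = registry.lookup(res, name)
            atoms.append(
                AtomBall(
                    atom_index=idx, chain_id=chain_id,
                    residue_seq=start_res + i, insertion_code="",
                    residue_name=res, atom_name=canonical,
                    center=pos, radius=radius, atom_type=tid,
                    element=canonical[0],
                )
            )
            idx += 1

    structure = Structure(
        atoms, label=label or f"toy-{geometry}-{sequence[:8]}(seed={seed})"
    )
    _assert_separation(structure)
    return structure


def _assert_separation(structure: Structure, min_dist: float = 0.8) -> None:
    from scipy.spatial import cKDTree

    tree = cKDTree(structure.centers)
    if tree.query_pairs(min_dist):
        raise RuntimeError(
            f"generated structure {structure.label!r} has atoms closer "
            f"than {min_dist} A — template error"
        )


def make_toy_dimer(
    sequence_a: str,
    sequence_b: str,
    gap: float = 1.0,
    seed: int = 0,
    label: str | None = None,
) -> Structure:
    """Two toy chains stacked with a controlled inter-chain surface gap.

    Chain B is flipped and translated along z until the smallest
    surface-to-surface distance between the chains equals ``gap`` (in A).
    A small gap yields a contact interface; a large one yields none.
    """
    a = make_toy_polypeptide(sequence_a, "extended", seed=seed, chain_id="A")
    b = make_toy_polypeptide(sequence_b, "extended", seed=seed + 1, chain_id="B")

    ca, ra = a.centers, a.radii
    cb, rb = b.centers.copy(), b.radii
    cb[:, 2] *= -1.0  # flip so both chains' side chains face each other

    def min_surface_gap(t: float) -> float:
        shifted = cb + np.array([0.0, 0.0, t])
        d = np.linalg.norm(ca[:, None, :] - shifted[None, :, :], axis=2)
        return float((d - ra[:, None] - rb[None, :]).min())

    lo, hi = 0.0, 200.0
    while min_surface_gap(lo) > gap:
        lo -= 50.0
    t = brentq(lambda t: min_surface_gap(t) - gap, lo, hi, xtol=1e-10)

    atoms: list[AtomBall] = list(a.atoms)
    idx = len(atoms)
    from dataclasses import replace

    for k, atom in enumerate(b.atoms):
        new_center = np.array([cb[k, 0], cb[k, 1], cb[k, 2] + t])
        atoms.append(replace(atom, atom_index=idx, center=new_center))
        idx += 1
    return Structure(
        atoms,
        label=label or f"toy-dimer-gap{gap:g}(seed={seed})",
    )


def export_fixture(structure: Structure, directory, name: str,
                   expected: dict | None = None) -> None:
    """Write a generated structure as PDB plus a JSON property sidecar.

    The sidecar records provenance (the generator label) and any
    expected-property annotations (e.g. closed-form areas) supplied by
    the caller, so exported fixtures stay self-describing.
    """
    import json
    from pathlib import Path

    from .structure import write_scored_pdb

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / f"{name}.pdb").write_text(write_scored_pdb(structure))
    sidecar = {
        "label": structure.label,
        "n_atoms": len(structure),
        "chains": structure.chains,
        "expected": expected or {},
    }
    (directory / f"{name}.json").write_text(json.dumps(sidecar, indent=2) + "\n")


# ---------------------------------------------------------------------------
# Synthetic contact-type observations


def make_synthetic_observations(
    p_observed: dict[tuple[int, int, ContactCategory], float],
    n_quanta: int = 100_000,
    seed: int = 0,
) -> tuple[ObservationTable, dict[tuple[int, int, ContactCategory], float]]:
    """Multinomial area quanta from a known contact-type distribution.

    Returns the observation table (1 A^2 quanta) together with the truth
    energies ``ln(P_expected / P_observed)`` where ``P_expected`` is the
    analytic independence null of the *exact* ``p_observed`` — the same
    null the trainer estimates from data.
    """
    types = sorted(p_observed)
    probs = np.array([p_observed[t] for t in types], dtype=float)
    if (probs < 0).any() or not math.isclose(probs.sum(), 1.0, rel_tol=1e-9):
        raise ValueError("p_observed must be a probability distribution")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_quanta, probs)
    table = ObservationTable()
    for t, c in zip(types, counts):
        if c:
            table.add(t[0], t[1], t[2], float(c))

    null = independence_null(dict(zip(types, probs)))
    truth = {
        t: math.log(null[t] / p_observed[t]) if p_observed[t] > 0 else math.inf
        for t in types
    }
    return table, truth
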
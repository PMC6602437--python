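"""Protein structure model and PDB input/output.

A structure is an ordered list of heavy-atom balls.  Each ball carries a
van der Waals radius and an atom-type id taken from the registry built
out of ``data/atom_classes.yaml``.  The PDB reader is intentionally
bespoke (fixed-column parsing) so that dialect handling — MODEL blocks,
altloc filtering, hydrogen and hetero-atom exclusion, non-standard
residue remapping — is fully under this package's control.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .residues import (
    BACKBONE_ATOMS,
    SIDE_CHAIN_ATOMS,
    STANDARD_RESIDUES,
    THREE_TO_ONE,
    element_of,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AtomBall",
    "Structure",
    "AtomTypeRegistry",
    "default_registry",
    "read_structures",
    "read_fasta_sequence",
    "extract_sequence",
    "align_and_truncate",
    "write_scored_pdb",
    "EmptyStructureError",
]

SOLVENT_TYPE = 0  # reserved atom-type id for the solvent pseudo-partner


class EmptyStructureError(ValueError):
    """Raised when an input contains no scoreable protein atoms."""


@dataclass(frozen=True)
class AtomBall:
    """One protein heavy atom represented as a ball."""

    atom_index: int
    chain_id: str
    residue_seq: int
    insertion_code: str
    residue_name: str
    atom_name: str
    center: np.ndarray  # shape (3,), Angstrom
    radius: float       # van der Waals radius, Angstrom
    atom_type: int
    element: str

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"non-positive radius for {self}")
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_seq, self.insertion_code)


@dataclass
class Structure:
    """Ordered collection of heavy-atom balls, possibly multi-chain."""

    atoms: list[AtomBall]
    label: str = ""

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    @property
    def centers(self) -> np.ndarray:
        return np.array([a.center for a in self.atoms], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms], dtype=float)

    def __len__(self) -> int:
        return len(self.atoms)

    def residues(self) -> dict[tuple[str, int, str], list[AtomBall]]:
        """Residues in order of first appearance, mapping key -> atoms."""
        out: dict[tuple[str, int, str], list[AtomBall]] = {}
        for a in self.atoms:
            out.setdefault(a.residue_key, []).append(a)
        return out

    def validate(self) -> None:
        seen = set()
        for a in self.atoms:
            key = (a.chain_id, a.residue_seq, a.insertion_code, a.atom_name)
            if key in seen:
                raise ValueError(f"duplicate atom {key} in structure {self.label!r}")
            seen.add(key)


class AtomTypeRegistry:
    """Maps (residue_name, atom_name) to a small-integer atom type and radius.

    Type id 0 is reserved for the solvent pseudo-partner; protein types
    are numbered 1..N in lexicographic (residue, atom) order so that ids
    are stable across sessions.
    """

    def __init__(self, config: Mapping) -> None:
        self._radii_by_class: dict[str, float] = dict(config["radii"])
        sp2 = {res: set(names) for res, names in config.get("sp2_carbons", {}).items()}
        self.residue_remap: dict[str, str] = dict(config.get("residue_remap", {}))
        self.atom_remap: dict[str, dict[str, str]] = {
            res: dict(m) for res, m in config.get("atom_remap", {}).items()
        }
        self.version: int = int(config.get("version", 1))

        pairs: list[tuple[str, str]] = []
        for res in STANDARD_RESIDUES:
            for name in BACKBONE_ATOMS + SIDE_CHAIN_ATOMS[res] + ("OXT",):
                pairs.append((res, name))
        pairs.sort()
        self._type_of: dict[tuple[str, str], int] = {
            pair: i + 1 for i, pair in enumerate(pairs)
        }
        self._pair_of: dict[int, tuple[str, str]] = {
            i: pair for pair, i in self._type_of.items()
        }
        self._radius_of_type: dict[int, float] = {}
        for (res, name), tid in self._type_of.items():
            self._radius_of_type[tid] = self._radii_by_class[
                self._atom_class(res, name, sp2)
            ]

    @staticmethod
    def _atom_class(res: str, name: str, sp2: Mapping[str, set]) -> str:
        elem = element_of(name)
        if elem in ("N", "O", "S"):
            return elem
        if elem == "C":
            if name in sp2.get("*", set()) or name in sp2.get(res, set()):
                return "C_sp2"
            return "C_sp3"
        raise KeyError(f"no radius class for element {elem} ({res} {name})")

    @property
    def solvent_type(self) -> int:
        return SOLVENT_TYPE

    @property
    def protein_types(self) -> list[int]:
        return sorted(self._pair_of)

    def __len__(self) -> int:
        return len(self._type_of)

    def canonical_residue(self, residue_name: str) -> str | None:
        """Standard residue name after remapping, or None if unknown."""
        res = residue_name.strip().upper()
        res = self.residue_remap.get(res, res)
        return res if res in SIDE_CHAIN_ATOMS else None

    def lookup(self, residue_name: str, atom_name: str) -> tuple[int, float, str] | None:
        """(atom_type, radius, canonical atom name) or None if not typed."""
        raw_res = residue_name.strip().upper()
        res = self.canonical_residue(raw_res)
        if res is None:
            return None
        name = atom_name.strip().upper()
        name = self.atom_remap.get(raw_res, {}).get(name, name)
        tid = self._type_of.get((res, name))
        if tid is None:
            return None
        return tid, self._radius_of_type[tid], name

    def type_id(self, residue_name: str, atom_name: str) -> int:
        found = self.lookup(residue_name, atom_name)
        if found is None:
            raise KeyError(f"no atom type for ({residue_name}, {atom_name})")
        return found[0]

    def type_name(self, type_id: int) -> str:
        if type_id == SOLVENT_TYPE:
            return "SOLVENT"
        res, name = self._pair_of[type_id]
        return f"{res}:{name}"

    def type_from_name(self, text: str) -> int:
        if text == "SOLVENT":
            return SOLVENT_TYPE
        res, _, name = text.partition(":")
        return self._type_of[(res, name)]

    def radius(self, type_id: int) -> float:
        return self._radius_of_type[type_id]


def _load_default_config() -> dict:
    with resources.files("tessqa.data").joinpath("atom_classes.yaml").open() as fh:
        return yaml.safe_load(fh)


_DEFAULT_REGISTRY: AtomTypeRegistry | None = None


def default_registry() -> AtomTypeRegistry:
    """The registry built from the packaged atom-class config (cached)."""
    global _DEFAULT_REGISTRY
    if _DEFAULT_REGISTRY is None:
        _DEFAULT_REGISTRY = AtomTypeRegistry(_load_default_config())
    return _DEFAULT_REGISTRY


# ---------------------------------------------------------------------------
# PDB reading


def _is_hydrogen(atom_name: str, element: str) -> bool:
    if element in ("H", "D"):
        return True
    if element:
        return False
    # No element column: infer from the atom name (digits may lead, "1HB").
    stripped = atom_name.strip()
    for ch in stripped:
        if ch.isdigit():
            continue
        return ch in ("H", "D")
    return False


def _parse_atom_record(line: str) -> dict | None:
    """Parse one ATOM/HETATM line; returns None on malformed records."""
    try:
        name = line[12:16]
        altloc = line[16]
        resname = line[17:20]
        chain = line[21]
        resseq = int(line[22:26])
        icode = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError):
        return None
    element = line[76:78].strip().upper() if len(line) >= 78 else ""
    return {
        "name": name,
        "altloc": altloc,
        "resname": resname,
        "chain": chain.strip() or "A",
        "resseq": resseq,
        "icode": icode,
        "xyz": (x, y, z),
        "element": element,
    }


def read_structures(
    pdb_text: str,
    mode: str = "plain",
    label: str = "input",
    registry: AtomTypeRegistry | None = None,
) -> list[Structure]:
    """Read protein structures from PDB text.

    ``mode='plain'`` yields one :class:`Structure` per MODEL block (one
    structure if there are none); ``mode='assembly'`` combines all MODEL
    blocks into a single structure, disambiguating repeated chain ids by
    suffixing the model ordinal.  Hydrogens, waters, ligands and nucleic
    acids are dropped; alternate locations other than '' / 'A' are
    dropped; non-standard residues are remapped via the registry or
    skipped with a warning.
    """
    if mode not in ("plain", "assembly"):
        raise ValueError(f"mode must be 'plain' or 'assembly', got {mode!r}")
    registry = registry or default_registry()

    models: list[list[dict]] = [[]]
    n_atom_records = 0
    n_malformed = 0
    in_model = False
    for line in pdb_text.splitlines():
        rec = line[:6]
        if rec == "MODEL ":
            if in_model or models[-1]:
                models.append([])
            in_model = True
        elif rec == "ENDMDL":
            in_model = False
        elif rec in ("ATOM  ", "HETATM"):
            n_atom_records += 1
            parsed = _parse_atom_record(line)
            if parsed is None:
                n_malformed += 1
                logger.warning("skipping malformed record: %r", line.rstrip())
                continue
            models[-1].append(parsed)
    models = [m for m in models if m] or [[]]
    if n_atom_records and n_malformed == n_atom_records:
        raise ValueError(f"{label}: all {n_atom_records} atom records malformed")

    def build(records: Iterable[dict], chain_suffix: str, start_index: int,
              atoms: list[AtomBall], seen: set) -> int:
        idx = start_index
        skipped: dict[str, int] = {}
        for r in records:
            if r["altloc"] not in (" ", "A"):
                continue
            if _is_hydrogen(r["name"], r["element"]):
                continue
            found = registry.lookup(r["resname"], r["name"])
            if found is None:
                key = r["resname"].strip()
                skipped[key] = skipped.get(key, 0) + 1
                continue
            tid, radius, canonical_name = found
            res = registry.canonical_residue(r["resname"])
            chain = r["chain"] + chain_suffix
            ukey = (chain, r["resseq"], r["icode"], canonical_name)
            if ukey in seen:
                continue
            seen.add(ukey)
            atoms.append(
                AtomBall(
                    atom_index=idx,
                    chain_id=chain,
                    residue_seq=r["resseq"],
                    insertion_code=r["icode"],
                    residue_name=res,
                    atom_name=canonical_name,
                    center=np.array(r["xyz"], dtype=float),
                    radius=radius,
                    atom_type=tid,
                    element=element_of(canonical_name),
                )
            )
            idx += 1
        for res, n in sorted(skipped.items()):
            logger.warning("%s: skipped %d atom(s) of unrecognized residue/atom %s",
                           label, n, res)
        return idx

    structures: list[Structure] = []
    if mode == "plain":
        for m_i, records in enumerate(models):
            atoms: list[AtomBall] = []
            build(records, "", 0, atoms, set())
            if atoms:
                tag = f"{label}" if len(models) == 1 else f"{label}#model{m_i + 1}"
                structures.append(Structure(atoms, label=f"{tag} (plain)"))
    else:
        atoms = []
        seen: set = set()
        idx = 0
        used_chains: set[str] = set()
        for m_i, records in enumerate(models):
            model_chains = {r["chain"] for r in records}
            suffix = ""
            if m_i > 0 and (model_chains & used_chains):
                suffix = str(m_i + 1)
            used_chains |= {c + suffix for c in model_chains}
            idx = build(records, suffix, idx, atoms, seen)
        if atoms:
            structures.append(Structure(atoms, label=f"{label} (assembly)"))

    if not structures:
        raise EmptyStructureError(f"{label}: no protein atoms found")
    return structures


def read_fasta_sequence(text: str) -> str:
    """Target sequence from FASTA text (first record) or a plain string."""
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError("empty sequence input")
    if lines[0].startswith(">"):
        seq_lines = []
        for ln in lines[1:]:
            if ln.startswith(">"):
                break
            seq_lines.append(ln)
        seq = "".join(seq_lines)
    else:
        seq = "".join(lines)
    seq = seq.upper().replace(" ", "")
    if not seq.isalpha():
        raise ValueError("sequence contains non-alphabetic characters")
    return seq


# ---------------------------------------------------------------------------
# Sequence operations


def extract_sequence(structure: Structure) -> str:
    """One-letter sequence; chains concatenated in structure order."""
    if not structure.atoms:
        raise EmptyStructureError("cannot extract sequence from empty structure")
    return "".join(
        THREE_TO_ONE.get(atoms[0].residue_name, "X")
        for atoms in structure.residues().values()
    )


def align_and_truncate(structure: Structure, target_sequence: str) -> Structure:
    """Keep only residues aligned to the target sequence and renumber them.

    The concatenated chain sequence is globally aligned to the target
    (match +1, mismatch -1, gap open -2, gap extend -1).  Unaligned
    residues are discarded; kept residues take their 1-based target
    position as the new residue number.  Chain ids are untouched and
    insertion codes are cleared by the renumbering.
    """
    target = target_sequence.strip().upper()
    if not target or not target.isalpha():
        raise ValueError("target sequence must be non-empty and alphabetic")
    residues = list(structure.residues().items())
    if not residues:
        raise EmptyStructureError("cannot truncate an empty structure")
    seq = extract_sequence(structure)

    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -1.0
    alignment = aligner.align(seq, target)[0]

    mapping: dict[int, int] = {}  # structure residue ordinal -> target position (0-based)
    for (s_start, s_end), (t_start, t_end) in zip(*alignment.aligned):
        for k in range(s_end - s_start):
            mapping[s_start + k] = t_start + k
    n_identical = sum(1 for s, t in mapping.items() if seq[s] == target[t])
    if not mapping or n_identical == 0:
        raise ValueError("no alignable region between structure and target sequence")

    new_atoms: list[AtomBall] = []
    idx = 0
    for ordinal, (_, atoms) in enumerate(residues):
        if ordinal not in mapping:
            continue
        new_seq = int(mapping[ordinal]) + 1
        for a in atoms:
            new_atoms.append(
                replace(a, atom_index=idx, residue_seq=new_seq, insertion_code="")
            )
            idx += 1
    return Structure(new_atoms, label=structure.label + " (truncated)")


# ---------------------------------------------------------------------------
# PDB writing


def _chain_letter_map(chains: Sequence[str]) -> dict[str, str]:
    """Single-character chain ids for writing; identity when possible."""
    alphabet = ("ABCDEFGHIJKLMNOPQRSTUVWXYZ"
                "abcdefghijklmnopqrstuvwxyz0123456789")
    if all(len(c) == 1 for c in chains):
        return {c: c for c in chains}
    out: dict[str, str] = {}
    used: set[str] = set()
    for c in chains:
        pick = c if len(c) == 1 and c not in used else next(
            (ch for ch in alphabet if ch not in used), "Z"
        )
        out[c] = pick
        used.add(pick)
    return out


def write_scored_pdb(
    structure: Structure,
    per_atom_values: Mapping[int, float] | None = None,
    missing_value: float = -1.0,
) -> str:
    """Render the structure as PDB text with values in the B-factor column.

    Values are formatted to two decimals and clamped to the PDB field
    range [-999.99, 999.99] with a warning.  Atoms without a value get
    ``missing_value``.
    """
    if not structure.atoms:
        raise EmptyStructureError("cannot write an empty structure")
    values = per_atom_values or {}
    cmap = _chain_letter_map(structure.chains)
    lines: list[str] = []
    serial = 0
    prev_chain: str | None = None
    for a in structure.atoms:
        if prev_chain is not None and a.chain_id != prev_chain:
            lines.append("TER")
        prev_chain = a.chain_id
        serial += 1
        v = float(values.get(a.atom_index, missing_value))
        if not (-999.99 <= v <= 999.99):
            warnings.warn(f"B-factor value {v} clamped to PDB field range")
            v = min(max(v, -999.99), 999.99)
        name = a.atom_name
        # PDB atom-name column convention: element right-aligned in 13-14.
        name_field = f" {name:<3s}" if len(name) < 4 else name
        x, y, z = a.center
        lines.append(
            f"ATOM  {serial:5d} {name_field:<4s} {a.residue_name:<3s} "
            f"{cmap[a.chain_id]}{a.residue_seq:4d}{a.insertion_code or ' ':1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{v:6.2f}"
            f"          {a.element:>2s}"
        )
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"
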
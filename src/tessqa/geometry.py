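"""Tessellation-derived inter-atomic contact areas.

Each atom is a ball with a van der Waals radius.  Space is partitioned by
the radical (power) tessellation of the balls: the cell of ball *i* is the
set of points whose power distance ``|x-c_i|^2 - r_i^2`` is minimal.  Cells
are constrained to the inside of the solvent-accessible surface (SAS) —
the union of spheres of radius (r + probe).  The area of the face shared
by two constrained cells is the contact area of the two atoms; the part of
an atom's cell boundary lying on the SAS is its solvent contact area.

Face areas are computed exactly up to disk polygonization: the face lives
on the radical plane of the pair, is clipped by the half-planes of all
competing balls (a convex polygon), and then intersected with the union of
the SAS-sphere cross-section disks.  Solvent areas are evaluated with a
dense deterministic Fibonacci quadrature on each SAS sphere.  A separate
Monte-Carlo classification oracle provides independent area estimates for
validation.
"""

from __future__ import annotations

import logging
import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

__all__ = [
    "ContactSet",
    "BurialWeights",
    "BallCloud",
    "compute_contacts",
    "mc_area_oracle",
    "compute_burial_weights",
    "restrict_to_interchain",
    "write_contacts_tsv",
    "DegenerateBallsError",
]

DEFAULT_PROBE = 1.4          # Angstrom; standard water probe
DEFAULT_SPHERE_POINTS = 60_000
DEFAULT_DISK_SEGS = 96       # quarter-circle segments for SAS disk polygons
MIN_AREA = 1e-4              # Angstrom^2; faces below this are discarded


class DegenerateBallsError(ValueError):
    """Coincident or near-coincident ball centers: tessellation undefined."""


@dataclass(frozen=True)
class BallCloud:
    """A bare set of balls (no protein identity); duck-types Structure."""

    centers: np.ndarray
    radii: np.ndarray
    label: str = "balls"

    def __len__(self) -> int:
        return len(self.radii)


@dataclass
class ContactSet:
    """Symmetric inter-atomic contact areas plus solvent contact areas.

    ``pair_areas`` maps an ordered (i < j) atom-index pair to the area of
    the shared constrained-cell face; ``solvent_areas`` maps an atom index
    to the area of its cell boundary on the SAS.  Areas in Angstrom^2;
    zero-area entries are absent.
    """

    pair_areas: dict[tuple[int, int], float]
    solvent_areas: dict[int, float]
    probe_radius: float
    n_atoms: int = 0

    def area(self, i: int, j: int) -> float:
        return self.pair_areas.get((min(i, j), max(i, j)), 0.0)

    def total_area(self) -> float:
        return sum(self.pair_areas.values()) + sum(self.solvent_areas.values())

    def atom_contacts(self, i: int) -> tuple[list[tuple[int, float]], float]:
        """(partner, area) list and solvent area of atom ``i``."""
        pairs = [
            (j if a == i else a, area)
            for (a, j), area in self.pair_areas.items()
            if a == i or j == i
        ]
        return pairs, self.solvent_areas.get(i, 0.0)


@dataclass
class BurialWeights:
    """Integer burial depth per atom: 1 on the solvent-exposed layer."""

    depths: dict[int, int] = field(default_factory=dict)

    def __getitem__(self, i: int) -> int:
        return self.depths[i]

    def __len__(self) -> int:
        return len(self.depths)


def _as_arrays(structure) -> tuple[np.ndarray, np.ndarray]:
    centers = np.asarray(structure.centers, dtype=float)
    radii = np.asarray(structure.radii, dtype=float)
    if centers.ndim != 2 or centers.shape[1] != 3 or len(centers) != len(radii):
        raise ValueError("structure must provide (n,3) centers and n radii")
    if len(centers) == 0:
        raise ValueError("no atoms to tessellate")
    if not (np.isfinite(centers).all() and np.isfinite(radii).all()):
        raise ValueError("non-finite coordinates or radii")
    if (radii <= 0).any():
        raise ValueError("all radii must be positive")
    return centers, radii


def _check_degenerate(centers: np.ndarray) -> None:
    tree = cKDTree(centers)
    close = tree.query_pairs(0.01)
    if close:
        i, j = sorted(close)[0]
        raise DegenerateBallsError(
            f"balls {i} and {j} are closer than 0.01 A "
            f"(distance {np.linalg.norm(centers[i] - centers[j]):.2e} A)"
        )


def _canonical_frame(centers: np.ndarray) -> np.ndarray:
    """Rigid-motion canonical coordinates (PCA frame, skewness-fixed signs).

    Makes every downstream area a pure function of the internal geometry,
    so rigid motions of the input change results only at rounding level.
    Falls back to plain centering for degenerate (symmetric) spectra.
    """
    c = centers - centers.mean(axis=0)
    if len(c) < 3:
        return c
    cov = c.T @ c / len(c)
    w, vecs = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w, vecs = w[order], vecs[:, order]
    scale = max(w[0], 1e-12)
    if (w[0] - w[1]) / scale < 1e-6 or (w[1] - w[2]) / scale < 1e-6:
        return c
    axes = []
    for k in range(2):
        v = vecs[:, k]
        a = c @ v
        s3 = float((a**3).sum())
        if abs(s3) > 1e-9 * float(np.abs(a).max() or 1.0) ** 3:
            v = v * np.sign(s3)
        else:
            v = v * np.sign(a[np.argmax(np.abs(a))])
        axes.append(v)
    axes.append(np.cross(axes[0], axes[1]))
    return c @ np.column_stack(axes)


def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    k = int(np.argmin(np.abs(normal)))
    e = np.zeros(3)
    e[k] = 1.0
    u = np.cross(normal, e)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    return u, v


def _clip_polygon(poly: list[np.ndarray], alpha: float, beta: float,
                  gamma: float) -> list[np.ndarray]:
    """Sutherland–Hodgman clip of a convex 2-D polygon by a*x + b*y <= g."""
    nrm = math.hypot(alpha, beta)
    if nrm < 1e-12:
        return poly if gamma >= 0 else []
    out: list[np.ndarray] = []
    n = len(poly)
    for idx in range(n):
        p, q = poly[idx], poly[(idx + 1) % n]
        fp = alpha * p[0] + beta * p[1] - gamma
        fq = alpha * q[0] + beta * q[1] - gamma
        if fp <= 0:
            out.append(p)
            if fq > 0:
                out.append(p + (q - p) * (fp / (fp - fq)))
        elif fq <= 0:
            out.append(p + (q - p) * (fp / (fp - fq)))
    return out


def _poly_area(poly: list[np.ndarray]) -> float:
    if len(poly) < 3:
        return 0.0
    arr = np.array(poly)
    x, y = arr[:, 0], arr[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


_FIB_CACHE: dict[int, np.ndarray] = {}


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit vectors (Fibonacci lattice)."""
    if n not in _FIB_CACHE:
        i = np.arange(n, dtype=float) + 0.5
        z = 1.0 - 2.0 * i / n
        rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
        theta = math.pi * (1.0 + math.sqrt(5.0)) * i
        _FIB_CACHE[n] = np.column_stack(
            (rho * np.cos(theta), rho * np.sin(theta), z)
        )
    return _FIB_CACHE[n]


def _face_area(
    i: int,
    j: int,
    centers: np.ndarray,
    radii: np.ndarray,
    sas_r: np.ndarray,
    bound_r: np.ndarray,
    tree: cKDTree,
    disk_segs: int,
) -> float:
    ci, cj = centers[i], centers[j]
    ri, rj = radii[i], radii[j]
    diff = cj - ci
    d = float(np.linalg.norm(diff))
    normal = diff / d
    # Radical plane: foot point on the center line.
    t = (d * d + ri * ri - rj * rj) / (2.0 * d * d)
    p0 = ci + t * diff
    rho2 = min(bound_r[i] ** 2 - (t * d) ** 2,
               bound_r[j] ** 2 - ((1.0 - t) * d) ** 2)
    if rho2 <= 0:
        return 0.0
    rho = math.sqrt(rho2)
    u, v = _plane_basis(normal)

    reach = rho * math.sqrt(2.0) + float(bound_r.max())
    cand = tree.query_ball_point(p0, reach)

    # Convex region on the plane: start square, clip by competitor half-planes.
    poly = [np.array([-rho, -rho]), np.array([rho, -rho]),
            np.array([rho, rho]), np.array([-rho, rho])]
    for k in cand:
        if k == i or k == j:
            continue
        g = centers[k] - ci
        alpha = 2.0 * float(u @ g)
        beta = 2.0 * float(v @ g)
        gamma = (float(centers[k] @ centers[k]) - float(ci @ ci)
                 - radii[k] ** 2 + ri * ri - 2.0 * float(p0 @ g))
        poly = _clip_polygon(poly, alpha, beta, gamma)
        if len(poly) < 3:
            return 0.0

    # SAS constraint: intersect with the union of SAS-sphere cross sections.
    disks: list[tuple[np.ndarray, float]] = []
    for m in cand:
        h = float((centers[m] - p0) @ normal)
        rad2 = sas_r[m] ** 2 - h * h
        if rad2 <= 0:
            continue
        c2d = np.array([float((centers[m] - p0) @ u),
                        float((centers[m] - p0) @ v)])
        disks.append((c2d, math.sqrt(rad2)))
        if m == i or m == j:
            # Fast path: polygon entirely inside this pair's own SAS disk.
            arr = np.array(poly)
            if (np.linalg.norm(arr - c2d, axis=1) <= math.sqrt(rad2)).all():
                return _poly_area(poly)
    if not disks:
        return 0.0

    from shapely.geometry import Point, Polygon
    from shapely.ops import unary_union

    region = Polygon([tuple(p) for p in poly])
    if region.area <= 0:
        return 0.0
    minx, miny, maxx, maxy = region.bounds
    circles = []
    for c2d, rad in disks:
        if (c2d[0] + rad < minx or c2d[0] - rad > maxx
                or c2d[1] + rad < miny or c2d[1] - rad > maxy):
            continue
        circles.append(Point(c2d[0], c2d[1]).buffer(rad, quad_segs=disk_segs))
    if not circles:
        return 0.0
    return float(region.intersection(unary_union(circles)).area)


def compute_contacts(
    structure,
    probe_radius: float = DEFAULT_PROBE,
    *,
    sphere_points: int = DEFAULT_SPHERE_POINTS,
    disk_segs: int = DEFAULT_DISK_SEGS,
    min_area: float = MIN_AREA,
) -> ContactSet:
    """Contact and solvent areas of every atom in the structure.

    Parameters
    ----------
    structure
        A :class:`~tessqa.structure.Structure` or any object exposing
        ``centers`` (n,3) and ``radii`` (n,).
    probe_radius
        Solvent probe radius in Angstrom (default 1.4, a water probe).
    sphere_points
        Number of Fibonacci quadrature points per SAS sphere for solvent
        areas; controls solvent-area discretization error.
    disk_segs
        Quarter-circle resolution of the polygonal SAS disks used when a
        face is clipped by the SAS boundary.
    min_area
        Faces below this area (Angstrom^2) are discarded.
    """
    if probe_radius < 0:
        raise ValueError("probe radius must be non-negative")
    centers, radii = _as_arrays(structure)
    _check_degenerate(centers)
    centers = _canonical_frame(centers)

    n = len(centers)
    r_max = float(radii.max())
    sas_r = radii + probe_radius
    # Bound on how far a constrained-cell point can lie from its center:
    # any point in cell i inside the SAS union has power(i) <= 2*r_max*p + p^2.
    w_slack = 2.0 * r_max * probe_radius + probe_radius**2
    bound_r = np.sqrt(radii**2 + w_slack)

    tree = cKDTree(centers)
    pair_areas: dict[tuple[int, int], float] = {}
    if n > 1:
        cutoff = 2.0 * float(bound_r.max())
        for i, j in sorted(tree.query_pairs(cutoff)):
            if np.linalg.norm(centers[i] - centers[j]) > bound_r[i] + bound_r[j]:
                continue
            area = _face_area(i, j, centers, radii, sas_r, bound_r, tree, disk_segs)
            if area >= min_area:
                pair_areas[(i, j)] = area

    solvent_areas: dict[int, float] = {}
    unit = _fibonacci_sphere(sphere_points)
    b_max = float(bound_r.max())
    for i in range(n):
        ri, Ri = float(radii[i]), float(sas_r[i])
        nbrs = [k for k in tree.query_ball_point(centers[i], Ri + b_max) if k != i]
        if not nbrs:
            solvent_areas[i] = 4.0 * math.pi * Ri * Ri
            continue
        nb = np.asarray(nbrs)
        # Exclude a quadrature point if it is occluded by another SAS sphere
        # or power-closer to another ball; one threshold covers both.
        thr = radii[nb] ** 2 + probe_radius**2 + \
            2.0 * probe_radius * np.maximum(radii[nb], ri)
        keep = 0
        for start in range(0, sphere_points, 20000):
            pts = centers[i] + Ri * unit[start:start + 20000]
            d2 = ((pts[:, None, :] - centers[nb][None, :, :]) ** 2).sum(axis=2)
            keep += int((d2 >= thr[None, :]).all(axis=1).sum())
        area = 4.0 * math.pi * Ri * Ri * keep / sphere_points
        if area >= min_area:
            solvent_areas[i] = area

    return ContactSet(pair_areas, solvent_areas, probe_radius, n_atoms=n)


# ---------------------------------------------------------------------------
# Monte-Carlo validation oracle (kept independent of the deterministic path)


def mc_area_oracle(
    structure,
    probe_radius: float,
    query: tuple,
    n_samples: int = 100_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Unbiased Monte-Carlo estimate of one contact or solvent area.

    ``query`` is ``("pair", i, j)`` — uniform sampling on the pair's
    radical plane inside a bounding disk, classifying each point by the
    power-distance rule against *all* balls and by SAS-union membership —
    or ``("solvent", i)`` — uniform sampling on atom *i*'s SAS sphere,
    classified by non-occlusion and nearest-cell membership.

    Returns ``(area, standard_error)`` in Angstrom^2.
    """
    if n_samples < 1000:
        raise ValueError("n_samples must be at least 1000")
    centers, radii = _as_arrays(structure)
    rng = np.random.default_rng(seed)
    sas_r = radii + probe_radius
    r_max = float(radii.max())
    w_slack = 2.0 * r_max * probe_radius + probe_radius**2
    bound_r = np.sqrt(radii**2 + w_slack)

    kind = query[0]
    if kind == "pair":
        _, i, j = query
        ci, cj = centers[i], centers[j]
        ri, rj = float(radii[i]), float(radii[j])
        diff = cj - ci
        d = float(np.linalg.norm(diff))
        normal = diff / d
        t = (d * d + ri * ri - rj * rj) / (2.0 * d * d)
        p0 = ci + t * diff
        rho2 = min(bound_r[i] ** 2 - (t * d) ** 2,
                   bound_r[j] ** 2 - ((1.0 - t) * d) ** 2)
        if rho2 <= 0:
            return 0.0, 0.0
        rho = math.sqrt(rho2)
        u, v = _plane_basis(normal)
        rr = rho * np.sqrt(rng.random(n_samples))
        th = 2.0 * math.pi * rng.random(n_samples)
        pts = p0 + np.outer(rr * np.cos(th), u) + np.outer(rr * np.sin(th), v)
        d2_all = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        power = d2_all - (radii**2)[None, :]
        in_sas = (d2_all <= (sas_r**2)[None, :]).any(axis=1)
        own = power[:, i]
        closest = own <= power.min(axis=1) + 1e-9
        frac = float(np.mean(in_sas & closest))
        ref = math.pi * rho * rho
    elif kind == "solvent":
        _, i = query
        Ri = float(sas_r[i])
        dirs = rng.normal(size=(n_samples, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        pts = centers[i] + Ri * dirs
        d2_all = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        power = d2_all - (radii**2)[None, :]
        others = np.ones(len(centers), dtype=bool)
        others[i] = False
        unoccluded = (d2_all[:, others] >= (sas_r[others] ** 2)[None, :] - 1e-9).all(axis=1)
        closest = power[:, i] <= power.min(axis=1) + 1e-9
        frac = float(np.mean(unoccluded & closest))
        ref = 4.0 * math.pi * Ri * Ri
    else:
        raise ValueError(f"unknown query kind {kind!r}")

    area = ref * frac
    se = ref * math.sqrt(max(frac * (1.0 - frac), 0.0) / n_samples)
    return area, se


# ---------------------------------------------------------------------------
# Burial weights and interface restriction


def compute_burial_weights(structure, contacts: ContactSet) -> BurialWeights:
    """Layer-peeling burial depth on the contact graph.

    Solvent-exposed atoms (positive solvent area) have depth 1; every
    other atom's depth is 1 plus its graph distance to the exposed layer.
    Atoms with no contacts, or cut off from any exposed atom, get depth 1
    with a warning.
    """
    n = len(structure)
    adj: dict[int, set[int]] = {i: set() for i in range(n)}
    for (i, j) in contacts.pair_areas:
        adj[i].add(j)
        adj[j].add(i)

    depths: dict[int, int] = {}
    queue: deque[int] = deque()
    for i in range(n):
        if contacts.solvent_areas.get(i, 0.0) > 0.0:
            depths[i] = 1
            queue.append(i)
    while queue:
        i = queue.popleft()
        for k in adj[i]:
            if k not in depths:
                depths[k] = depths[i] + 1
                queue.append(k)
    for i in range(n):
        if i not in depths:
            logger.warning(
                "atom %d has no path to the solvent-exposed layer; weight 1", i
            )
            depths[i] = 1
    return BurialWeights(depths)


def restrict_to_interchain(contacts: ContactSet, structure) -> ContactSet:
    """Keep only contacts whose two atoms belong to different chains."""
    chains = [a.chain_id for a in structure.atoms]
    if len(set(chains)) < 2:
        raise ValueError("no inter-chain interface possible: single-chain structure")
    pair_areas = {
        (i, j): area
        for (i, j), area in contacts.pair_areas.items()
        if chains[i] != chains[j]
    }
    return ContactSet(pair_areas, {}, contacts.probe_radius, contacts.n_atoms)


def write_contacts_tsv(structure, contacts: ContactSet) -> str:
    """Contact table as TSV with deterministic row ordering."""
    atoms = structure.atoms
    lines = ["chain1\tres1\tatom1\tchain2\tres2\tatom2\tarea"]
    for (i, j) in sorted(contacts.pair_areas):
        a, b = atoms[i], atoms[j]
        lines.append(
            f"{a.chain_id}\t{a.residue_seq}\t{a.atom_name}\t"
            f"{b.chain_id}\t{b.residue_seq}\t{b.atom_name}\t"
            f"{contacts.pair_areas[(i, j)]:.4f}"
        )
    for i in sorted(contacts.solvent_areas):
        a = atoms[i]
        lines.append(
            f"{a.chain_id}\t{a.residue_seq}\t{a.atom_name}\t"
            f"-\t-\tSOLVENT\t{contacts.solvent_areas[i]:.4f}"
        )
    return "\n".join(lines) + "\n"
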
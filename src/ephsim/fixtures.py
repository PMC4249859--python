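"""Deterministic synthetic inputs with known ground truth.

Two generators cover every stage of the pipeline without external data:

* :func:`mixed_seeding` — the initial condition of every simulation: uniform
  random non-overlapping positions with cell types assigned by random
  permutation at the exact requested Eph:ephrin ratio (mirroring a co-culture
  seeded from a counted cell suspension).
* :func:`synthetic_constellation` — planted, hexagonally packed clusters at a
  chosen spacing, with ground truth (component count, per-cluster cell
  counts, per-cluster pixel areas) computed by oracles that share no code
  with the production rasterizer/labeller: a union-find over the disc
  touching graph and a brute-force pixel-centre-in-union-of-discs counter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulator import EPH, EPHRIN, Domain, SimulationState, Snapshot, TYPE_CODES

__all__ = [
    "mixed_seeding",
    "PlantedCluster",
    "ConstellationSpec",
    "ConstellationTruth",
    "synthetic_constellation",
    "hex_packing",
    "oracle_union_find_components",
    "oracle_disc_pixel_area",
]

MAX_ATTEMPTS_PER_CELL = 1000  # rejection-sampling budget


def mixed_seeding(
    n_eph: int,
    n_ephrin: int,
    domain: Domain,
    seed: int | None = None,
    min_separation: float = 2.0,
    rng: np.random.Generator | None = None,
) -> SimulationState:
    """Random well-mixed seeding of both populations.

    Positions are drawn uniformly over the domain by rejection sampling with
    a minimum pairwise distance (default 2 µm — cells are seeded as a
    suspension, not pre-spread).  Types are assigned by a random permutation
    so the requested counts are exact, not merely expected.

    Raises if the packing is infeasible (n·π·min_separation² must stay below
    half the domain area) or if the attempt budget is exhausted.
    """
    n = n_eph + n_ephrin
    if n <= 0:
        raise ValueError("need at least one cell")
    area = domain.width * domain.height
    if n * np.pi * min_separation**2 >= area / 2.0:
        raise ValueError(
            f"infeasible packing: {n} cells at min separation "
            f"{min_separation} µm in a {domain.width}×{domain.height} µm domain"
        )
    if rng is None:
        rng = np.random.default_rng(seed)

    positions = np.empty((n, 2))
    placed = 0
    attempts = 0
    budget = MAX_ATTEMPTS_PER_CELL * n
    while placed < n:
        if attempts >= budget:
            raise RuntimeError(
                f"rejection sampling exhausted {budget} attempts after placing "
                f"{placed}/{n} cells"
            )
        candidate = rng.uniform([0.0, 0.0], [domain.width, domain.height])
        attempts += 1
        if placed:
            d2 = np.sum((positions[:placed] - candidate) ** 2, axis=1)
            if d2.min() < min_separation**2:
                continue
        positions[placed] = candidate
        placed += 1

    types = np.concatenate(
        [np.full(n_eph, EPH, dtype=np.int8), np.full(n_ephrin, EPHRIN, dtype=np.int8)]
    )
    types = types[rng.permutation(n)]
    return SimulationState(
        time=0.0,
        ids=np.arange(n, dtype=np.int64),
        types=types,
        positions=positions,
        last_division=np.zeros(n),
        domain=domain,
        rng=rng,
    )


def hex_packing(n_cells: int, spacing: float) -> np.ndarray:
    """Centres of ``n_cells`` points on a hexagonal lattice, densest first.

    Points are generated on a triangular lattice with the given spacing and
    the ``n_cells`` closest to the origin are kept, producing compact,
    roughly circular planted clusters (1 → point, 7 → hexagon + centre, ...).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rings = int(np.ceil(np.sqrt(n_cells))) + 1
    pts = []
    for i in range(-rings, rings + 1):
        for j in range(-rings, rings + 1):
            x = spacing * (i + 0.5 * (j % 2))
            y = spacing * (np.sqrt(3.0) / 2.0) * j
            pts.append((x, y))
    pts = np.array(pts)
    order = np.argsort(np.hypot(pts[:, 0], pts[:, 1]), kind="stable")
    return pts[order[:n_cells]]


@dataclass(frozen=True)
class PlantedCluster:
    """One planted cluster: centre (µm), cell count, packing spacing, type."""

    centre: tuple[float, float]
    n_cells: int
    spacing: float
    cell_type: str = "EPH"


@dataclass(frozen=True)
class ConstellationSpec:
    """Planted constellation: clusters plus optional background singles.

    ``r_eff`` is the disc radius used both for the separation invariant
    (clusters must be > 2·r_eff + spacing apart so the ground-truth component
    count is well defined) and by the pixel-area oracle.
    """

    clusters: tuple[PlantedCluster, ...]
    domain: Domain
    r_eff: float
    singles: tuple[tuple[float, float, str], ...] = ()
    pixel_size: float = 1.0


@dataclass
class ConstellationTruth:
    """Ground truth for one population of a planted constellation."""

    n_components: int
    cell_counts: list[int]  # per component, sorted descending
    areas_um2: list[float]  # per component, same order as cell_counts
    component_of_cell: np.ndarray  # component label per cell of the population


def oracle_union_find_components(positions: np.ndarray, touch_distance: float):
    """Connected components of the disc touching graph, by plain union-find.

    Independent of the raster pipeline: two cells are linked iff their centre
    distance is <= ``touch_distance`` (discs of radius touch_distance/2
    overlap or touch).  Returns (n_components, label array).
    """
    n = len(positions)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            dx = positions[i, 0] - positions[j, 0]
            dy = positions[i, 1] - positions[j, 1]
            if dx * dx + dy * dy <= touch_distance**2:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    roots = [find(i) for i in range(n)]
    uniq = sorted(set(roots))
    relabel = {r: k for k, r in enumerate(uniq)}
    labels = np.array([relabel[r] for r in roots], dtype=np.intp)
    return len(uniq), labels


def oracle_disc_pixel_area(
    positions: np.ndarray,
    r_eff: float,
    domain: Domain,
    pixel_size: float = 1.0,
) -> float:
    """Area (µm²) of the union of discs, by brute-force pixel enumeration.

    Counts every in-domain pixel whose centre lies within ``r_eff`` of some
    cell centre, scanning the full distance matrix — deliberately naive and
    separate from the production rasterizer.
    """
    if len(positions) == 0:
        return 0.0
    nx = int(np.ceil(domain.width / pixel_size))
    ny = int(np.ceil(domain.height / pixel_size))
    xs = (np.arange(nx) + 0.5) * pixel_size
    ys = (np.arange(ny) + 0.5) * pixel_size
    count = 0
    for y in ys:  # row-wise to bound memory
        d2 = (xs[:, None] - positions[None, :, 0]) ** 2 + (
            y - positions[None, :, 1]
        ) ** 2
        count += int((d2.min(axis=1) <= r_eff**2).sum())
    return count * pixel_size**2


def synthetic_constellation(spec: ConstellationSpec):
    """Build a planted snapshot and its ground truth.

    Returns ``(snapshot, truth)`` where ``truth`` maps each population name
    present in the constellation to a :class:`ConstellationTruth`.  Raises if
    any two planted clusters violate the separation invariant (closest
    cross-cluster cell distance must exceed 2·r_eff + spacing).
    """
    groups: list[tuple[np.ndarray, str]] = []
    for cl in spec.clusters:
        pts = hex_packing(cl.n_cells, cl.spacing) + np.asarray(cl.centre)
        groups.append((pts, cl.cell_type))
    for x, y, t in spec.singles:
        groups.append((np.array([[x, y]]), t))

    max_spacing = max((cl.spacing for cl in spec.clusters), default=0.0)
    min_gap = 2.0 * spec.r_eff + max_spacing
    for gi in range(len(groups)):
        for gj in range(gi + 1, len(groups)):
            pi, pj = groups[gi][0], groups[gj][0]
            d2 = ((pi[:, None, :] - pj[None, :, :]) ** 2).sum(axis=2)
            if d2.min() <= min_gap**2:
                raise ValueError(
                    f"planted groups {gi} and {gj} are closer than the "
                    f"separation invariant 2·r_eff + spacing = {min_gap:.1f} µm"
                )

    positions = np.vstack([g[0] for g in groups])
    types = np.concatenate(
        [np.full(len(g[0]), TYPE_CODES[g[1]], dtype=np.int8) for g in groups]
    )
    if np.any(positions < 0) or np.any(
        positions > [spec.domain.width, spec.domain.height]
    ):
        raise ValueError("planted constellation extends outside the domain")

    n = len(positions)
    snapshot = Snapshot(
        time=0.0,
        ids=np.arange(n, dtype=np.int64),
        types=types,
        positions=positions,
        last_division=np.zeros(n),
    )

    truth: dict[str, ConstellationTruth] = {}
    for name, code in TYPE_CODES.items():
        mask = types == code
        if not mask.any():
            continue
        pop_pos = positions[mask]
        n_comp, labels = oracle_union_find_components(pop_pos, 2.0 * spec.r_eff)
        counts, areas = [], []
        for k in range(n_comp):
            members = pop_pos[labels == k]
            counts.append(len(members))
            areas.append(
                oracle_disc_pixel_area(
                    members, spec.r_eff, spec.domain, spec.pixel_size
                )
            )
        order = np.argsort(-np.array(counts), kind="stable")
        truth[name] = ConstellationTruth(
            n_components=n_comp,
            cell_counts=[counts[k] for k in order],
            areas_um2=[areas[k] for k in order],
            component_of_cell=labels,
        )
    return snapshot, truth
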
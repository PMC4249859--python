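"""Time propagation of the two-population cell system.

Each cell centre follows an overdamped Langevin equation: the deterministic
drift is the sum of pairwise radial forces from :mod:`ephsim.core_model`, and
the stochastic term is an independent 2-D Brownian motion with diffusion
coefficient D (per-axis increment variance 2·D·dt).  Integration is
first-order Euler–Maruyama.  Population growth is a pure-birth (Yule)
process: each cell divides in a step of length dt with probability
1 − e^(−β·dt), independent of its history, which is equivalent in law to
exponential inter-division times with rate β.

Internal units are µm and minutes.  Configuration-facing quantities use the
conventions of the experimental system: β in 1/h, dt in seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .core_model import InteractionParams, max_pair_stiffness

__all__ = [
    "EPH",
    "EPHRIN",
    "TYPE_NAMES",
    "CellState",
    "MotilityParams",
    "BirthParams",
    "Domain",
    "SimulationState",
    "Snapshot",
    "Trajectory",
    "NeighbourIndex",
    "build_neighbour_index",
    "drift",
    "step",
    "max_stable_dt",
    "apply_births",
    "reflect",
    "run",
    "total_potential_energy",
]

# integer codes for the two populations; code_i + code_j classifies a pair
# (0 = Eph-Eph, 1 = heterotypic, 2 = ephrin-ephrin)
EPH = 0
EPHRIN = 1
TYPE_NAMES = {EPH: "EPH", EPHRIN: "EPHRIN"}
TYPE_CODES = {"EPH": EPH, "EPHRIN": EPHRIN}

DAUGHTER_OFFSET_UM = 1.0  # spawn distance of a daughter cell, µm


@dataclass(frozen=True)
class CellState:
    """Single-cell view: id, population, position (µm), last division time."""

    id: int
    cell_type: str
    position: np.ndarray
    last_division_time: float


@dataclass(frozen=True)
class MotilityParams:
    """Brownian motility; D is the diffusion coefficient in µm²/min."""

    D: float

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError(f"diffusion coefficient must be >= 0, got {self.D}")


@dataclass(frozen=True)
class BirthParams:
    """Pure-birth proliferation; beta is the division rate in 1/h."""

    beta: float

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError(f"birth rate must be >= 0, got {self.beta}")

    @property
    def beta_per_min(self) -> float:
        return self.beta / 60.0


@dataclass(frozen=True)
class Domain:
    """Rectangular simulation field [0, width] × [0, height] in µm."""

    width: float
    height: float
    boundary: str = "REFLECTING"

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("domain dimensions must be positive")
        if self.boundary not in ("REFLECTING", "PERIODIC"):
            raise ValueError(
                f"boundary must be REFLECTING or PERIODIC, got {self.boundary!r}"
            )


@dataclass
class Snapshot:
    """Immutable record of all cell positions at one time point."""

    time: float  # minutes
    ids: np.ndarray  # (N,) int64
    types: np.ndarray  # (N,) int8, EPH/EPHRIN codes
    positions: np.ndarray  # (N, 2) float64, µm
    last_division: np.ndarray  # (N,) float64, minutes

    @property
    def n_cells(self) -> int:
        return len(self.ids)

    def cells(self) -> list[CellState]:
        return [
            CellState(
                int(self.ids[k]),
                TYPE_NAMES[int(self.types[k])],
                self.positions[k].copy(),
                float(self.last_division[k]),
            )
            for k in range(self.n_cells)
        ]


@dataclass
class SimulationState:
    """Full mutable state of a run: time, cells (as arrays), domain, RNG.

    Cells are stored in ascending-id order (ids are assigned sequentially and
    only appended), which fixes the traversal order of all stochastic draws.
    """

    time: float
    ids: np.ndarray
    types: np.ndarray
    positions: np.ndarray
    last_division: np.ndarray
    domain: Domain
    rng: np.random.Generator
    next_id: int = field(default=-1)

    def __post_init__(self) -> None:
        if self.next_id < 0:
            self.next_id = int(self.ids.max()) + 1 if len(self.ids) else 0

    @property
    def n_cells(self) -> int:
        return len(self.ids)

    def snapshot(self) -> Snapshot:
        return Snapshot(
            time=self.time,
            ids=self.ids.copy(),
            types=self.types.copy(),
            positions=self.positions.copy(),
            last_division=self.last_division.copy(),
        )


@dataclass
class Trajectory:
    """Time-ordered snapshots of a run, first record at t = 0."""

    snapshots: list[Snapshot]

    def __post_init__(self) -> None:
        times = [s.time for s in self.snapshots]
        if times and any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("snapshot times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.snapshots)

    def __iter__(self):
        return iter(self.snapshots)

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.snapshots])

    def nearest(self, time_min: float, max_gap: float | None = None) -> Snapshot:
        """Snapshot closest to ``time_min``; error if farther than ``max_gap``."""
        times = self.times
        k = int(np.argmin(np.abs(times - time_min)))
        if max_gap is not None and abs(times[k] - time_min) > max_gap:
            raise ValueError(
                f"no snapshot within {max_gap} min of t = {time_min} min "
                f"(trajectory spans {times[0]}–{times[-1]} min)"
            )
        return self.snapshots[k]


class NeighbourIndex:
    """Fixed-radius neighbour queries over a set of 2-D positions.

    Backed by a k-d tree; ``query(i)`` returns exactly the indices j ≠ i with
    d(i, j) <= cutoff, and ``pairs()`` the unique such pairs (i < j).
    """

    def __init__(self, positions: np.ndarray, cutoff: float) -> None:
        if cutoff <= 0:
            raise ValueError(f"cutoff must be > 0, got {cutoff}")
        self.positions = np.asarray(positions, dtype=float).reshape(-1, 2)
        self.cutoff = float(cutoff)
        self._tree = cKDTree(self.positions) if len(self.positions) else None

    def query(self, i: int) -> np.ndarray:
        if self._tree is None:
            return np.empty(0, dtype=np.intp)
        idx = self._tree.query_ball_point(self.positions[i], self.cutoff)
        return np.array(sorted(j for j in idx if j != i), dtype=np.intp)

    def pairs(self) -> np.ndarray:
        """Unique neighbour pairs as an (M, 2) array with i < j."""
        if self._tree is None:
            return np.empty((0, 2), dtype=np.intp)
        return self._tree.query_pairs(self.cutoff, output_type="ndarray")


def build_neighbour_index(positions: np.ndarray, cutoff: float) -> NeighbourIndex:
    """Build a fixed-radius neighbour index for the given positions."""
    return NeighbourIndex(positions, cutoff)


def _pair_class_tables(params: InteractionParams):
    """Per-pair-class force coefficients indexed by type_i + type_j.

    Row k of each array holds the coefficients for class code k
    (0 = Eph-Eph, 1 = heterotypic with attenuated attraction,
    2 = ephrin-ephrin).  The heterotypic row uses arithmetic-mean
    symmetrized parameters so forces stay antisymmetric.
    """
    from .core_model import symmetrized_pair_params

    het = symmetrized_pair_params(params.eph, params.ephrin)
    rows = [
        (params.eph, 0.0),
        (het, params.C),
        (params.ephrin, 0.0),
    ]
    Rr = np.array([p.R / p.r for p, _ in rows])
    Aa = np.array([(1.0 - att) * p.A / p.a for p, att in rows])
    inv_r = np.array([1.0 / p.r for p, _ in rows])
    inv_a = np.array([1.0 / p.a for p, _ in rows])
    return Rr, Aa, inv_r, inv_a


def drift(
    state: SimulationState,
    params: InteractionParams,
    index: NeighbourIndex,
) -> np.ndarray:
    """Deterministic velocity (µm/min) of every cell: summed pair forces.

    An isolated cell has zero drift; the total drift over all cells vanishes
    by pairwise antisymmetry.  Coincident pairs (d = 0) contribute the finite
    contact force along a uniformly random direction drawn from the state's
    RNG stream.
    """
    n = state.n_cells
    out = np.zeros((n, 2))
    pairs = index.pairs()
    if len(pairs) == 0:
        return out
    i, j = pairs[:, 0], pairs[:, 1]
    delta = state.positions[i] - state.positions[j]
    d = np.hypot(delta[:, 0], delta[:, 1])

    code = state.types[i].astype(np.intp) + state.types[j].astype(np.intp)
    Rr, Aa, inv_r, inv_a = _pair_class_tables(params)
    mag = Rr[code] * np.exp(-d * inv_r[code]) - Aa[code] * np.exp(-d * inv_a[code])

    with np.errstate(invalid="ignore", divide="ignore"):
        unit = delta / d[:, None]
    zero = d == 0.0
    if np.any(zero):
        theta = state.rng.uniform(0.0, 2.0 * math.pi, size=int(zero.sum()))
        unit[zero, 0] = np.cos(theta)
        unit[zero, 1] = np.sin(theta)

    fx = mag * unit[:, 0]
    fy = mag * unit[:, 1]
    out[:, 0] = np.bincount(i, weights=fx, minlength=n) - np.bincount(
        j, weights=fx, minlength=n
    )
    out[:, 1] = np.bincount(i, weights=fy, minlength=n) - np.bincount(
        j, weights=fy, minlength=n
    )
    return out


def max_stable_dt(params: InteractionParams) -> float:
    """Largest admissible Euler time step (minutes) for the given forces.

    Bound: dt <= 1 / (2·max|u''(0)|) over the three pair classes — the
    non-oscillatory relaxation limit of the stiffest linearized two-cell
    mode.  It also underwrites monotone decrease of the total pair potential
    in the noiseless, birthless case.
    """
    return 1.0 / max_pair_stiffness(params)


def reflect(position: np.ndarray, domain: Domain) -> np.ndarray:
    """Apply the domain boundary condition to positions (vectorized).

    REFLECTING mirrors coordinates at the walls (triangle-wave fold, valid
    for any excursion); PERIODIC wraps them modulo the domain size.
    """
    pos = np.array(position, dtype=float, copy=True)
    size = np.array([domain.width, domain.height])
    if domain.boundary == "PERIODIC":
        return np.mod(pos, size)
    folded = np.mod(pos, 2.0 * size)
    over = folded > size
    if pos.ndim == 1:
        folded[over] = 2.0 * size[over] - folded[over]
    else:
        folded = np.where(over, 2.0 * size - folded, folded)
    return folded


def step(
    state: SimulationState,
    dt: float,
    motility: MotilityParams,
    params: InteractionParams | None,
    index: NeighbourIndex | None = None,
    cutoff: float = 60.0,
) -> SimulationState:
    """One Euler–Maruyama step of length ``dt`` minutes.

    X(t+dt) = X(t) + drift·dt + ξ with ξ ~ Normal(0, 2·D·dt) per axis, then
    the boundary condition.  ``params=None`` disables interactions (pure
    diffusion).  ``dt`` must satisfy the stability bound of
    :func:`max_stable_dt`.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if params is not None:
        dt_max = max_stable_dt(params)
        if dt > dt_max:
            raise ValueError(
                f"dt = {dt * 60:.3f} s exceeds the stability bound for these "
                f"interaction parameters; maximum admissible dt = "
                f"{dt_max * 60:.3f} s ({dt_max:.5f} min)"
            )
        if index is None:
            index = build_neighbour_index(state.positions, cutoff)
        velocity = drift(state, params, index)
    else:
        velocity = 0.0

    new_pos = state.positions + np.asarray(velocity) * dt
    if motility.D > 0:
        sigma = math.sqrt(2.0 * motility.D * dt)
        new_pos = new_pos + state.rng.normal(0.0, sigma, size=state.positions.shape)
    new_pos = reflect(new_pos, state.domain)
    return SimulationState(
        time=state.time + dt,
        ids=state.ids,
        types=state.types,
        positions=new_pos,
        last_division=state.last_division,
        domain=state.domain,
        rng=state.rng,
        next_id=state.next_id,
    )


def apply_births(state: SimulationState, dt: float, birth: BirthParams) -> SimulationState:
    """Pure-birth divisions over (t, t+dt].

    Each cell independently divides with probability 1 − e^(−β·dt).  A
    dividing cell keeps its position and resets its last-division time; the
    daughter (same type, fresh id) is placed 1 µm away in a uniformly random
    direction.  Short-range repulsion separates the pair over subsequent
    steps.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if birth.beta == 0 or state.n_cells == 0:
        return state
    p_divide = 1.0 - math.exp(-birth.beta_per_min * dt)
    dividing = state.rng.random(state.n_cells) < p_divide
    n_new = int(dividing.sum())
    if n_new == 0:
        return state
    t_new = state.time
    theta = state.rng.uniform(0.0, 2.0 * math.pi, size=n_new)
    offset = DAUGHTER_OFFSET_UM * np.column_stack([np.cos(theta), np.sin(theta)])
    daughters = reflect(state.positions[dividing] + offset, state.domain)

    last_division = state.last_division.copy()
    last_division[dividing] = t_new
    new_ids = np.arange(state.next_id, state.next_id + n_new, dtype=np.int64)
    return SimulationState(
        time=state.time,
        ids=np.concatenate([state.ids, new_ids]),
        types=np.concatenate([state.types, state.types[dividing]]),
        positions=np.vstack([state.positions, daughters]),
        last_division=np.concatenate([last_division, np.full(n_new, t_new)]),
        domain=state.domain,
        rng=state.rng,
        next_id=state.next_id + n_new,
    )


def total_potential_energy(state: SimulationState, params: InteractionParams) -> float:
    """Sum of pairwise (attenuated) potentials over all cell pairs.

    Diagnostic for the gradient-flow property: with D = 0 and β = 0 the
    Euler update is gradient descent on this quantity.
    """
    n = state.n_cells
    if n < 2:
        return 0.0
    from .core_model import symmetrized_pair_params

    het = symmetrized_pair_params(params.eph, params.ephrin)
    rows = [(params.eph, 0.0), (het, params.C), (params.ephrin, 0.0)]
    R = np.array([p.R for p, _ in rows])
    A = np.array([(1.0 - att) * p.A for p, att in rows])
    inv_r = np.array([1.0 / p.r for p, _ in rows])
    inv_a = np.array([1.0 / p.a for p, _ in rows])

    iu, ju = np.triu_indices(n, k=1)
    delta = state.positions[iu] - state.positions[ju]
    d = np.hypot(delta[:, 0], delta[:, 1])
    code = state.types[iu].astype(np.intp) + state.types[ju].astype(np.intp)
    u = R[code] * np.exp(-d * inv_r[code]) - A[code] * np.exp(-d * inv_a[code])
    return float(u.sum())


def run(config) -> Trajectory:
    """Run a full simulation from a validated configuration.

    Seeds the initial mixed population, then alternates a motion step and a
    birth step until the configured duration, recording snapshots at the
    output interval (first record at t = 0).  Bit-reproducible for a fixed
    seed.
    """
    from .fixtures import mixed_seeding
    from .io_cli import RunConfig  # noqa: F401  (documented config type)

    params = config.interaction_params()
    motility = MotilityParams(D=config.motility.D)
    birth = BirthParams(beta=config.birth.beta)
    domain = Domain(
        width=config.domain.width,
        height=config.domain.height,
        boundary=config.domain.boundary,
    )
    dt_min = config.numerics.dt_s / 60.0
    duration_min = config.numerics.duration_h * 60.0
    out_every = config.numerics.output_interval_min

    rng = np.random.default_rng(config.seed)
    state = mixed_seeding(
        n_eph=config.initial.n_eph,
        n_ephrin=config.initial.n_ephrin,
        domain=domain,
        rng=rng,
        min_separation=config.initial.min_separation_um,
    )

    n_steps = int(round(duration_min / dt_min)) if duration_min > 0 else 0
    steps_per_output = max(1, int(round(out_every / dt_min)))
    snapshots = [state.snapshot()]
    for k in range(1, n_steps + 1):
        state = step(
            state,
            dt_min,
            motility,
            params,
            cutoff=config.numerics.cutoff_um,
        )
        state = apply_births(state, dt_min, birth)
        # recompute time from the step counter to avoid float accumulation
        state.time = k * dt_min
        if k % steps_per_output == 0 or k == n_steps:
            if state.time > snapshots[-1].time:
                snapshots.append(state.snapshot())
    return Trajectory(snapshots)
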
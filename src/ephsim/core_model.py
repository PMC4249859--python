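"""Pairwise interaction model for Eph/ephrin-mediated cell-cell forces.

Two intermingled cell populations (Eph-receptor-expressing and
ephrin-expressing) interact through short-range radial forces derived from a
potential with a repulsive core (cell surface tension / volume exclusion) and
a longer-ranged attractive well (the sum of all adhesion mechanisms):

    u(d) = R * exp(-d / r) - A * exp(-d / a),        r < a

``R`` and ``A`` set the magnitudes, ``r`` and ``a`` the length scales (µm) of
repulsion and attraction respectively.  Two like cells settle at the distance
``d*`` where ``u'(d*) = 0``; half of that separation is the *effective cell
radius* used for rendering and rasterization.

When an Eph cell contacts an ephrin cell, bidirectional signalling attenuates
adhesion.  This is modelled by scaling only the attraction term of
heterotypic pairs by ``(1 - C)`` with an attenuation constant ``C`` in
[0, 1]: at ``C = 1`` adhesion is cancelled entirely and only surface-tension
repulsion remains; at ``C = 0`` heterotypic pairs behave homotypically.

The functional form lives exclusively in this module so an alternative
potential can be swapped in without touching the simulator.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PopulationParams",
    "InteractionParams",
    "PairClass",
    "potential",
    "potential_derivative",
    "net_force_magnitude",
    "symmetrized_pair_params",
    "pair_force",
    "equilibrium_separation",
    "effective_radius",
    "max_pair_stiffness",
]


class PairClass(enum.Enum):
    """Classification of a cell pair by population membership."""

    HOMOTYPIC_EPH = "homotypic_eph"
    HOMOTYPIC_EPHRIN = "homotypic_ephrin"
    HETEROTYPIC = "heterotypic"


@dataclass(frozen=True)
class PopulationParams:
    """Force-potential parameters of one cell population.

    Parameters
    ----------
    R : float
        Repulsion magnitude (dimensionless potential amplitude).
    A : float
        Attraction magnitude (same scale as ``R``).
    r : float
        Repulsion length scale, µm.
    a : float
        Attraction length scale, µm.  Must exceed ``r`` so the potential has
        a finite equilibrium separation.
    """

    R: float
    A: float
    r: float
    a: float

    def __post_init__(self) -> None:
        if not self.R > 0:
            raise ValueError(f"repulsion magnitude R must be > 0, got {self.R}")
        if self.A < 0:
            raise ValueError(f"attraction magnitude A must be >= 0, got {self.A}")
        if not self.r > 0 or not self.a > 0:
            raise ValueError(f"length scales must be > 0, got r={self.r}, a={self.a}")
        if not self.r < self.a:
            raise ValueError(
                f"repulsion must be shorter-ranged than attraction (r < a); "
                f"got r={self.r}, a={self.a}"
            )


@dataclass(frozen=True)
class InteractionParams:
    """Interaction parameters for a two-population co-culture.

    ``C`` is the heterotypic attenuation constant: the fraction of the
    adhesion (attraction) force cancelled by Eph/ephrin signalling when the
    two cells of a pair belong to different populations.
    """

    eph: PopulationParams
    ephrin: PopulationParams
    C: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.C <= 1.0:
            raise ValueError(f"attenuation constant C must be in [0, 1], got {self.C}")


def potential(d, p: PopulationParams, attenuation: float = 0.0):
    """Pair potential u(d) = R·e^(−d/r) − (1−attenuation)·A·e^(−d/a).

    ``attenuation`` is 0 for homotypic pairs and ``C`` for heterotypic pairs.
    Accepts scalar or array ``d`` (µm); negative distances are a domain error.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    u = p.R * np.exp(-d / p.r) - (1.0 - attenuation) * p.A * np.exp(-d / p.a)
    return float(u) if u.ndim == 0 else u


def potential_derivative(d, p: PopulationParams, attenuation: float = 0.0):
    """Analytic u'(d) of the (optionally attenuated) pair potential."""
    d = np.asarray(d, dtype=float)
    du = (-p.R / p.r) * np.exp(-d / p.r) + (1.0 - attenuation) * (p.A / p.a) * np.exp(
        -d / p.a
    )
    return float(du) if du.ndim == 0 else du


def net_force_magnitude(d, p_pair: PopulationParams, pair_class: PairClass, C: float):
    """Signed radial force between two cells at centre distance ``d``.

    Positive values push the cells apart (repulsion), negative pull them
    together (adhesion).  For heterotypic pairs the attraction term is scaled
    by ``(1 − C)``; repulsion is never attenuated, so at ``C = 1`` only the
    surface-tension repulsion remains and the force is non-negative for all
    ``d``.
    """
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr <= 0):
        raise ValueError("distance must be > 0 for a defined force direction")
    att = C if pair_class is PairClass.HETEROTYPIC else 0.0
    f = -potential_derivative(d_arr, p_pair, attenuation=att)
    return float(f) if np.ndim(f) == 0 else f


def symmetrized_pair_params(
    p_i: PopulationParams, p_j: PopulationParams
) -> PopulationParams:
    """Mixing rule for a pair drawn from populations with unequal parameters.

    Component-wise arithmetic mean of (R, A, r, a).  Using one shared
    parameter set per pair guarantees F_ij = −F_ji (momentum conservation)
    even when R_eph ≠ R_ephrin.
    """
    return PopulationParams(
        R=0.5 * (p_i.R + p_j.R),
        A=0.5 * (p_i.A + p_j.A),
        r=0.5 * (p_i.r + p_j.r),
        a=0.5 * (p_i.a + p_j.a),
    )


def _params_for_pair(
    type_i: str, type_j: str, params: InteractionParams
) -> tuple[PopulationParams, PairClass]:
    if type_i == type_j:
        if type_i == "EPH":
            return params.eph, PairClass.HOMOTYPIC_EPH
        return params.ephrin, PairClass.HOMOTYPIC_EPHRIN
    return symmetrized_pair_params(params.eph, params.ephrin), PairClass.HETEROTYPIC


def pair_force(
    pos_i,
    pos_j,
    type_i: str,
    type_j: str,
    params: InteractionParams,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Drift contribution (µm/min, 2-vector) exerted on cell *i* by cell *j*.

    Radial: magnitude from :func:`net_force_magnitude` at the pair distance,
    direction along ``pos_i − pos_j``.  Coincident centres (d = 0, e.g. the
    instant after a division) get the finite contact-force magnitude along a
    uniformly random direction drawn from ``rng``; a deterministic tie-break
    would bias daughter-cell separation.
    """
    pos_i = np.asarray(pos_i, dtype=float)
    pos_j = np.asarray(pos_j, dtype=float)
    p_pair, pair_class = _params_for_pair(type_i, type_j, params)
    delta = pos_i - pos_j
    d = float(np.hypot(delta[0], delta[1]))
    att = params.C if pair_class is PairClass.HETEROTYPIC else 0.0
    if d == 0.0:
        if rng is None:
            raise ValueError("coincident centres require an RNG for the direction")
        theta = rng.uniform(0.0, 2.0 * math.pi)
        direction = np.array([math.cos(theta), math.sin(theta)])
        magnitude = -potential_derivative(0.0, p_pair, attenuation=att)
        return magnitude * direction
    magnitude = net_force_magnitude(d, p_pair, pair_class, params.C)
    return magnitude * delta / d


def equilibrium_separation(p: PopulationParams) -> float:
    """Distance d* at which the homotypic pair force vanishes (u'(d*) = 0).

    For the exponential form, d* = ln(R·a / (A·r)) / (1/r − 1/a).  Requires
    A > 0 and R·a/(A·r) > 1, otherwise the potential is purely repulsive and
    no equilibrium exists.
    """
    if p.A == 0:
        raise ValueError("no equilibrium: purely repulsive potential (A = 0)")
    ratio = (p.R * p.a) / (p.A * p.r)
    if ratio <= 1.0:
        raise ValueError(
            f"no equilibrium: R·a/(A·r) = {ratio:.4g} <= 1 (attraction dominates "
            "at contact)"
        )
    return math.log(ratio) / (1.0 / p.r - 1.0 / p.a)


def effective_radius(p: PopulationParams) -> float:
    """Effective cell radius r_eff = d*/2.

    Two like cells at rest sit at separation d*, i.e. they touch at their
    effective radii.  Used as the disc radius for rendering and raster
    cluster analysis.
    """
    return 0.5 * equilibrium_separation(p)


def max_pair_stiffness(params: InteractionParams) -> float:
    """Largest linearized relaxation rate (1/min) over all pair classes.

    The stiffest mode of a two-cell system is longitudinal at contact with
    rate 2·|u''(0)| = 2·|R/r² − (1−att)·A/a²|.  Used by the simulator's
    time-step stability check.
    """
    rates = []
    for p, att in (
        (params.eph, 0.0),
        (params.ephrin, 0.0),
        (symmetrized_pair_params(params.eph, params.ephrin), params.C),
    ):
        curv = p.R / p.r**2 - (1.0 - att) * p.A / p.a**2
        rates.append(2.0 * abs(curv))
    return max(rates)
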
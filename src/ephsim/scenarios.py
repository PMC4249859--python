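"""Named configurations reproducing the in-silico co-culture experiments.

Each scenario bundles a complete :class:`~ephsim.io_cli.RunConfig` at *desk
scale*: the experimental well (≈50,000 cells on 0.8 cm²) is represented at
the same seeding density, 6.25×10⁻⁴ cells/µm², on a 640×640 µm field —
256 initial cells.  Full well scale is reachable by overriding the domain
and counts.

Scenarios
---------
``fig1_timecourse``
    Segregation time course: 1:3 Eph:ephrin ratio, equal adhesion and
    surface tension in both populations, full heterotypic de-adhesion
    (C = 1), 49 h with snapshots every 20 min.
``fig3_no_signal`` / ``fig3_low_ephrin`` / ``fig3_wt`` / ``fig3_epha3``
    Signal-strength series at 1:1 ratio: C = 0 (signalling-dead receptor),
    C = 0.5 (low ephrin partner; intermediate attenuation as a documented
    placeholder), C = 1 (wild type), and C = 1 with R_eph = 220 (enhanced
    signalling compacts Eph cells by lowering their surface-tension
    amplitude, shrinking their effective radius).
``fig4_equal_adhesion`` / ``fig4_asymmetric_adhesion``
    Differential-adhesion comparison at 1:1: A_eph = A_ephrin = 100 versus
    A_eph = 110, A_ephrin = 100 — the asymmetric case produces the tightly
    packed "islands-in-a-sea" pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .cluster_analysis import ClusterBins, cluster_density, cluster_report
from .io_cli import (
    DomainConfig,
    InitialConfig,
    InteractionConfig,
    NumericsConfig,
    PopulationConfig,
    RunConfig,
)
from .simulator import Trajectory

__all__ = ["Scenario", "SCENARIO_NAMES", "make_scenario", "summarize_timecourse"]

DESK_DOMAIN = DomainConfig(width=640.0, height=640.0, boundary="REFLECTING")
DESK_CELLS = 256  # 640² µm² × 6.25e-4 cells/µm²


@dataclass(frozen=True)
class Scenario:
    """A named, fully specified simulation + analysis configuration."""

    name: str
    config: RunConfig
    description: str


def _base(n_eph: int, n_ephrin: int, C: float, duration_h: float) -> RunConfig:
    return RunConfig(
        seed=0,
        domain=DESK_DOMAIN,
        initial=InitialConfig(n_eph=n_eph, n_ephrin=n_ephrin),
        interaction=InteractionConfig(C=C),
        numerics=NumericsConfig(duration_h=duration_h, output_interval_min=20.0),
    )


def _scenarios() -> dict[str, Scenario]:
    eph_220 = PopulationConfig(R=220.0)
    eph_A110 = PopulationConfig(A=110.0)
    fig3_kw = dict(n_eph=DESK_CELLS // 2, n_ephrin=DESK_CELLS // 2, duration_h=48.0)
    table = {
        "fig1_timecourse": Scenario(
            "fig1_timecourse",
            _base(n_eph=DESK_CELLS // 4, n_ephrin=3 * DESK_CELLS // 4, C=1.0,
                  duration_h=49.0),
            "Segregation time course, 1:3 Eph:ephrin, C = 1, 49 h.",
        ),
        "fig3_no_signal": Scenario(
            "fig3_no_signal",
            _base(C=0.0, **fig3_kw),
            "Signalling-inactive receptor: no heterotypic de-adhesion (C = 0).",
        ),
        "fig3_low_ephrin": Scenario(
            "fig3_low_ephrin",
            _base(C=0.5, **fig3_kw),
            "Low-ephrin partner cells: intermediate attenuation (C = 0.5).",
        ),
        "fig3_wt": Scenario(
            "fig3_wt",
            _base(C=1.0, **fig3_kw),
            "Wild-type receptor: full heterotypic de-adhesion (C = 1).",
        ),
        "fig3_epha3": Scenario(
            "fig3_epha3",
            replace(
                _base(C=1.0, **fig3_kw),
                interaction=InteractionConfig(eph=eph_220, C=1.0),
            ),
            "Enhanced signalling: C = 1 with R_eph = 220, compacting the Eph "
            "population (smaller effective radius).",
        ),
        "fig4_equal_adhesion": Scenario(
            "fig4_equal_adhesion",
            _base(C=1.0, **fig3_kw),
            "Equal homotypic adhesion (A_eph = A_ephrin = 100).",
        ),
        "fig4_asymmetric_adhesion": Scenario(
            "fig4_asymmetric_adhesion",
            replace(
                _base(C=1.0, **fig3_kw),
                interaction=InteractionConfig(eph=eph_A110, C=1.0),
            ),
            "Raised Eph-Eph adhesion (A_eph = 110 vs A_ephrin = 100): "
            "tightly packed islands-in-a-sea.",
        ),
    }
    return table


SCENARIO_NAMES = tuple(sorted(_scenarios()))


def make_scenario(name: str) -> Scenario:
    """Return the named scenario; unknown names list the valid ones."""
    table = _scenarios()
    if name not in table:
        raise ValueError(
            f"unknown scenario '{name}'; valid names: {', '.join(sorted(table))}"
        )
    return table[name]


def summarize_timecourse(
    trajectory: Trajectory,
    times_h,
    config: RunConfig,
    population: str = "EPH",
) -> list[dict]:
    """Cluster bins and mean density of one population at requested times.

    For each time (hours) the nearest snapshot within half the output
    interval is analysed with the full raster pipeline.  Returns one record
    per time: ``{"time_h", "bins": ClusterBins, "mean_density":
    cells/1000 µm² (nan if no clusters), "n_clusters"}``.
    """
    max_gap = config.numerics.output_interval_min / 2.0
    out = []
    for t_h in times_h:
        snap = trajectory.nearest(t_h * 60.0, max_gap=max_gap)
        clusters, bins = cluster_report(
            snap,
            population,
            r_eff=config.r_eff(population),
            domain=config.sim_domain(),
            pixel_size=config.analysis.pixel_size,
            connectivity=config.analysis.connectivity,
            edges=config.analysis.bin_edges,
        )
        densities = [cluster_density(c) for c in clusters]
        out.append(
            {
                "time_h": t_h,
                "bins": bins,
                "mean_density": float(sum(densities) / len(densities))
                if densities
                else float("nan"),
                "n_clusters": len(clusters),
            }
        )
    return out
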
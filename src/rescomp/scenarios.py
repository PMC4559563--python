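"""Named parameter presets, an end-to-end analysis runner, and a random sampler.

The presets bundle the worked numerical examples of the four supported
configurations — one or two Holling II consumers on one resource, one or
two Liebig consumers on two essential resources — each with the initial
state used to illustrate its transient itinerary.  ``run_scenario`` chains
the full pipeline: closed-form equilibria, eigenvalue classification,
forward-Euler trajectory, and the visit sequence along the saddle points.

``sample_system`` draws random but structurally valid systems for
property-based testing; the same seed always yields the same system.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .equilibria import StationaryPoint, find_all_equilibria
from .model import ConsumerSpec, GrowthModel, ResourceSpec, SystemSpec
from .simulate import (
    DEFAULT_EPS,
    DEFAULT_MIN_DUR,
    Trajectory,
    VisitRecord,
    detect_visits,
    integrate_euler,
)
from .stability import ClassificationResult, classify

__all__ = [
    "Scenario",
    "ScenarioReport",
    "SCENARIOS",
    "scenario_names",
    "get_scenario",
    "run_scenario",
    "sample_system",
    "SHAPES",
]


# ---------------------------------------------------------------------------
# system factories
# ---------------------------------------------------------------------------

def one_consumer_one_resource(
    f_mB: float = 2.5, k_RB: float = 1.0, m_B: float = 1.0,
    a_R: float = 1.0, s_R: float = 1.0, q_RB: float = 1.0,
) -> SystemSpec:
    """Single Holling II consumer ``B`` on a single chemostat resource ``R``."""
    return SystemSpec(
        resources=[ResourceSpec("R", a=a_R, s=s_R)],
        consumers=[
            ConsumerSpec(
                "B", m=m_B,
                growth=GrowthModel("holling2", f_max=f_mB, k={"R": k_RB}),
                q={"R": q_RB},
            )
        ],
    )


def two_consumers_one_resource(s_R: float, a_R: float = 1.0) -> SystemSpec:
    """Consumers ``A`` (f_max=3) and ``B`` (f_max=2) competing for ``R``.

    Unit mortality, conversion and half-saturation for both; the critical
    levels are then 0.5 for ``A`` and 1 for ``B``, so ``A`` is the stronger
    competitor.
    """
    def consumer(cid: str, f_max: float) -> ConsumerSpec:
        return ConsumerSpec(
            cid, m=1.0,
            growth=GrowthModel("holling2", f_max=f_max, k={"R": 1.0}),
            q={"R": 1.0},
        )

    return SystemSpec(
        resources=[ResourceSpec("R", a=a_R, s=s_R)],
        consumers=[consumer("A", 3.0), consumer("B", 2.0)],
    )


def one_consumer_two_resources(
    s_P: float, s_R: float = 1.0, a: float = 1.0, q: float = 1.0,
) -> SystemSpec:
    """Single Liebig consumer ``B`` on essential resources ``P`` and ``R``.

    Unit half-saturations and mortality with f_max=3 put both critical
    levels at 0.5; ``a`` and ``q`` scale the resource dynamics without
    moving the stationary densities.
    """
    return SystemSpec(
        resources=[ResourceSpec("P", a=a, s=s_P), ResourceSpec("R", a=a, s=s_R)],
        consumers=[
            ConsumerSpec(
                "B", m=1.0,
                growth=GrowthModel("liebig_min", f_max=3.0, k={"P": 1.0, "R": 1.0}),
                q={"P": q, "R": q},
            )
        ],
    )


def two_consumers_two_resources(
    s_P: float = 1.0, s_R: float = 1.0, swap_q: bool = False, scale: float = 1.0,
) -> SystemSpec:
    """Liebig consumers ``A`` and ``B`` on essential resources ``P`` and ``R``.

    Half-saturations k_PA=0.9, k_PB=0.7, k_RA=0.8, k_RB=1 with unit
    mortality and f_max=3 place the isocline corners at (0.45, 0.4) for
    ``A`` and (0.35, 0.5) for ``B``, so the isoclines intersect at
    (P_A, R_B) = (0.45, 0.5).  With the default conversion factors
    (q_PA=1, q_RA=0.8, q_PB=0.8, q_RB=1) each consumer takes mostly the
    resource that limits it and coexistence is stable; ``swap_q``
    interchanges the q's of the two consumers, flipping det(Q) and turning
    the coexistence point into a saddle.  ``scale`` multiplies every ``a``
    and ``q`` (slower resource turnover; same equilibria, vortex dynamics).
    """
    qA = {"P": 1.0, "R": 0.8}
    qB = {"P": 0.8, "R": 1.0}
    if swap_q:
        qA, qB = {"P": 0.8, "R": 1.0}, {"P": 1.0, "R": 0.8}
    qA = {r: v * scale for r, v in qA.items()}
    qB = {r: v * scale for r, v in qB.items()}
    return SystemSpec(
        resources=[
            ResourceSpec("P", a=1.0 * scale, s=s_P),
            ResourceSpec("R", a=1.0 * scale, s=s_R),
        ],
        consumers=[
            ConsumerSpec(
                "A", m=1.0,
                growth=GrowthModel("liebig_min", f_max=3.0, k={"P": 0.9, "R": 0.8}),
                q=qA,
            ),
            ConsumerSpec(
                "B", m=1.0,
                growth=GrowthModel("liebig_min", f_max=3.0, k={"P": 0.7, "R": 1.0}),
                q=qB,
            ),
        ],
    )


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Scenario:
    """A named system + initial state + suggested horizon + expected outcome."""

    name: str
    system: SystemSpec
    x0: np.ndarray
    t_end: float
    notes: str


def _build_scenarios() -> dict[str, Scenario]:
    sc: dict[str, Scenario] = {}

    def add(name: str, system: SystemSpec, x0: dict[str, float], t_end: float, notes: str):
        sc[name] = Scenario(name, system, system.state(**x0), t_end, notes)

    add("fig2a", one_consumer_one_resource(), {"B": 0.01, "R": 0.0}, 200.0,
        "lingers at the trivial saddle (0, 1), then settles in the stable "
        "node at (B, R) = (1/3, 2/3)")
    add("fig2c", one_consumer_one_resource(a_R=0.1, q_RB=0.1), {"B": 0.01, "R": 0.0}, 400.0,
        "same equilibria as fig2a but slow resource turnover: spirals into "
        "the coexistence point, a stable vortex with Re(lambda) = -0.065")
    add("fig3a", two_consumers_one_resource(s_R=0.8), {"A": 0.001, "B": 1.0, "R": 0.0}, 200.0,
        "supply too low for B: B dies out, A settles at (A, R) = (0.3, 0.5)")
    add("fig3b", two_consumers_one_resource(s_R=1.2), {"A": 0.001, "B": 1.0, "R": 0.0}, 300.0,
        "B first holds its boundary level B' = 0.2, then A takes over")
    add("fig4a", one_consumer_two_resources(s_P=0.9), {"B": 0.01, "P": 0.0, "R": 0.0}, 200.0,
        "P-limited coexistence at (B, P, R) = (0.4, 0.5, 0.6)")
    add("fig4b", one_consumer_two_resources(s_P=0.7), {"B": 0.01, "P": 0.0, "R": 0.0}, 200.0,
        "lower P supply: same stationary P = 0.5, lower B = 0.2, higher R = 0.8")
    add("fig4c", one_consumer_two_resources(s_P=0.9, a=0.1, q=0.1),
        {"B": 0.01, "P": 0.0, "R": 0.0}, 600.0,
        "same equilibria as fig4a, slow resource turnover: stable vortex")
    add("fig5a", two_consumers_two_resources(),
        {"A": 0.001, "B": 0.01, "P": 0.0, "R": 0.5}, 300.0,
        "itinerary supply point -> B-point -> stable coexistence at "
        "(A, B, P, R) = (0.417, 0.167, 0.45, 0.5)")
    add("fig5c", two_consumers_two_resources(),
        {"A": 0.0, "B": 0.01, "P": 0.0, "R": 0.5}, 300.0,
        "A strictly absent: ends at the B-point (B, P, R) = (0.5, 0.6, 0.5)")
    add("fig5e", two_consumers_two_resources(),
        {"A": 0.001, "B": 0.0, "P": 0.0, "R": 0.5}, 300.0,
        "B strictly absent: ends at the A-point (A, P, R) = (0.55, 0.45, 0.56)")
    add("fig6a", two_consumers_two_resources(s_R=0.8),
        {"A": 0.0001, "B": 0.01, "P": 0.8, "R": 1.0}, 300.0,
        "supply point outside the wedge: itinerary supply -> B-point -> "
        "stable A-point (A, P, R) = (0.5, 0.5, 0.4)")
    add("fig6c", two_consumers_two_resources(s_P=0.8),
        {"A": 0.01, "B": 0.0001, "P": 1.0, "R": 0.8}, 300.0,
        "mirror case: ends at the stable B-point (B, P, R) = (0.5, 0.4, 0.5)")
    add("fig7a", two_consumers_two_resources(swap_q=True),
        {"A": 0.01, "B": 0.05, "P": 0.0, "R": 0.5}, 300.0,
        "swapped conversion factors: coexistence is a saddle; this start "
        "lies in the basin of the stable B-point")
    add("fig7c", two_consumers_two_resources(swap_q=True),
        {"A": 0.01, "B": 0.03, "P": 0.8, "R": 0.0}, 300.0,
        "same system, different start: ends at the stable A-point")
    add("fig8", two_consumers_two_resources(scale=0.1),
        {"A": 0.001, "B": 0.01, "P": 0.0, "R": 0.5}, 1000.0,
        "all a's and q's one tenth: same stationary points as fig5a, "
        "oscillatory approach (stable vortex)")
    return sc


SCENARIOS: dict[str, Scenario] = _build_scenarios()


def scenario_names() -> list[str]:
    return sorted(SCENARIOS)


def get_scenario(name: str) -> Scenario:
    try:
        return SCENARIOS[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; available: {', '.join(scenario_names())}"
        ) from None


@dataclass
class ScenarioReport:
    """Full analysis of one preset: equilibria, classifications, trajectory, visits."""

    scenario: Scenario
    points: list[StationaryPoint]
    classifications: list[ClassificationResult]
    trajectory: Trajectory
    visits: list[VisitRecord]

    def feasible_points(self) -> list[StationaryPoint]:
        return [pt for pt in self.points if pt.feasible]

    def visit_kinds(self) -> list[str]:
        """Human-readable itinerary, e.g. ['supply', 'B', 'A+B']."""
        out = []
        for v in self.visits:
            out.append("+".join(v.point.present_consumers) or "supply")
        return out


def run_scenario(
    name: str,
    dt: float | None = None,
    t_end: float | None = None,
    eps: float = DEFAULT_EPS,
    min_dur: float = DEFAULT_MIN_DUR,
) -> ScenarioReport:
    """Run the full pipeline on a preset and collect the results."""
    sc = get_scenario(name)
    points = find_all_equilibria(sc.system)
    classifications = [classify(sc.system, pt) for pt in points]
    traj = integrate_euler(sc.system, sc.x0, dt=dt, t_end=sc.t_end if t_end is None else t_end)
    visits = detect_visits(traj, [pt for pt in points if pt.feasible],
                           eps=eps, min_dur=min_dur)
    return ScenarioReport(sc, points, classifications, traj, visits)


# ---------------------------------------------------------------------------
# random sampler for property tests
# ---------------------------------------------------------------------------

SHAPES = ("1c1r", "2c1r", "1c2r", "2c2r")

#: Log-uniform sampling ranges for the random system generator.
RANGES = {"rate": (0.05, 5.0), "density": (0.1, 5.0), "q": (0.1, 2.0)}


def _loguniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def sample_system(seed: int, shape: str | None = None) -> SystemSpec:
    """Draw a random valid system; the same seed always gives the same system.

    Rates (``a``, ``m``, ``f_max``) are log-uniform on [0.05, 5], densities
    (``k``, ``s``) on [0.1, 5], conversion factors ``q`` on [0.1, 2].
    ``shape`` picks the configuration (one of :data:`SHAPES`); if omitted it
    is drawn uniformly.  One-resource consumers get Holling II growth,
    two-resource consumers Liebig minimum growth.
    """
    rng = np.random.default_rng(seed)
    if shape is None:
        shape = SHAPES[rng.integers(len(SHAPES))]
    if shape not in SHAPES:
        raise ValueError(f"unknown shape {shape!r}; expected one of {SHAPES}")
    nc = int(shape[0])
    nr = int(shape[2])
    rlo, rhi = RANGES["rate"]
    dlo, dhi = RANGES["density"]
    qlo, qhi = RANGES["q"]
    rids = ["R"] if nr == 1 else ["P", "R"]
    cids = ["B"] if nc == 1 else ["A", "B"]
    resources = [
        ResourceSpec(rid, a=_loguniform(rng, rlo, rhi), s=_loguniform(rng, dlo, dhi))
        for rid in rids
    ]
    consumers = []
    for cid in cids:
        variant = "holling2" if nr == 1 else "liebig_min"
        growth = GrowthModel(
            variant,
            f_max=_loguniform(rng, rlo, rhi),
            k={rid: _loguniform(rng, dlo, dhi) for rid in rids},
        )
        consumers.append(
            ConsumerSpec(
                cid,
                m=_loguniform(rng, rlo, rhi),
                growth=growth,
                q={rid: _loguniform(rng, qlo, qhi) for rid in rids},
            )
        )
    return SystemSpec(resources=resources, consumers=consumers)
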
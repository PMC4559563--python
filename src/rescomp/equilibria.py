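"""Closed-form stationary points for systems with up to two consumers and resources.

Every supported configuration (1 or 2 consumers crossed with 1 or 2
resources) admits a complete closed-form enumeration of its stationary
points:

* the *supply point* (all consumers absent, every resource at its stable
  level ``s_j``) always exists;
* each consumer alone persists at the resource level(s) where its growth
  exactly balances its mortality — on one resource this is the critical
  level ``R* = k m / (f_max - m)``, on two essential resources the
  intersection of the supply line through ``(s_P, s_R)`` with the L-shaped
  zero-growth isocline;
* with two consumers on two resources the isoclines may intersect, and the
  2x2 linear system through the conversion matrix ``Q`` yields the
  coexistence densities.

Each returned point carries a feasibility flag (all densities
non-negative); infeasible points are reported rather than discarded, since
their sign pattern is what decides the qualitative outcome of competition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ConfigError, GrowthModel, SystemSpec, rhs

__all__ = [
    "FEAS_TOL",
    "NoPositiveSolution",
    "SingularConversionError",
    "StationaryPoint",
    "critical_resource_level",
    "supply_point",
    "coexistence_1c1r",
    "single_consumer_point_1r",
    "single_consumer_point_2r",
    "coexistence_2c2r",
    "find_all_equilibria",
    "residual",
    "points_table",
]

#: Densities down to -FEAS_TOL count as zero (boundary-feasible); float
#: noise at thresholds should not flip a feasibility verdict.
FEAS_TOL = 1e-12


class NoPositiveSolution(ValueError):
    """The growth law never reaches the mortality rate: the consumer cannot
    persist at any resource level."""


class SingularConversionError(ValueError):
    """The conversion matrix Q is singular; coexistence densities are undetermined."""


@dataclass(eq=False)
class StationaryPoint:
    """A stationary state of the model with bookkeeping for analysis.

    ``kind`` is ``"supply"`` (no consumers), ``"single_consumer"`` (exactly
    one consumer present) or ``"coexistence"`` (all consumers present).
    ``limiting_resource`` maps each present consumer to the resource id of
    its active growth branch (for Liebig growth) or its sole resource.
    ``on_corner`` marks points that sit exactly on a Liebig kink, where the
    Jacobian follows the lower-index branch convention.
    """

    state: np.ndarray
    kind: str
    present_consumers: tuple[str, ...]
    feasible: bool
    limiting_resource: dict[str, str] = field(default_factory=dict)
    on_corner: bool = False
    diagnostic: str = ""

    def density(self, system: SystemSpec, label: str) -> float:
        return float(self.state[system.labels.index(label)])


def _finish(system: SystemSpec, state: np.ndarray, kind: str,
            present: tuple[str, ...], limiting: dict[str, str],
            on_corner: bool = False, diagnostic: str = "") -> StationaryPoint:
    feasible = bool(np.all(state >= -FEAS_TOL))
    return StationaryPoint(
        state=np.asarray(state, float),
        kind=kind,
        present_consumers=present,
        feasible=feasible,
        limiting_resource=limiting,
        on_corner=on_corner,
        diagnostic=diagnostic,
    )


def critical_resource_level(f_max: float, k: float, m: float) -> float:
    """Resource density where a Holling II consumer has zero net growth.

    Solves ``f_max R / (R + k) = m`` for ``R``, giving ``k m / (f_max - m)``.
    Only exists when the maximal growth rate exceeds the mortality;
    otherwise the consumer declines at every resource level and
    :class:`NoPositiveSolution` is raised.
    """
    if m <= 0:
        raise ConfigError(f"mortality must be positive, got {m}")
    if f_max <= m:
        raise NoPositiveSolution(
            f"maximal growth rate {f_max} does not exceed mortality {m}; "
            "the consumer cannot persist at any resource level"
        )
    return k * m / (f_max - m)


def supply_point(system: SystemSpec) -> StationaryPoint:
    """The consumer-free stationary point: every resource at its stable level."""
    state = np.zeros(system.dim)
    state[system.n_consumers:] = system._s
    return _finish(system, state, "supply", (), {})


# ---------------------------------------------------------------------------
# one resource
# ---------------------------------------------------------------------------

def _critical_levels(growth: GrowthModel, m: float) -> dict[str, float]:
    """Critical level per referenced resource branch of a growth law."""
    return {rid: critical_resource_level(growth.f_max, kv, m) for rid, kv in growth.k.items()}


def single_consumer_point_1r(system: SystemSpec, cid: str) -> StationaryPoint:
    """Stationary point with only consumer ``cid`` on the single resource.

    The resource settles at the consumer's critical level ``R*`` and the
    consumer at ``N* = a (s - R*) / (q m)``; feasible only when ``R* < s``
    (enough supply to sustain the consumer).
    """
    if system.n_resources != 1:
        raise ConfigError("single_consumer_point_1r requires exactly one resource")
    i = system.consumer_index(cid)
    cons = system.consumers[i]
    res = system.resources[0]
    levels = _critical_levels(cons.growth, cons.m)
    rstar = levels[res.id]
    q = cons.q[res.id]
    if q <= 0:
        raise ConfigError(f"consumer {cid!r} has zero conversion factor for {res.id!r}")
    nstar = res.a * (res.s - rstar) / (q * cons.m)
    state = np.zeros(system.dim)
    state[i] = nstar
    state[system.n_consumers] = rstar
    kind = "coexistence" if system.n_consumers == 1 else "single_consumer"
    return _finish(system, state, kind, (cid,), {cid: res.id})


def coexistence_1c1r(system: SystemSpec) -> StationaryPoint:
    """Coexistence point of one consumer and one resource (closed form)."""
    if system.n_consumers != 1 or system.n_resources != 1:
        raise ConfigError("coexistence_1c1r requires exactly one consumer and one resource")
    return single_consumer_point_1r(system, system.consumers[0].id)


# ---------------------------------------------------------------------------
# two resources
# ---------------------------------------------------------------------------

def single_consumer_point_2r(system: SystemSpec, cid: str) -> StationaryPoint:
    """Stationary point with only consumer ``cid`` on two essential resources.

    The resource densities must lie both on the consumer's L-shaped
    zero-growth isocline and on the supply line through ``(s_P, s_R)``
    whose slope is set by the dilution rates and conversion factors
    (consumption removes the two resources in a fixed ratio).  Both
    branches of the isocline are tried; the consistent candidate is the one
    whose free coordinate lies strictly above its own critical level.  If
    neither branch is consistent the supply point cannot sustain the
    consumer and an infeasible point with a diagnostic is returned.
    """
    if system.n_resources != 2:
        raise ConfigError("single_consumer_point_2r requires exactly two resources")
    i = system.consumer_index(cid)
    cons = system.consumers[i]
    if cons.growth.variant != "liebig_min":
        raise ConfigError(f"consumer {cid!r}: two-resource closed forms require liebig_min growth")
    resP, resR = system.resources
    levels = _critical_levels(cons.growth, cons.m)
    Pc, Rc = levels[resP.id], levels[resR.id]
    qP, qR = cons.q[resP.id], cons.q[resR.id]
    if qP <= 0 or qR <= 0:
        raise ConfigError(f"consumer {cid!r}: closed forms require positive conversion factors")

    # supply line: (s_P - P)/(s_R - R) = a_R qP / (a_P qR)
    cand = []  # (P*, R*, limiting rid, slack of the consistency inequality)
    r_at_Pc = resR.s - (resP.a * qR / (resR.a * qP)) * (resP.s - Pc)
    cand.append((Pc, r_at_Pc, resP.id, r_at_Pc - Rc))
    p_at_Rc = resP.s - (resR.a * qP / (resP.a * qR)) * (resR.s - Rc)
    cand.append((p_at_Rc, Rc, resR.id, p_at_Rc - Pc))

    consistent = [c for c in cand if c[3] > FEAS_TOL]
    on_corner = any(abs(c[3]) <= FEAS_TOL for c in cand)
    diagnostic = ""
    if consistent:
        Pstar, Rstar, limiting, _ = consistent[0]
    elif on_corner:
        Pstar, Rstar, limiting = Pc, Rc, resP.id  # lower-index branch convention
    else:
        # supply line passes below the isocline corner: no intersection
        Pstar, Rstar, limiting = Pc, Rc, resP.id
        diagnostic = (
            f"supply point ({resP.s}, {resR.s}) cannot reach the zero-growth "
            f"isocline of {cid!r} (corner at ({Pc:.6g}, {Rc:.6g})); no stationary "
            "point with this consumer"
        )
    nstar = resR.a * (resR.s - Rstar) / (qR * cons.m)
    state = np.zeros(system.dim)
    state[i] = nstar
    state[system.n_consumers + 0] = Pstar
    state[system.n_consumers + 1] = Rstar
    kind = "coexistence" if system.n_consumers == 1 else "single_consumer"
    pt = _finish(system, state, kind, (cid,), {cid: limiting}, on_corner, diagnostic)
    if diagnostic:
        pt.feasible = False
    return pt


def coexistence_2c2r(system: SystemSpec) -> list[StationaryPoint]:
    """Coexistence points of two consumers on two essential resources.

    The two L-shaped isoclines can intersect where one consumer is limited
    by one resource and its competitor by the other.  Both branch pairings
    are enumerated; a candidate intersection ``(P*, R*)`` is kept when each
    consumer's non-limiting resource sits at or above its own critical
    level.  The consumer densities then solve the linear system ``Q (m_A A,
    m_B B)^T = (a_P (s_P - P*), a_R (s_R - R*))^T``; the point is feasible
    when both are positive, which is exactly the condition that the supply
    point lies inside the wedge spanned by the consumption vectors.
    """
    if system.n_consumers != 2 or system.n_resources != 2:
        raise ConfigError("coexistence_2c2r requires exactly two consumers and two resources")
    consA, consB = system.consumers
    for c in (consA, consB):
        if c.growth.variant != "liebig_min":
            raise ConfigError(f"consumer {c.id!r}: 2c2r closed forms require liebig_min growth")
    resP, resR = system.resources
    detQ = float(np.linalg.det(system._Q))
    if abs(detQ) < 1e-12:
        raise SingularConversionError(
            "conversion matrix Q is singular (proportional columns); "
            "coexistence densities are undetermined"
        )
    try:
        levA = _critical_levels(consA.growth, consA.m)
        levB = _critical_levels(consB.growth, consB.m)
    except NoPositiveSolution:
        return []

    points: list[StationaryPoint] = []
    # pairings: (limiting resource of A, limiting resource of B) on opposite axes
    pairings = [
        (resP.id, resR.id, levA[resP.id], levB[resR.id]),
        (resR.id, resP.id, levB[resP.id], levA[resR.id]),
    ]
    for limA, limB, Pstar, Rstar in pairings:
        # consistency: the non-limiting coordinate of each consumer must be
        # at or above that consumer's own critical level on that resource
        slackA = (Rstar - levA[resR.id]) if limA == resP.id else (Pstar - levA[resP.id])
        slackB = (Pstar - levB[resP.id]) if limB == resR.id else (Rstar - levB[resR.id])
        if slackA < -FEAS_TOL or slackB < -FEAS_TOL:
            continue
        on_corner = min(slackA, slackB) <= FEAS_TOL
        b = np.array([resP.a * (resP.s - Pstar), resR.a * (resR.s - Rstar)])
        mAA, mBB = np.linalg.solve(system._Q, b)
        Astar, Bstar = mAA / consA.m, mBB / consB.m
        state = np.array([Astar, Bstar, Pstar, Rstar])
        points.append(
            _finish(
                system, state, "coexistence", (consA.id, consB.id),
                {consA.id: limA, consB.id: limB}, on_corner,
            )
        )
    return points


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def find_all_equilibria(system: SystemSpec) -> list[StationaryPoint]:
    """All closed-form stationary points of a supported configuration.

    Supports up to two consumers and two resources; larger systems raise
    ``NotImplementedError`` (generic simulation remains available).
    Consumers whose maximal growth rate does not exceed their mortality
    simply contribute no boundary point.
    """
    nc, nr = system.n_consumers, system.n_resources
    if nc > 2 or nr > 2:
        raise NotImplementedError(
            f"closed-form equilibria support at most 2 consumers and 2 resources; "
            f"got {nc} consumer(s), {nr} resource(s)"
        )
    points = [supply_point(system)]
    single = single_consumer_point_1r if nr == 1 else single_consumer_point_2r
    for c in system.consumers:
        try:
            points.append(single(system, c.id))
        except NoPositiveSolution:
            continue
    if nc == 2 and nr == 2:
        try:
            points.extend(coexistence_2c2r(system))
        except NoPositiveSolution:
            pass
    return points


def residual(system: SystemSpec, point: StationaryPoint) -> float:
    """Max-norm of the right-hand side at the point (0 at a true equilibrium).

    Evaluated without the domain check so that infeasible points (negative
    consumer densities, which still solve the stationarity equations
    algebraically) can be verified too.
    """
    return float(np.max(np.abs(rhs(system, point.state, check=False))))


def points_table(system: SystemSpec, points: list[StationaryPoint]) -> pd.DataFrame:
    """One row per stationary point: densities, kind, feasibility, limiting branches."""
    rows = []
    for pt in points:
        row: dict = dict(zip(system.labels, pt.state))
        row["kind"] = pt.kind
        row["present_consumers"] = "+".join(pt.present_consumers) or "-"
        row["feasible"] = pt.feasible
        row["limiting"] = ";".join(f"{c}:{r}" for c, r in pt.limiting_resource.items()) or "-"
        row["on_corner"] = pt.on_corner
        if pt.diagnostic:
            row["diagnostic"] = pt.diagnostic
        rows.append(row)
    return pd.DataFrame(rows)
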
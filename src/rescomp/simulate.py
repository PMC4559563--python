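"""Fixed-step forward-Euler integration and transient visit detection.

The dynamics is deterministic and, away from stationary points, fast on
the scale of the rate parameters — but trajectories started near-empty
characteristically travel from saddle to saddle, lingering near each for a
time set by the inverse of its slowest unstable rate before escaping along
the unstable direction.  :func:`detect_visits` extracts that itinerary
from a trajectory: the ordered list of stationary points the state came
close to, with entry/exit times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .equilibria import StationaryPoint, find_all_equilibria
from .model import DomainError, SystemSpec

__all__ = [
    "DEFAULT_EPS",
    "DEFAULT_MIN_DUR",
    "DivergenceError",
    "Trajectory",
    "VisitRecord",
    "default_dt",
    "default_t_end",
    "integrate_euler",
    "detect_visits",
    "trajectory_frame",
]

#: Default visit-detection radius (Euclidean, full state space) and minimum
#: dwell time for an approach to count as a visit.  A transient pass by a
#: saddle happens while the invading consumer is already growing, so the
#: closest approach is loose (~0.15 density units in the worked examples);
#: ambiguity between points is resolved by nearest-point assignment, not by
#: shrinking the radius.
DEFAULT_EPS = 0.2
DEFAULT_MIN_DUR = 2.0

#: Components below this abort the integration (step too large).
ABORT_TOL = -1e-6


class DivergenceError(RuntimeError):
    """The Euler iteration produced a non-finite state."""


@dataclass
class Trajectory:
    """A forward-Euler trajectory: uniform time grid and the state at each node.

    ``states`` has one row per time point, columns in the system's state
    layout (consumers first).  ``termination`` is ``"completed"`` or a
    diagnostic explaining an early stop.
    """

    system: SystemSpec
    dt: float
    times: np.ndarray
    states: np.ndarray
    termination: str = "completed"

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]


@dataclass
class VisitRecord:
    """A maximal interval during which the trajectory stayed within ``eps``
    of one stationary point."""

    point: StationaryPoint
    t_enter: float
    t_exit: float
    min_distance: float


def default_dt(system: SystemSpec) -> float:
    """Step small relative to the fastest rate in the system: ``0.01 / max rate``."""
    return 0.01 / system.rate_scale()


def default_t_end(system: SystemSpec) -> float:
    """Horizon long enough to settle: 100x the slowest stable timescale.

    The slowest stable timescale is the largest ``1/|Re(lambda)|`` over the
    eigenvalues of the feasible stable stationary points.  Falls back to
    ``100 / (slowest rate parameter)`` when no classified stable point is
    available (e.g. unsupported configurations).
    """
    from .stability import classify

    slowest = None
    try:
        for pt in find_all_equilibria(system):
            if not pt.feasible:
                continue
            res = classify(system, pt)
            if res.klass in ("stable_node", "stable_vortex"):
                ts = max(t for t in res.timescales if np.isfinite(t))
                slowest = ts if slowest is None else max(slowest, ts)
    except NotImplementedError:
        pass
    if slowest is None:
        slowest = 1.0 / min(system._a.min(), system._m.min())
    return 100.0 * slowest


def integrate_euler(
    system: SystemSpec,
    x0: np.ndarray,
    dt: float | None = None,
    t_end: float | None = None,
) -> Trajectory:
    """Integrate ``x_{n+1} = x_n + dt * rhs(x_n)`` from ``x0`` up to ``t_end``.

    Consumers starting at exactly zero stay exactly zero (their derivative
    is identically zero and no clamping is ever applied).  If any component
    drops below ``-1e-6`` the run stops early with a step-size diagnostic;
    a non-finite state raises :class:`DivergenceError` naming the step.
    """
    if dt is None:
        dt = default_dt(system)
    if t_end is None:
        t_end = default_t_end(system)
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    x0 = np.asarray(x0, float)
    if x0.shape != (system.dim,):
        raise DomainError(f"x0 has shape {x0.shape}, system expects ({system.dim},)")
    if np.any(x0 < 0):
        raise DomainError(f"initial state must be non-negative, got {x0}")

    n_steps = int(round(t_end / dt))
    nc = system.n_consumers
    m, a, s, Q = system._m, system._a, system._s, system._Q
    K, mask, fmax = system._K, system._mask, system._fmax
    states = np.empty((n_steps + 1, system.dim))
    states[0] = x0
    x = x0.copy()
    termination = "completed"
    last = n_steps
    for n in range(n_steps):
        N, R = x[:nc], x[nc:]
        Rc = np.maximum(R, 0.0)
        ratio = np.where(mask, Rc[:, None] / (Rc[:, None] + K), np.inf)
        f = fmax * ratio.min(axis=0)
        dN = (f - m) * N
        dR = a * (s - R) - Q @ (f * N)
        x = x + dt * np.concatenate([dN, dR])
        if not np.all(np.isfinite(x)):
            raise DivergenceError(
                f"non-finite state at step {n + 1} (t = {(n + 1) * dt:.6g}); "
                "reduce the time step dt"
            )
        states[n + 1] = x
        if np.min(x) < ABORT_TOL:
            termination = (
                f"negative density {np.min(x):.3g} at step {n + 1} "
                f"(t = {(n + 1) * dt:.6g}): time step too large, retry with smaller dt"
            )
            last = n + 1
            break
    times = np.arange(last + 1) * dt
    return Trajectory(system=system, dt=dt, times=times, states=states[: last + 1],
                      termination=termination)


def detect_visits(
    traj: Trajectory,
    points: list[StationaryPoint],
    eps: float = DEFAULT_EPS,
    min_dur: float = DEFAULT_MIN_DUR,
) -> list[VisitRecord]:
    """Chronological list of stays within ``eps`` of the given stationary points.

    Distance is Euclidean in the full state space (not a phase-plane
    projection).  Each time point is assigned to its nearest stationary
    point, so visits never overlap; a maximal run nearer than ``eps`` that
    lasts at least ``min_dur`` becomes one :class:`VisitRecord`.
    """
    if eps <= 0 or min_dur <= 0:
        raise ValueError("eps and min_dur must be positive")
    if not points:
        return []
    P = np.stack([pt.state for pt in points])  # (npts, dim)
    d = np.linalg.norm(traj.states[:, None, :] - P[None, :, :], axis=2)  # (T, npts)
    nearest = d.argmin(axis=1)
    within = d[np.arange(len(traj.times)), nearest] < eps
    visits: list[VisitRecord] = []
    start = None
    for idx in range(len(traj.times) + 1):
        boundary = (
            idx == len(traj.times)
            or not within[idx]
            or (start is not None and nearest[idx] != nearest[start])
        )
        if start is None:
            if idx < len(traj.times) and within[idx]:
                start = idx
            continue
        if boundary:
            t_enter, t_exit = traj.times[start], traj.times[idx - 1]
            if t_exit - t_enter >= min_dur:
                p = int(nearest[start])
                visits.append(
                    VisitRecord(
                        point=points[p],
                        t_enter=float(t_enter),
                        t_exit=float(t_exit),
                        min_distance=float(d[start:idx, p].min()),
                    )
                )
            start = idx if idx < len(traj.times) and within[idx] else None
    return visits


def trajectory_frame(traj: Trajectory) -> pd.DataFrame:
    """Trajectory as a tidy table: column ``t`` then one column per state label."""
    df = pd.DataFrame(traj.states, columns=traj.system.labels)
    df.insert(0, "t", traj.times)
    return df
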
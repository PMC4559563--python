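"""Jacobians, eigenvalues and classification of stationary points.

Linearising the consumer-resource equations about a stationary point gives
the Jacobi matrix, whose eigenvalues are rates: a negative real part is the
rate at which perturbations along the corresponding eigenvector decay, a
positive one the rate at which they grow.  Classification therefore
considers both the sign pattern (node / vortex / saddle) and the
magnitudes, reported as timescales ``1/|Re(lambda)|`` — a saddle with a
tiny unstable rate can dominate the observable transient dynamics for
arbitrarily long even though it is formally unstable.
"""

from __future__ import annotations

import cmath
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .equilibria import StationaryPoint, coexistence_1c1r
from .model import ConfigError, DomainError, SystemSpec, rhs

__all__ = [
    "TOL_IM",
    "ClassificationResult",
    "jacobian",
    "finite_difference_jacobian",
    "eigen_1c1r_coexistence",
    "classify",
    "coexistence_sign_criterion",
    "classification_table",
]

#: Imaginary parts below this are treated as real (no vortex).
TOL_IM = 1e-10

CLASSES = (
    "stable_node",
    "stable_vortex",
    "saddle",
    "unstable_node",
    "unstable_vortex",
    "non_hyperbolic",
)


@dataclass
class ClassificationResult:
    """Eigenvalues and the qualitative type of a stationary point.

    ``timescales`` are ``1/|Re(lambda)|`` in eigenvalue order;
    ``slowest_unstable_rate`` is the smallest positive real part (the rate
    bounding how slowly the system can escape a saddle), or ``None`` for
    stable points.
    """

    eigenvalues: list[complex]
    klass: str
    timescales: list[float]
    slowest_unstable_rate: float | None
    on_corner: bool = False


def _hyperbolicity_tol(system: SystemSpec) -> float:
    # scale-aware: a rate is "zero" only relative to the fastest rate present
    return 1e-8 * system.rate_scale()


def jacobian(system: SystemSpec, state: np.ndarray) -> np.ndarray:
    """Analytic Jacobi matrix of the right-hand side at ``state``.

    Block structure (consumers first, resources second)::

        [ diag(f_i - m_i)      N_i df_i/dR_j                  ]
        [ -q_ji f_i            -a_j I - sum_i q_ji N_i df_i/dR_j ]

    For Liebig growth the derivative of the active (most limiting) branch
    is used; exactly on a corner the lower-index branch is taken by
    convention and the non-smoothness is flagged via
    :meth:`SystemSpec.growth_gradients`.
    """
    x = np.asarray(state, float)
    if x.shape != (system.dim,):
        raise DomainError(f"state has shape {x.shape}, expected ({system.dim},)")
    nc, nr = system.n_consumers, system.n_resources
    N, R = x[:nc], x[nc:]
    f, _ = system.growth_rates(R)
    grad, _, _ = system.growth_gradients(R)  # (nc, nr)
    J = np.zeros((system.dim, system.dim))
    J[:nc, :nc] = np.diag(f - system._m)
    J[:nc, nc:] = N[:, None] * grad
    J[nc:, :nc] = -(system._Q * f[None, :])
    J[nc:, nc:] = -np.diag(system._a) - system._Q @ (N[:, None] * grad)
    return J


def finite_difference_jacobian(system: SystemSpec, state: np.ndarray) -> np.ndarray:
    """Central finite-difference Jacobian, step ``1e-6 * max(1, |x_k|)`` per axis.

    Independent of the analytic derivatives; used as an oracle in the test
    suite and as the only path for states where analytic branch bookkeeping
    is unavailable.
    """
    x = np.asarray(state, float)
    J = np.zeros((system.dim, system.dim))
    for kcol in range(system.dim):
        h = 1e-6 * max(1.0, abs(x[kcol]))
        xp, xm = x.copy(), x.copy()
        xp[kcol] += h
        xm[kcol] -= h
        J[:, kcol] = (rhs(system, xp, check=False) - rhs(system, xm, check=False)) / (2 * h)
    return J


def eigen_1c1r_coexistence(system: SystemSpec) -> tuple[complex, complex]:
    """Closed-form eigenvalue pair at the 1-consumer/1-resource coexistence point.

    With ``c = q N* f'(R*)`` the pair is

    .. math::

        \\lambda_\\pm = -\\tfrac12 (a + c)
                        \\pm \\tfrac12 \\sqrt{(a + c)^2 - 4 m c},

    real for a well-separated node, complex (a stable vortex) when the
    resource timescale is much slower than the consumer's.  Ordered by
    descending real part.
    """
    point = coexistence_1c1r(system)
    if not point.feasible:
        raise ConfigError(
            "the coexistence point is not biologically feasible for these parameters"
        )
    cons = system.consumers[0]
    res = system.resources[0]
    rstar = point.density(system, res.id)
    nstar = point.density(system, cons.id)
    k = cons.growth.k[res.id]
    fprime = cons.growth.f_max * k / (rstar + k) ** 2
    c = cons.q[res.id] * nstar * fprime
    a = res.a
    disc = (a + c) ** 2 - 4 * cons.m * c
    root = cmath.sqrt(complex(disc))
    lam_plus = -0.5 * (a + c) + 0.5 * root
    lam_minus = -0.5 * (a + c) - 0.5 * root
    pair = sorted((lam_plus, lam_minus), key=lambda z: -z.real)
    return pair[0], pair[1]


def classify(system: SystemSpec, point: StationaryPoint) -> ClassificationResult:
    """Classify a stationary point from the eigenvalues of its Jacobian.

    Eigenvalues are sorted by descending real part.  Real parts within
    ``1e-8 * max(a_j, m_i, f_max_i)`` of zero make the point
    ``non_hyperbolic`` (no verdict is guessed); otherwise the sign pattern
    decides between node, vortex and saddle, with complex eigenvalues
    (|Im| > 1e-10) marking a vortex.
    """
    J = jacobian(system, point.state)
    ev = np.linalg.eigvals(J)
    ev = sorted((complex(z) for z in ev), key=lambda z: -z.real)
    tol_re = _hyperbolicity_tol(system)
    re = np.array([z.real for z in ev])
    im = np.array([z.imag for z in ev])
    has_vortex = bool(np.any(np.abs(im) > TOL_IM))
    if np.any(np.abs(re) <= tol_re):
        klass = "non_hyperbolic"
    elif np.any(re > tol_re) and np.any(re < -tol_re):
        klass = "saddle"
    elif np.all(re < -tol_re):
        klass = "stable_vortex" if has_vortex else "stable_node"
    else:
        klass = "unstable_vortex" if has_vortex else "unstable_node"
    timescales = [float(1.0 / abs(z.real)) if abs(z.real) > 0 else np.inf for z in ev]
    unstable = re[re > tol_re]
    slowest = float(unstable.min()) if unstable.size else None
    _, _, on_corner = system.growth_gradients(point.state[system.n_consumers:])
    return ClassificationResult(
        eigenvalues=list(ev),
        klass=klass,
        timescales=timescales,
        slowest_unstable_rate=slowest,
        on_corner=on_corner or point.on_corner,
    )


def coexistence_sign_criterion(system: SystemSpec, point: StationaryPoint) -> str:
    """Determinant sign test for a two-consumer/two-resource coexistence point.

    Compares ``sign(det Q)`` with the sign of the determinant of the growth
    gradient matrix (rows = consumers, columns = resources) at the isocline
    intersection.  Equal signs mean each consumer predominantly consumes
    the resource that limits it there, and the point is stable; opposite
    signs give a saddle.  Returns ``"stable"``, ``"saddle"`` or
    ``"degenerate"`` (either determinant vanishes, no verdict).
    """
    if system.n_consumers != 2 or system.n_resources != 2:
        raise ConfigError("the sign criterion applies to 2-consumer/2-resource systems")
    if point.kind != "coexistence" or not point.feasible:
        raise ConfigError("the sign criterion applies to a feasible coexistence point")
    R = point.state[system.n_consumers:]
    grad, _, _ = system.growth_gradients(R)
    detQ = float(np.linalg.det(system._Q))
    detG = float(np.linalg.det(grad))
    if abs(detQ) < 1e-12 or abs(detG) < 1e-12:
        return "degenerate"
    return "stable" if detQ * detG > 0 else "saddle"


def classification_table(
    system: SystemSpec,
    points: list[StationaryPoint],
    results: list[ClassificationResult] | None = None,
) -> pd.DataFrame:
    """Stability report: densities, class, eigenvalues and timescales per point."""
    if results is None:
        results = [classify(system, pt) for pt in points]
    rows = []
    for pt, res in zip(points, results):
        row: dict = dict(zip(system.labels, pt.state))
        row["kind"] = pt.kind
        row["feasible"] = pt.feasible
        row["class"] = res.klass
        for n, (z, ts) in enumerate(zip(res.eigenvalues, res.timescales), start=1):
            row[f"re_lambda{n}"] = float(f"{z.real:.6g}")
            row[f"im_lambda{n}"] = float(f"{z.imag:.6g}")
            row[f"timescale{n}"] = float(f"{ts:.6g}") if np.isfinite(ts) else np.inf
        rows.append(row)
    return pd.DataFrame(rows)
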
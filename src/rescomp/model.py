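"""Core consumer-resource model: parameter containers, growth laws, ODE right-hand side.

The model couples ``n`` consumer densities :math:`N_i(t)` to ``m`` resource
densities :math:`R_j(t)` through a system of ordinary differential equations

.. math::

    \\frac{dN_i}{dt} &= (f_i(R_1, R_2, \\ldots) - m_i)\\,N_i, \\\\
    \\frac{dR_j}{dt} &= a_j (s_j - R_j) - \\sum_i q_{ji} f_i N_i,

where each resource is replenished chemostat-style toward a stable level
``s_j`` at dilution rate ``a_j``, each consumer dies at a constant per-capita
rate ``m_i``, and consumption of resource ``j`` by consumer ``i`` is
proportional to the consumer's growth with a fixed conversion factor
``q_ji`` (an inverse yield).  Two relative growth laws are supported: the
Holling type II saturating response for a single resource, and Liebig's law
of the minimum over several essential resources.

All quantities are in dimensionless model units: densities set the scale via
the half-saturation constants, rates via the mortality/dilution parameters.
State vectors list consumer densities first, then resource densities, each
in declaration order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "NEG_TOL",
    "ConfigError",
    "DomainError",
    "ResourceSpec",
    "GrowthModel",
    "ConsumerSpec",
    "SystemSpec",
    "holling_growth",
    "liebig_growth",
    "chemostat_supply",
    "rhs",
    "system_from_dict",
    "system_to_dict",
    "load_system",
    "save_system",
]

#: Densities more negative than this are rejected as outside the model domain.
#: Slightly negative values (forward-Euler round-off) are treated as zero
#: inside the growth functions; the dynamics is never silently clamped.
NEG_TOL = 1e-9

GROWTH_VARIANTS = ("holling2", "liebig_min")


class ConfigError(ValueError):
    """A model configuration violates the schema or a structural invariant."""


class DomainError(ValueError):
    """A state or argument lies outside the model's biological domain."""


# ---------------------------------------------------------------------------
# growth laws and the supply term
# ---------------------------------------------------------------------------

def holling_growth(R: float, f_max: float, k: float) -> float:
    """Holling type II relative growth rate ``f_max * R / (R + k)``.

    Parameters
    ----------
    R : float
        Resource density (>= 0).
    f_max : float
        Maximal relative growth rate, approached as ``R -> inf``.
    k : float
        Half-saturation constant: the density at which growth is ``f_max/2``.
    """
    if f_max <= 0:
        raise DomainError(f"f_max must be positive, got {f_max}")
    if k <= 0:
        raise DomainError(f"half-saturation k must be positive, got {k}")
    if R < -NEG_TOL:
        raise DomainError(f"negative resource density {R}")
    R = max(float(R), 0.0)
    return f_max * R / (R + k)


def liebig_growth(
    densities: Mapping[str, float], f_max: float, k: Mapping[str, float]
) -> float:
    """Liebig minimum growth over essential resources.

    Returns ``f_max * min_j R_j / (R_j + k_j)`` over every resource named in
    ``k``: growth is set by the single most limiting resource, and is zero
    whenever any essential resource is absent.
    """
    if f_max <= 0:
        raise DomainError(f"f_max must be positive, got {f_max}")
    missing = [rid for rid in k if rid not in densities]
    if missing:
        raise ConfigError(f"no density supplied for essential resource(s) {missing}")
    worst = np.inf
    for rid, kj in k.items():
        if kj <= 0:
            raise DomainError(f"half-saturation k[{rid!r}] must be positive, got {kj}")
        Rj = densities[rid]
        if Rj < -NEG_TOL:
            raise DomainError(f"negative density for resource {rid!r}: {Rj}")
        Rj = max(float(Rj), 0.0)
        ratio = Rj / (Rj + kj)
        if ratio < worst:
            worst = ratio
    return f_max * worst


def chemostat_supply(R: float, spec: "ResourceSpec") -> float:
    """Chemostat supply term ``a * (s - R)``: relaxation toward the stable level."""
    if R < -NEG_TOL:
        raise DomainError(f"negative resource density {R}")
    return spec.a * (spec.s - float(R))


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResourceSpec:
    """A chemostat resource with dilution rate ``a`` and stable level ``s``."""

    id: str
    a: float
    s: float

    def __post_init__(self) -> None:
        if not self.id:
            raise ConfigError("resource id must be a non-empty string")
        if not self.a > 0:
            raise ConfigError(f"resource {self.id!r}: dilution rate a must be > 0, got {self.a}")
        if self.s < 0:
            raise ConfigError(f"resource {self.id!r}: stable level s must be >= 0, got {self.s}")


@dataclass(frozen=True)
class GrowthModel:
    """A consumer's relative growth law.

    ``variant`` is ``"holling2"`` (single resource, saturating) or
    ``"liebig_min"`` (minimum over essential resources).  ``k`` maps resource
    ids to half-saturation constants; a Holling model references exactly one
    resource, a Liebig model must reference every resource of the system it
    is embedded in (checked by :class:`SystemSpec`).
    """

    variant: str
    f_max: float
    k: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.variant not in GROWTH_VARIANTS:
            raise ConfigError(
                f"unknown growth variant {self.variant!r}; expected one of {GROWTH_VARIANTS}"
            )
        if not self.f_max > 0:
            raise ConfigError(f"f_max must be > 0, got {self.f_max}")
        object.__setattr__(self, "k", dict(self.k))
        if not self.k:
            raise ConfigError("growth model must reference at least one resource")
        for rid, kv in self.k.items():
            if not kv > 0:
                raise ConfigError(f"half-saturation k[{rid!r}] must be > 0, got {kv}")
        if self.variant == "holling2" and len(self.k) != 1:
            raise ConfigError(
                f"holling2 growth references exactly one resource, got {sorted(self.k)}"
            )

    def rate(self, densities: Mapping[str, float]) -> float:
        """Evaluate the relative growth rate at the given resource densities."""
        if self.variant == "holling2":
            (rid, kv), = self.k.items()
            if rid not in densities:
                raise ConfigError(f"no density supplied for resource {rid!r}")
            return holling_growth(densities[rid], self.f_max, kv)
        return liebig_growth(densities, self.f_max, self.k)


@dataclass(frozen=True)
class ConsumerSpec:
    """A consumer with mortality ``m``, a growth law, and conversion factors ``q``."""

    id: str
    m: float
    growth: GrowthModel
    q: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.id:
            raise ConfigError("consumer id must be a non-empty string")
        if not self.m > 0:
            raise ConfigError(f"consumer {self.id!r}: mortality m must be > 0, got {self.m}")
        object.__setattr__(self, "q", dict(self.q))
        if any(qv < 0 for qv in self.q.values()):
            raise ConfigError(f"consumer {self.id!r}: conversion factors must be >= 0")
        if not any(qv > 0 for qv in self.q.values()):
            raise ConfigError(f"consumer {self.id!r}: at least one conversion factor must be > 0")


@dataclass
class SystemSpec:
    """A full model: ordered resources and consumers plus derived arrays.

    On construction the cross-references are validated (every ``q`` and ``k``
    key names a declared resource; the conversion matrix ``Q`` with rows in
    resource order and columns in consumer order is complete) and the dense
    parameter arrays used by the numerical routines are cached.
    """

    resources: Sequence[ResourceSpec]
    consumers: Sequence[ConsumerSpec]

    def __post_init__(self) -> None:
        self.resources = tuple(self.resources)
        self.consumers = tuple(self.consumers)
        if not self.resources:
            raise ConfigError("a system needs at least one resource")
        if not self.consumers:
            raise ConfigError("a system needs at least one consumer")
        rids = [r.id for r in self.resources]
        cids = [c.id for c in self.consumers]
        if len(set(rids + cids)) != len(rids + cids):
            raise ConfigError(f"resource/consumer ids must be unique, got {cids + rids}")
        rset = set(rids)
        for c in self.consumers:
            extra = set(c.q) - rset
            if extra:
                raise ConfigError(f"consumer {c.id!r}: q references undeclared resource(s) {sorted(extra)}")
            if set(c.q) != rset:
                missing = sorted(rset - set(c.q))
                raise ConfigError(
                    f"consumer {c.id!r}: q must cover every resource; missing {missing}"
                )
            extra = set(c.growth.k) - rset
            if extra:
                raise ConfigError(
                    f"consumer {c.id!r}: growth references undeclared resource(s) {sorted(extra)}"
                )
            if c.growth.variant == "liebig_min" and set(c.growth.k) != rset:
                missing = sorted(rset - set(c.growth.k))
                raise ConfigError(
                    f"consumer {c.id!r}: liebig_min growth must reference every resource; "
                    f"missing {missing}"
                )
        nr, nc = len(self.resources), len(self.consumers)
        self._a = np.array([r.a for r in self.resources], float)
        self._s = np.array([r.s for r in self.resources], float)
        self._m = np.array([c.m for c in self.consumers], float)
        self._fmax = np.array([c.growth.f_max for c in self.consumers], float)
        self._Q = np.array([[c.q[r.id] for c in self.consumers] for r in self.resources], float)
        # half-saturation matrix with a placeholder where a resource is not
        # referenced by a consumer's growth law; _mask marks real entries
        self._K = np.ones((nr, nc))
        self._mask = np.zeros((nr, nc), dtype=bool)
        for i, c in enumerate(self.consumers):
            for j, r in enumerate(self.resources):
                if r.id in c.growth.k:
                    self._K[j, i] = c.growth.k[r.id]
                    self._mask[j, i] = True

    # -- shape and labelling ------------------------------------------------

    @property
    def n_consumers(self) -> int:
        return len(self.consumers)

    @property
    def n_resources(self) -> int:
        return len(self.resources)

    @property
    def dim(self) -> int:
        return self.n_consumers + self.n_resources

    @property
    def labels(self) -> list[str]:
        """State-vector labels: consumer ids then resource ids."""
        return [c.id for c in self.consumers] + [r.id for r in self.resources]

    @property
    def Q(self) -> np.ndarray:
        """Conversion matrix, rows = resources, columns = consumers."""
        return self._Q.copy()

    def consumer_index(self, cid: str) -> int:
        for i, c in enumerate(self.consumers):
            if c.id == cid:
                return i
        raise KeyError(f"no consumer {cid!r}; have {[c.id for c in self.consumers]}")

    def resource_index(self, rid: str) -> int:
        for j, r in enumerate(self.resources):
            if r.id == rid:
                return j
        raise KeyError(f"no resource {rid!r}; have {[r.id for r in self.resources]}")

    def state(self, **densities: float) -> np.ndarray:
        """Build a state vector from keyword densities by id; absent ids are 0."""
        x = np.zeros(self.dim)
        labels = self.labels
        for key, val in densities.items():
            if key not in labels:
                raise KeyError(f"unknown id {key!r}; state labels are {labels}")
            x[labels.index(key)] = val
        return x

    def rate_scale(self) -> float:
        """Largest rate parameter in the system (max of a_j, m_i, f_max_i)."""
        return float(max(self._a.max(), self._m.max(), self._fmax.max()))

    # -- vectorised growth evaluation --------------------------------------

    def growth_rates(self, R: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Relative growth rates of all consumers at resource densities ``R``.

        Returns ``(f, active)`` where ``active[i]`` is the index of the
        limiting resource for consumer ``i`` (the Holling resource, or the
        active Liebig branch; ties resolve to the lower resource index).
        """
        Rc = np.maximum(np.asarray(R, float), 0.0)
        ratio = np.where(self._mask, Rc[:, None] / (Rc[:, None] + self._K), np.inf)
        active = ratio.argmin(axis=0)
        cols = np.arange(self.n_consumers)
        f = self._fmax * ratio[active, cols]
        return f, active

    def growth_gradients(self, R: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
        """Partial derivatives ``df_i/dR_j`` at resource densities ``R``.

        Uses the active branch of each growth law (the lower-index resource
        on an exact Liebig tie).  Returns ``(grad, active, on_corner)`` with
        ``grad`` of shape (n_consumers, n_resources); ``on_corner`` is True
        when some consumer sits exactly on a Liebig corner, where the growth
        law is continuous but not differentiable.
        """
        Rc = np.maximum(np.asarray(R, float), 0.0)
        ratio = np.where(self._mask, Rc[:, None] / (Rc[:, None] + self._K), np.inf)
        active = ratio.argmin(axis=0)
        cols = np.arange(self.n_consumers)
        grad = np.zeros((self.n_consumers, self.n_resources))
        kact = self._K[active, cols]
        grad[cols, active] = self._fmax * kact / (Rc[active] + kact) ** 2
        on_corner = False
        for i in range(self.n_consumers):
            others = ratio[:, i].copy()
            others[active[i]] = np.inf
            nxt = others.min()
            if np.isfinite(nxt) and abs(nxt - ratio[active[i], i]) <= 1e-12:
                on_corner = True
        return grad, active, on_corner


# ---------------------------------------------------------------------------
# right-hand side
# ---------------------------------------------------------------------------

def rhs(system: SystemSpec, state: np.ndarray, *, check: bool = True) -> np.ndarray:
    """Time derivative of the full state (consumers first, then resources).

    ``dN_i/dt = (f_i - m_i) N_i`` and ``dR_j/dt = a_j (s_j - R_j) - sum_i
    q_ji f_i N_i``.  A consumer at exactly zero density has exactly zero
    derivative, so absent consumers can never appear.  Entries more negative
    than ``-NEG_TOL`` are rejected; small negative round-off is treated as
    zero inside the growth functions only.
    """
    x = np.asarray(state, float)
    if x.shape != (system.dim,):
        raise DomainError(
            f"state has shape {x.shape}, system expects ({system.dim},) "
            f"with labels {system.labels}"
        )
    if check:
        if not np.all(np.isfinite(x)):
            raise DomainError("state contains non-finite entries")
        if np.any(x < -NEG_TOL):
            raise DomainError(f"state contains negative densities beyond tolerance: {x}")
    nc = system.n_consumers
    N, R = x[:nc], x[nc:]
    f, _ = system.growth_rates(R)
    dN = (f - system._m) * N
    dR = system._a * (system._s - R) - system._Q @ (f * N)
    return np.concatenate([dN, dR])


# ---------------------------------------------------------------------------
# configuration serialization (strict JSON/YAML schema)
# ---------------------------------------------------------------------------

def _require_keys(d: Mapping, allowed: set[str], required: set[str], where: str) -> None:
    if not isinstance(d, Mapping):
        raise ConfigError(f"{where}: expected a mapping, got {type(d).__name__}")
    extra = set(d) - allowed
    if extra:
        raise ConfigError(f"{where}: unknown key(s) {sorted(extra)}; allowed {sorted(allowed)}")
    missing = required - set(d)
    if missing:
        raise ConfigError(f"{where}: missing required key(s) {sorted(missing)}")


def system_from_dict(doc: Mapping) -> SystemSpec:
    """Build a :class:`SystemSpec` from a plain configuration mapping.

    Schema: ``{"resources": [{"id", "a", "s"}, ...], "consumers": [{"id",
    "m", "growth": {"variant", "f_max", "k": {rid: value}}, "q": {rid:
    value}}, ...]}``.  Unknown keys are rejected with an informative error.
    """
    _require_keys(doc, {"resources", "consumers"}, {"resources", "consumers"}, "top level")
    resources = []
    for n, rd in enumerate(doc["resources"]):
        _require_keys(rd, {"id", "a", "s"}, {"id", "a", "s"}, f"resources[{n}]")
        resources.append(ResourceSpec(id=rd["id"], a=float(rd["a"]), s=float(rd["s"])))
    consumers = []
    for n, cd in enumerate(doc["consumers"]):
        _require_keys(cd, {"id", "m", "growth", "q"}, {"id", "m", "growth", "q"}, f"consumers[{n}]")
        gd = cd["growth"]
        _require_keys(
            gd, {"variant", "f_max", "k"}, {"variant", "f_max", "k"},
            f"consumers[{n}].growth",
        )
        growth = GrowthModel(
            variant=gd["variant"],
            f_max=float(gd["f_max"]),
            k={rid: float(v) for rid, v in gd["k"].items()},
        )
        consumers.append(
            ConsumerSpec(
                id=cd["id"],
                m=float(cd["m"]),
                growth=growth,
                q={rid: float(v) for rid, v in cd["q"].items()},
            )
        )
    return SystemSpec(resources=resources, consumers=consumers)


def system_to_dict(system: SystemSpec) -> dict:
    """Inverse of :func:`system_from_dict`; round-trips exactly."""
    return {
        "resources": [{"id": r.id, "a": r.a, "s": r.s} for r in system.resources],
        "consumers": [
            {
                "id": c.id,
                "m": c.m,
                "growth": {
                    "variant": c.growth.variant,
                    "f_max": c.growth.f_max,
                    "k": dict(c.growth.k),
                },
                "q": dict(c.q),
            }
            for c in system.consumers
        ],
    }


def load_system(path: str | Path) -> SystemSpec:
    """Read a system configuration from a JSON (``.json``) or YAML file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        doc = yaml.safe_load(text)
    else:
        doc = json.loads(text)
    return system_from_dict(doc)


def save_system(system: SystemSpec, path: str | Path) -> None:
    """Write a system configuration as JSON or YAML, chosen by file suffix."""
    path = Path(path)
    doc = system_to_dict(system)
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        path.write_text(yaml.safe_dump(doc, sort_keys=False))
    else:
        path.write_text(json.dumps(doc, indent=2) + "\n")
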
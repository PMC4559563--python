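import numpy as np
import pytest

from rescomp.equilibria import coexistence_2c2r
from rescomp.model import ConsumerSpec, GrowthModel, ResourceSpec, SystemSpec
from rescomp.scenarios import (
    get_scenario,
    one_consumer_one_resource,
    one_consumer_two_resources,
    two_consumers_one_resource,
    two_consumers_two_resources,
)


@pytest.fixture
def fig2a_system():
    """Single Holling II consumer, unit rates, f_max=2.5: stable coexistence."""
    return one_consumer_one_resource()


@pytest.fixture
def fig2c_system():
    """Same equilibria with slow resource turnover (a=q=0.1): stable vortex."""
    return one_consumer_one_resource(a_R=0.1, q_RB=0.1)


@pytest.fixture
def fig5_system():
    """Two Liebig consumers, two resources, stable coexistence wedge."""
    return two_consumers_two_resources()


@pytest.fixture
def fig6a_system():
    """Fig5 parameters with s_R=0.8: supply point outside the wedge."""
    return two_consumers_two_resources(s_R=0.8)


@pytest.fixture
def fig7_system():
    """Fig5 parameters with the consumers' q's interchanged: coexistence saddle."""
    return two_consumers_two_resources(swap_q=True)


@pytest.fixture
def fig3_factory():
    return two_consumers_one_resource


@pytest.fixture
def fig4_factory():
    return one_consumer_two_resources


@pytest.fixture
def scenario():
    return get_scenario


def make_feasible_2c2r(seed):
    """Random two-consumer/two-resource system with a guaranteed feasible
    coexistence point.

    Instead of rejection sampling (feasible coexistence is rare under
    independent parameter draws), the stationary densities are drawn first
    and the supply levels are solved from the stationarity conditions:
    s_j = R_j* + (sum_i q_ji m_i N_i*) / a_j.  The isocline corners are
    ordered so the two L-shaped isoclines intersect at (P_A, R_B), with
    consumer A limited by P and consumer B by R.  Both stable and saddle
    coexistence occurs depending on the conversion-factor draw.
    """
    rng = np.random.default_rng(seed)

    def loguni(lo, hi, n=None):
        return np.exp(rng.uniform(np.log(lo), np.log(hi), n))

    m = loguni(0.05, 5.0, 2)
    f_max = m * loguni(1.2, 4.0, 2)
    p_hi, p_lo = np.sort(loguni(0.1, 5.0, 2))[::-1]
    r_lo, r_hi = np.sort(loguni(0.1, 5.0, 2))
    crit = {"A": {"P": p_hi, "R": r_lo}, "B": {"P": p_lo, "R": r_hi}}
    a = loguni(0.05, 5.0, 2)
    q = {c: {"P": loguni(0.1, 2.0), "R": loguni(0.1, 2.0)} for c in "AB"}
    n_star = loguni(0.05, 2.0, 2)
    P_star, R_star = p_hi, r_hi  # intersection (P_A, R_B)
    s_P = P_star + (q["A"]["P"] * m[0] * n_star[0] + q["B"]["P"] * m[1] * n_star[1]) / a[0]
    s_R = R_star + (q["A"]["R"] * m[0] * n_star[0] + q["B"]["R"] * m[1] * n_star[1]) / a[1]
    consumers = []
    for i, cid in enumerate("AB"):
        k = {rid: lvl * (f_max[i] - m[i]) / m[i] for rid, lvl in crit[cid].items()}
        consumers.append(
            ConsumerSpec(
                cid, m=float(m[i]),
                growth=GrowthModel("liebig_min", f_max=float(f_max[i]), k=k),
                q={rid: float(v) for rid, v in q[cid].items()},
            )
        )
    return SystemSpec(
        resources=[
            ResourceSpec("P", a=float(a[0]), s=float(s_P)),
            ResourceSpec("R", a=float(a[1]), s=float(s_R)),
        ],
        consumers=consumers,
    )


@pytest.fixture(scope="session")
def feasible_2c2r_pairs():
    """500 random systems paired with their feasible coexistence point."""
    pairs = []
    seed = 0
    while len(pairs) < 500:
        system = make_feasible_2c2r(seed)
        seed += 1
        if abs(np.linalg.det(system.Q)) < 1e-6:
            continue
        pts = [p for p in coexistence_2c2r(system) if p.feasible and not p.on_corner]
        if pts:
            pairs.append((system, pts[0]))
    return pairs
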
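# Methods

## Model and assumptions

The package implements the classical consumer-resource competition model
in which consumers interact only through shared resources:

* consumer dynamics `dN_i/dt = (f_i - m_i) N_i`, with constant per-capita
  mortality `m_i` and a relative growth rate `f_i` that depends on the
  resource densities only (no direct consumer-consumer interaction);
* resource dynamics `dR_j/dt = a_j (s_j - R_j) - Σ_i q_ji f_i N_i`:
  chemostat supply relaxing to a stable level `s_j` at dilution rate
  `a_j` (no resource-resource interaction), minus consumption
  proportional to consumer growth through constant conversion factors
  `q_ji` (inverse yields).

Growth laws: Holling type II `f = f_max R/(R + k)` for one resource, and
Liebig's law of the minimum `f = f_max · min_j R_j/(R_j + k_j)` for
essential resources. Both are zero at zero resource and monotone
non-decreasing, which is what the qualitative theory relies on.

All quantities are in dimensionless model units; half-saturation
constants set the density scale and mortality/dilution rates the time
scale. A scale-covariance property test checks that multiplying all
densities together with every `k` and `s` by a common factor leaves all
rates unchanged.

## Parameters that matter

| parameter | units | meaning | typical default here |
|---|---|---|---|
| `a_j` | 1/time | resource dilution/turnover rate | 1 (0.1 in "slow" variants) |
| `s_j` | density | stable supply level | 0.7–1.2 across presets |
| `m_i` | 1/time | consumer mortality | 1 |
| `f_max,i` | 1/time | maximal growth rate | 2–3 |
| `k_ji` | density | half-saturation | 0.7–1 |
| `q_ji` | – | conversion factor (inverse yield) | 0.1–1 |

A consumer can persist on one resource only if `f_max > m`; its critical
level is then `R* = k m/(f_max - m)`, and coexistence with the resource is
feasible iff `R* < s`, equivalently `f_max > m (1 + k/s)`.

## Closed-form equilibria

* **Supply point** — all consumers zero, `R_j = s_j`; always exists.
* **One resource** — the resource sits at the consumer's critical level,
  the consumer at `N* = a (s - R*)/(q m)`; with two consumers each
  boundary point is computed the same way with the competitor absent.
* **Two resources, one consumer** — the stationarity of both resource
  equations forces the state onto the supply line through `(s_P, s_R)`
  with slope `a_R q_P / (a_P q_R)`; the stationary point is its
  intersection with the L-shaped isocline. Both branches (P-limited,
  R-limited) are evaluated and the candidate whose free coordinate lies
  strictly above its own critical level is kept. Because the supply line
  has strictly positive slope it always crosses the isocline exactly
  once; insufficient supply shows up as a negative implied consumer
  density (the point is returned flagged infeasible), not as a missing
  intersection. An intersection exactly at the corner is returned flagged
  `on_corner`, with the lower-index resource as the conventional active
  branch.
* **Two consumers, two resources** — the two branch pairings of the two
  L-shaped isoclines are enumerated; a candidate `(P*, R*)` is consistent
  when each consumer's non-limiting resource is at or above its own
  critical level. Consumer densities solve
  `Q (m_A A, m_B B)ᵀ = (a_P(s_P - P*), a_R(s_R - R*))ᵀ`; a singular `Q`
  (proportional consumption vectors) is reported as an error. Feasibility
  (both densities positive) is equivalent to the supply point lying in
  the wedge spanned by the consumption vectors — asserted on randomized
  systems in the test suite. All consistent intersections are returned;
  none is ranked.

Feasibility uses a tolerance of `1e-12`: densities down to `-1e-12` count
as boundary-feasible, so float noise at thresholds cannot flip a verdict.
Every feasible point is verified to satisfy `max |rhs| < 1e-9`.

## Stability analysis

The Jacobian is assembled analytically from the active growth branches;
a central finite-difference Jacobian (step `1e-6 · max(1, |x_k|)`) serves
as an independent oracle in the tests and as the fallback for states
where branch bookkeeping is unavailable. Classification uses the
eigenvalue real parts with a scale-aware tolerance
`tol_re = 1e-8 · max(a_j, m_i, f_max,i)`; any real part within the
tolerance yields `non_hyperbolic` rather than a guessed verdict, and
imaginary parts above `1e-10` mark a vortex. Eigenvalues are reported in
descending real part together with their timescales `1/|Re λ|` — for
transient dynamics the magnitude of the slowest unstable rate matters as
much as its sign, since it bounds how long a trajectory can linger at a
saddle.

For the single-consumer coexistence point the eigenvalue pair is also
available in closed form,
`λ± = -(a + c)/2 ± sqrt((a + c)² - 4 m c)/2` with `c = q N* f'(R*)`,
and is tested to agree with the generic eigensolver to `1e-9`. For
two-consumer coexistence the determinant sign criterion
`sign(det Q) · sign(det ∇f)` (saddle when negative) is implemented as an
independent route and tested against the eigenvalue classification on 500
randomized feasible systems.

Liebig-corner equilibria are classified with the active-branch Jacobian
but always flagged; no differentiability claim is made there.

## Simulation and visit detection

Integration is plain forward Euler with fixed step, `x_{n+1} = x_n + dt ·
rhs(x_n)`. Defaults: `dt = 0.01 / max(a_j, m_i, f_max,i)` (the step
resolves the fastest rate to 1%) and `t_end = 100 ×` the slowest stable
timescale. Densities are never clamped: a consumer starting at exactly
zero stays exactly zero (its derivative is identically zero), a component
dropping below `-1e-6` aborts the run with a retry-with-smaller-`dt`
diagnostic, and a non-finite state raises an error naming the step.
A Richardson test checks the expected first-order convergence of the
endpoints.

Visit detection assigns every time point to the nearest stationary point
(Euclidean distance in the full state space, not the phase-plane
projection) and keeps maximal runs closer than `eps` that last at least
`min_dur`. Defaults are `eps = 0.2`, `min_dur = 2` time units: measured
on the worked examples, a transient pass near a saddle happens while the
invading consumer is already growing, so the closest approach is loose
(≈ 0.15 density units to the B-only point in the two-consumer
two-resource run) and dwell times near the supply point are a few time
units. Tighter settings miss itinerary stages that are plainly visible in
the trajectories; nearest-point assignment keeps visits non-overlapping
even with the loose radius. Both knobs are exposed per call and on the
CLI.

## Presets

The fifteen presets (`fig2a` … `fig8`) cover: stable node and stable
vortex coexistence of one consumer and one resource; competitive
exclusion on one resource below/above the weaker consumer's critical
supply; one consumer on two essential resources with supply-level
trade-offs and a slow-turnover vortex variant; and two consumers on two
resources with stable coexistence, exclusion outside the consumption
wedge, bistability under swapped conversion factors, and a slow-turnover
vortex. Three small editorial choices are documented here as the
package's own: the two-resource presets use `k_RB = 1` (one source prints
an inconsistent subscript for that constant); the `fig4b` initial
consumer density reuses `B(0) = 0.01` from `fig4a`; and the `fig6c`
initial state mirrors `fig6a` across the consumer/resource role swap
(`P=1, R=0.8, A=0.01, B=0.0001`), consistent with the near-identical
mirrored time courses it produces. Where a printed endpoint disagrees
with the closed form in the third decimal (a `P` coordinate of 0.395 vs
the exact 0.4), the closed form is authoritative — the discrepancy is
finite-`dt` endpoint rounding.

## Random sampler

`sample_system(seed, shape)` draws structurally valid systems for
property tests: rates (`a`, `m`, `f_max`) log-uniform on [0.05, 5],
densities (`k`, `s`) on [0.1, 5], conversion factors on [0.1, 2], over
the four supported shapes. Under independent draws a feasible
two-consumer coexistence is rare (≈ 0.5%), so the test suite additionally
constructs feasible systems directly by drawing the stationary densities
first and solving the stationarity conditions for the supply levels; both
routes are exercised.

## What the tests do and do not show

All quantitative checks run on the dimensionless worked parameter sets
and on randomized systems within the ranges above. They validate the
closed forms, the analytic Jacobian, the criterion/eigenvalue agreement,
first-order Euler convergence and the saddle itineraries. They do not
address real ecological data: no stochastic demography, spatial
structure, time-varying supply, adaptive foraging, or more than two
consumers/resources (for larger systems only the generic `rhs`,
finite-difference Jacobian and Euler integrator apply, and phenomena such
as chaotic three-species regimes are out of scope). Euler with fixed step
is used deliberately for transparency, not efficiency; stiff parameter
combinations require a smaller `dt` than the default heuristic.
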
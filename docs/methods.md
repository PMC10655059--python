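# Methods

## Model and assumptions

`csmig` treats the 0–30 cm soil column as a catenary chain of six
compartments, one per 5-cm layer. ¹³⁷Cs moves only downward, from each
compartment to the next, at a first-order rate; the bottom compartment
leaks out of the modelled column. The state variables are the fractional
contributions `R_z = A_z / T` (ratios of per-layer mass activities to their
sum), so radioactive decay divides out of the dynamics and is applied only
where absolute activities are needed (deposition arithmetic, synthetic
profile generation).

Assumptions inherited from this model class:

- first-order, memoryless transfer — no explicit advection–diffusion
  physics, no sorption kinetics;
- the site is undisturbed (no ploughing or bioturbation that would remix
  layers);
- one rate per link; the single-parameter variant further assumes the rate
  is depth-independent. Depth-increasing rates are the expected signature
  of diffusion-dominated transport, which is why the rate-structure
  comparison (`compare_rate_models`) is part of the analysis.

The reference configuration is six 5-cm layers, soil density 1.3 g/cm³,
initial fractions (0.71, 0.11, 0.06, 0.05, 0.04, 0.02) at the deposition
date (1986-04-26). The initial vector sums to 0.99 as printed in the source
measurements and is deliberately never renormalized.

## Parameters

| parameter | units | default | why |
|---|---|---|---|
| `k` (transfer rate) | y⁻¹ | 0.024 | reference estimate from the surface-layer fit; 1/k ≈ 41.7 y residence time |
| layer thickness | cm | 5 | the sampling protocol's slice thickness |
| density | g/cm³ | 1.3 | measured site bulk density; deposition scales linearly in it |
| half-life | y | 30.08 | ¹³⁷Cs; used only for backdating/decay, configurable |
| `noise_cv` | – | 0.10 | reported combined standard uncertainty (coverage factor 1) of the mass activities |
| `deposition_0` | kBq/m² | 18.6 | backdated areal inventory at the reference site |
| `R5(0)` fixed intercept | – | 0.71 | the t = 0 surface fraction; fixed, not re-estimated, so `k` is the only free parameter |

## Fitting

`SurfaceFractionModel.fit()` minimises `Σ (R5_i − R5(0) e^{−k t_i})²` over
`k` alone (unweighted by default; a 1/σ² weighted option exists). The
optimizer starts from the deterministic log-ratio slope through the last
point, clipped to [1e-4, 1]. The reported standard error is the asymptotic
one-parameter Gauss–Newton value `sqrt(s² / Σ J_i²)` with
`J_i = −R5(0) t_i e^{−k t_i}` and `s² = RSS/(n−1)`; a seeded
residual-resampling bootstrap (`bootstrap_se`) is offered because the
asymptotic error understates scatter-driven uncertainty on small, irregular
designs. Fitting uses only the surface layer: its solution
`R5(0) e^{−kt}` is independent of all deeper rates, so the estimate is
identical under both rate structures.

## Numerical choices

- **Distinct-rate solver.** `general_chain_solution` propagates each
  compartment's solution symbolically as a sum of `c · t^p · e^{−λt}` terms
  through the recursion
  `R_i(t) = e^{−k_i t}[R_i(0) + k_{i−1} ∫₀ᵗ e^{k_i s} R_{i−1}(s) ds]`.
  For distinct rates this reproduces the Bateman product form; when the
  incoming term's rate coincides with the compartment's own rate the
  integral raises the polynomial degree instead of dividing by the rate
  difference, so the repeated-eigenvalue (confluent) solution is exact
  rather than a numerically cancelled limit.
- **Confluent threshold.** Rates are merged when they differ by less than
  1e-7 relative to the largest rate. The generic branch divides by rate
  gaps raised to the group size and loses all double-precision accuracy for
  spreads below roughly 1e-7·k in a six-link chain; merging at that spread
  perturbs the trajectory by only O(spread × horizon) ≈ 1e-5 absolute.
  Chains with several rates clustered at intermediate spreads
  (≈1e-7–1e-4 relative) sit between the two branches and can lose
  accuracy; the RK4 oracle is the cross-check for such inputs.
- **RK4 oracle.** `ode_oracle` integrates the raw ODEs with a fixed-step
  classical Runge–Kutta scheme, implemented independently of both analytic
  routes precisely so it can arbitrate them; at step 1e-3 y it agrees with
  the closed forms to ~1e-14 over a 50-year horizon.
- **t = 0.** Both solvers return the initial vector exactly (early return),
  honouring the invariant rather than accumulating rounding in the generic
  constant terms.
- **Degenerate inputs.** All-zero profiles, non-positive densities,
  negative elapsed times, non-contiguous layers, sub-3-point fits and
  all-non-positive series raise descriptive `ValueError`s; negative
  trajectory values beyond −1e-12 propagate (they indicate a real bug) while
  smaller rounding dust is clamped to zero.
- **Calendar convention.** Elapsed times are fractional years at
  365.25 d/y from 1986-04-26. Synthetic sampling times are snapped to the
  whole-day grid before propagation so that a written profile's date
  recovers the simulation time exactly on re-reading.

## Synthetic data

The generator emulates the statistical design of the 1987–2023 monitoring
campaign that motivates the package, whose raw series is unpublished:
six 5-cm layers, irregular sampling between 1.2 and 37 y after deposition
(default: 24 geometrically spaced times — the true campaign dates are not
printed, and geometric spacing mimics the denser early coverage of
post-accident monitoring), independent multiplicative Gaussian noise per
layer with CV 0.10 truncated at zero (lognormal optional), density
1.3 g/cm³ and backdated inventory 18.6 kBq/m². Sampled fraction vectors are
renormalized to sum 1 by default because measured `R_z` are ratios of
simultaneously measured activities; `renormalize=False` exposes the raw
(leaky) model fractions.

What it does *not* emulate: spatial heterogeneity across the site,
inter-campaign instrument changes, correlated (shared-calibration) errors
between layers, and any early-time fast percolation beyond what the initial
vector already encodes. Passing tests therefore demonstrate correctness of
the arithmetic and estimator behaviour under the stated noise model, not
fidelity to any particular field site.

A consequence of renormalization worth knowing: the chain leaks below
30 cm, so renormalized noiseless surface fractions equal
`0.71 e^{−kt}/S(t)` with `S(t)` slipping from 0.99 to ≈0.965 over 37 y.
The fixed-intercept fit on such series is biased low by ≈1.3e-3 y⁻¹ —
small against the ±0.006 uncertainty band, but visible. On raw
(non-renormalized) series the full loop
simulate → write → read → fit returns the generating rate to 1e-8.

## Problem sizes

Simulation-based checks use 200 replicates of 20–24-point series (fits take
milliseconds) and RK4 cross-checks at step 1e-3 y over a 50-year horizon —
sizes chosen so the whole suite exercises every claim in seconds while the
Monte Carlo standard error on recovery rates stays well below the decision
margins.

## Known limitations

- The intercept is fixed; if the true `R5(0)` differs from 0.71 the rate
  estimate absorbs the discrepancy.
- The asymptotic standard error assumes independent homoscedastic
  residuals; the measured series' scatter is likely heteroscedastic
  (multiplicative), for which the weighted fit or bootstrap is the better
  uncertainty route.
- The rate-structure comparison evaluates only the second layer and holds
  `k₁` fixed at the surface fit; it ranks candidate `k₂` values, it does
  not estimate `k₂`.
- Deposition arithmetic assumes uniform bulk density over depth.
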
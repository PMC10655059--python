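# csmig

Compartment modelling of long-term ¹³⁷Cs vertical migration in soil.

After a fallout event, radiocaesium deposited on the ground migrates slowly
downward. Monitoring campaigns sample undisturbed soil in 5-cm slices down
to 30 cm, measure the ¹³⁷Cs mass activity `A_z` (Bq/kg) of each layer by
gamma spectroscopy, and track the *fractional contribution* of each layer

```
R_z = A_z / T,        T = A_5 + A_10 + A_15 + A_20 + A_25 + A_30
```

over decades. `csmig` is for radioecologists who analyse such series: it
turns profile tables into fraction vectors and areal inventories (kBq/m²),
models the migration, and estimates the transfer rate with uncertainty.

## The model

Each layer is a compartment in a catenary chain with first-order downward
transfer at rate `k` (y⁻¹):

```
dR_5/dt  = −k R_5
dR_z/dt  =  k R_{z−5} − k R_z        (z = 10, …, 30)
```

Because the `R_z` are ratios, radioactive decay cancels and is not part of
the dynamics. The closed-form solution is polynomial-times-exponential,

```
R_z(t) = e^{−kt} Σ_{j ≤ z} R_j(0) (kt)^m / m!     (m = hops from layer j to z),
```

and the chain with distinct rates `k_1 < k_2 < …` (the signature of
diffusion-dominated migration) has the Bateman-type solution, e.g. for the
second layer

```
R_10(t) = (k_1 R_5(0)/(k_2−k_1)) (e^{−k_1 t} − e^{−k_2 t}) + R_10(0) e^{−k_2 t}.
```

`k` is the single free parameter, estimated from the surface series by
least squares on `R_5(t) = R_5(0) e^{−kt}` with the intercept fixed at the
initial measured value (0.71 at the reference site). Derived quantities:
mean residence time `1/k` and mean migration velocity `thickness × k`.

## Worked example

Simulate a 24-point campaign (1.2–37 y after deposition, 10% measurement
noise) and refit the transfer rate:

```python
from csmig import SyntheticConfig, simulate_fraction_series, fit_k, r10_peak_time, PAPER_INIT

cfg = SyntheticConfig(seed=11, k_true=0.024)
series = simulate_fraction_series(cfg)
res = fit_k([fv.t for fv in series], [fv[0] for fv in series])
print(res.summary())
```

```
Surface-fraction exponential fit (fixed intercept)
==================================================
n points              24
fixed R5(0)           0.71
method                ols
k (y^-1)              0.0210
std err (y^-1)        0.0008
RSS                   0.0138606
residence time (y)    47.6
migration vel (cm/y)  0.105
```

The estimate (0.0210 y⁻¹) sits below the generating 0.024 y⁻¹: measured
fractions are ratios that sum to 1 while the model chain leaks below 30 cm,
which biases the fixed-intercept fit slightly low (see `docs/methods.md`);
with the raw surface series (`renormalize=False`) the fit recovers the
generating rate to 8 decimals. The residence time is the mean time ¹³⁷Cs
spends in the 0–5 cm layer; the velocity is the effective downward speed of
the activity front. The second layer peaks at
`r10_peak_time(PAPER_INIT, k)` — about 35–40 y after deposition depending
on the fitted rate.

The same pipeline from the shell:

```
csmig simulate --seed 11 --k 0.024 -o series.csv
csmig fit series.csv -o fit.json
csmig predict --k 0.024 --t-max 50 --dt 1 -o curves.csv
csmig compare series.csv --k1 0.024 --k2 0.025,0.030,0.035 -o ranking.csv
```

`compare` ranks the equal-rate chain against variants whose second rate is
higher (rates increasing with depth are expected if diffusion dominates);
on equal-rate-generated data the equal-rate candidate wins, and a +4%
second rate is nearly indistinguishable from it.

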
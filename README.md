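# pkautoinit

Automated, data-driven **initial estimates for population pharmacokinetic
(PopPK) base models**. Given a longitudinal concentration–time dataset in the
NONMEM/nlmixr2 column convention (`ID, TIME, AMT, RATE, EVID, CMT, DV`,
optional `ADDL/II`), the pipeline computes starting values for the structural
parameters (CL, V_d/V_c, K_a, and — for extended models — V_max, K_m, V_p, Q,
V_p2, Q_2), the residual-error magnitudes (σ_add, σ_prop) and the
inter-individual variability (ω²), without any prior information from the
modeler. It is aimed at pharmacometricians who want a reproducible starting
point for nonlinear mixed-effects estimation, including on sparse designs
where eyeballing a profile is not an option.

## How it works

**Part 1 — one-compartment parameters.** Three independent methods run on the
same prepared data (dose-annotated individual records plus naïve pooled,
dose-normalized, quantile-binned profiles over time after dose):

* *Adaptive single-point method.* Per subject, V_d = Dose/C₁ from the first
  post-dose sample when it falls within 20 % of the half-life (≈13 %
  eliminated, since 1 − e^(−ln2·0.2) ≈ 0.13), and
  CL = Dose/(C_ss,avg·τ) from steady-state peak/trough pairs with
  C_ss,avg = (C_ss,max + C_ss,min)/2; a missing extreme is reconstructed from
  C_ss,min = C_ss,max·e^(−k_e·τ) (IV). An extended phase fills gaps using
  t½ (V_d = CL·t½/ln 2), a C_max-based V_c with the accumulation ratio
  R_ac = 1/(1 − e^(−k_e·τ)), and K_a by Brent root-finding on the analytic
  oral concentration equations. Individual values are summarized by a
  0.05-trimmed geometric mean.
* *Naïve pooled NCA.* Linear-up/log-down trapezoidal AUC; λ_z by a best-fit
  log-linear regression over trailing windows (adjusted-R² criterion);
  CL = 1/AUC per unit dose (AUC_0–∞ single dose, AUC_0–τ multiple dose),
  V_z = CL/λ_z; K_a by the Wagner–Nelson fraction-absorbed method.
* *Graphic methods.* On pooled first-dose data: V_extrap = 1/Y-intercept of
  the extrapolated terminal line (IV), and the method of residuals
  (ln C_residual = ln C₀ − K_a·t) for oral K_a.

Every complete method set **and every cross-method hybrid** (CL, V, K_a picked
independently) is simulated on each subject's dosing schedule and scored by

rRMSE [%] = 100 · √( 1/n Σᵢ (predᵢ − obsᵢ)² / ((predᵢ + obsᵢ)/2)² )

The lowest-rRMSE candidate is the recommendation.

**Part 2 — parameter sweeping.** Holding the Part-1 outputs fixed, grids of
candidate values are simulated by ODE integration and scored by the same
rRMSE: K_m at 4:1 … 1:20 of C_max with V_max = CL·(K_m + C) for C at
0.05–0.75·C_max (35 nodes); V_p from V_c:V_p ratios 10:1 … 1:10 and Q at
0.25–2-fold CL for 2-/3-compartment models.

**Part 3 — statistical components.** Per-subject log-linear regression of the
last three terminal points gives σ_add = √Var(C_obs − C_pred) and
σ_prop = √Var(C_obs/C_pred − 1), summarized by a 0.05-trimmed mean; when the
data cannot support this, σ_add falls back to 20 % of the mean observed
concentration. ω² is initialized at the pragmatic default 0.1 for every
structural parameter.

## Worked example

```python
from pkautoinit import PKInitModel
from pkautoinit.fixtures import DesignSpec, generate_dataset
from pkautoinit.simulate import ModelSpec, StructuralParams

spec = DesignSpec(route="bolus", model=ModelSpec(route="bolus"),
                  true_params=StructuralParams(cl=2.0, vc=20.0),
                  n_subjects=6, dosing=(100.0, 24.0, 1), sampling="rich",
                  seed=1)
res = PKInitModel(generate_dataset(spec)).fit()
print(res.summary())
```

```
PK initial estimates
================================================================
route: bolus   subjects: 6   observations: 54
selected method: nca   rRMSE: 1.22e-14%
----------------------------------------------------------------
parameter            value    source
cl                       2    nca
v                       20    nca
t_half              6.9315    terminal fit
sigma_add=6.41e-17  sigma_prop=1.282e-16  (regression);  omega^2 defaults: cl=0.1, v=0.1
```

On this noise-free one-compartment cohort (true CL = 2 L/h, V = 20 L) all
three methods agree; pooled NCA is selected by the tie-break, the recovered
values match the generating parameters, the rRMSE of the winning candidate is
numerically zero, and the regression-based residual sigmas are zero because
the data carry no noise. The same objects work from the shell:

```bash
pkautoinit simulate --design semi_sparse --route oral --seed 42 --out data.csv
pkautoinit run data.csv --model 1cmpt --model 2cmpt --out report.json
```

`run` exits with status 2 when no complete candidate parameter set can be
formed, printing per-method diagnostics.

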
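# Methods notes

This note documents the modelling assumptions, numerical choices and known
limitations of the pkautoinit pipeline, in the order the pipeline runs.

## Data preparation

Input events are parsed from delimited text in the NONMEM column convention;
`ADDL`/`II` dose series are expanded into explicit dose records. Route
detection: `RATE > 0` (or `DUR > 0`) → infusion; a dose compartment differing
from the modal observation compartment (classic depot layout) or an explicit
`ROUTE` column → extravascular; otherwise bolus. Subjects without dose
records are dropped with a warning; observations preceding any dose are
excluded from time-after-dose (TAD) analyses.

Steady state is flagged when the trailing run of doses is *regular* — every
inter-dose interval and every amount within ±25 % of the run's respective
median (both read as regimen-regularity conditions) — and the run covers at
least five doses or, once a half-life estimate exists, at least five
half-lives. The flag is recomputed lazily after the terminal fit because the
half-life is not known at annotation time. Note the five-dose arm is a
pragmatic rule, not a kinetic guarantee: five doses of a drug with
k_e·τ ≪ 1 are well short of plateau, and the steady-state CL formula then
inherits that bias.

Naïve pooling divides the *unique* TADs into at most `n_bins` (default 10)
quantile groups (type-7 quantile edges; a TAD tied with an interior edge goes
to the lower bin) and represents each bin by the median TAD and median
dose-normalized concentration. Three groups are pooled: first-dose,
multi-dose and mixed. Concentrations are normalized by the governing dose
amount, so pooled profiles are per unit dose throughout; zero/missing
concentrations are excluded from log-scale operations but retained for rRMSE
scoring.

## Terminal phase

λ_z is fitted by enumerating trailing windows of k = 3 … n post-peak bins of
the log-profile and keeping the negative-slope window with the highest
adjusted R²; near-ties (within 1e-9) prefer the larger window for a stabler
extrapolation. For extravascular data the absorption-peak bin is excluded —
unless that would leave fewer than three bins (very sparse oral designs), in
which case the peak is kept and the fit is flagged `includes_peak`. Such a
fit is treated as a rough half-life only: the single-point extended phase may
use it, but NCA declines it, because AUC extrapolation and V_z require a
clean terminal slope. This is what makes the adaptive single-point method the
only complete candidate on sparse multi-dose oral designs.

The pipeline fits the first-dose pooled group when it supports a fit, else
the mixed group: first-dose data are uncontaminated by accumulation.

## Adaptive single-point method

* First-point V_d (IV only) requires TAD ≤ 0.2·t½; the bias of Dose/C₁ is
  exactly e^(k_e·t₁), ≤ ~15 % at the window edge and ~13 % of the dose
  eliminated, which is the rationale for the 20 % rule.
* Steady-state CL uses the most recent qualifying interval per subject. With
  both extremes observed, CL = Dose/(C_ss,avg·τ). With a single sample the
  point is classified as C_ss,max when TAD ≤ τ/2 and C_ss,min otherwise (an
  isolated early sample reads as a peak, a late one as a trough), and the
  missing extreme is reconstructed by mono-exponential decay over the
  interval (bolus) or over τ − t_inf (infusion); extravascular intervals are
  ineligible for single-extreme completion. The (max+min)/2 average is exact
  only as k_e·τ → 0; its relative bias is k_e·τ(1+e^(−k_e·τ))/(2(1−e^(−k_e·τ))) − 1,
  about +2 % at k_e·τ = 0.5.
* Extended phase: V_d = CL·t½/ln 2 when CL is known; CL = V_d·ln 2/t½ when
  only V_d is known (the inverse relation — the only data-free completion);
  when both are missing, V_c from the C_max approach substitutes for V_d and
  CL = k_e·V_c. K_a solves the analytic single- or steady-state multiple-dose
  oral equation by Brent's method on (k_e·(1+1e-6), 1000], tolerance 1e-8 on
  K_a; the lower bracket guard avoids the k_a = k_e singularity. Multiple
  absorption-phase observations per subject are combined by a per-subject
  geometric mean before the population 0.05-trimmed geometric mean
  (floor(n·trim/2) values dropped at each end).

## NCA

AUC uses the linear-up/log-down trapezoid. Pooled bins rarely start at
TAD 0, so a time-zero anchor is prepended: bolus profiles back-extrapolate to
exp(β₀) from the terminal fit (standard NCA practice); first-dose
infusion/oral profiles start at zero; multi-dose non-bolus profiles start at
the trough C(τ) obtained by log-down extension — continuity of the
steady-state profile. AUC_0–τ truncates or extends the profile at τ = the
most frequent dosing interval; AUC_0–∞ adds C_last/λ_z, and an extrapolated
fraction ≥ 0.5 raises a warning but does not invalidate the result.
Wagner–Nelson uses the plain linear trapezoid for the cumulative AUC (as the
method is classically written), the fraction remaining 1 − F(t), and a
log-linear regression over absorption-phase bins with positive remainder; the
synthetic origin point carries no information and is excluded.

## Graphic methods

First-dose pooled data only. IV: V_extrap = 1/exp(β₀) per unit dose,
CL = λ_z·V_extrap. Oral: residuals C_extrap − C over bins strictly before
the peak bin (the peak itself has zero residual by construction);
non-positive residuals are dropped and fewer than two survivors leave K_a
unavailable. V_d ≈ Dose/C_extrap(0) assumes K_a ≫ K_e; the bias shrinks as
the separation grows (asymptotically exact, verified at K_a/K_e = 100).
Flip-flop kinetics are not detected — a known limitation: when absorption is
slower than elimination the fitted λ_z is actually K_a.

## Simulation engines

Linear one-compartment predictions use closed forms (bolus, zero-order
infusion, first-order absorption) with multiple dosing by superposition; the
k_a = k_e singularity switches to the t·k_e·e^(−k_e t) limiting kernel.
Everything else integrates the 1/2/3-compartment ODEs (linear or
Michaelis–Menten elimination, C' with CL·C replaced by V_max·C/(K_m+C))
piecewise between dose events with LSODA at rtol 1e-8 / atol 1e-10 — sweep
candidates with large V_max and small K_m are stiff. Observation times are
read from dense output; a concentration at a bolus instant is post-dose, in
both engines. An integration failure marks the sweep candidate failed
(infinite rRMSE) rather than aborting.

## Selection and sweeping

Candidates are scored on *all individual-level observations* (not pooled
bins) with the pairwise-mean rRMSE, which is bounded by 200 % and symmetric
in prediction and observation. Alternative metrics (observed-mean rRMSE,
MAPE) are available behind `PipelineConfig.metric` but are not the default:
they penalize bias more strongly and tend to push nonlinear parameters
upward. Ties within 1e-9 prefer NCA, then single-point, then graphical, then
hybrids — on rich data where methods agree, the NCA values are reported.

Sweep grids: K_m/C_max ratio ladder 4, 2, 1, 1/2, 1/4, 1/10, 1/20 (printed
endpoints 4:1 and 1:20 with an interior roughly log-spaced ladder, all
configurable); C fractions 0.05–0.75 of the maximum *observed* concentration;
V_c:V_p ratios 10:1 … 1:10 and Q folds 0.25–2 of CL, doubled for the second
peripheral compartment in three-compartment grids. The V_c axis carries up to
two candidates: the selected Part-1 V and the single-point extended-phase
V_c. K_a is re-used unchanged as a non-test parameter in extravascular
sweeps. Ties break toward the smaller grid index, so sweep output is
deterministic. No continuous refinement follows the grid minimum.

## Error model and IIV

The per-subject terminal regression uses the last three positive points by
default; with three points and two fitted coefficients, the residual variance
(computed with n−1) has a single degree of freedom, so the per-subject sigmas
are noisy and biased — the cross-subject 0.05-trimmed mean (2.5 % per tail)
is a stabilizer, not a cure, and the Monte-Carlo test asserts only
order-of-magnitude agreement. Regression sigmas are computed on each
subject's last qualifying stretch of observations regardless of occasion.
The fallback (σ_add = 20 %·mean DV, σ_prop = 0.2) is taken exactly when the
regression path signals insufficiency — the two paths never mix. ω² = 0.1
for every structural parameter unless overridden.

## Synthetic designs

The fixture generator draws per-subject parameters lognormally
(variance ω² on the log scale), simulates with the engines above, applies
combined error y = f·(1+ε_prop) + ε_add and truncates negatives at zero. All
randomness derives from the design seed. Templates: *rich*
(0.25, 0.5, 1, 2, 4, 6, 8, 12, 24 h post dose — a conventional dense
schedule, configurable), *semi-sparse* (three round-robin groups with sample
pairs (2, 8), (4, 12), (6, 24) h within one interval after multiple doses —
the pairing of the six published times into groups is this package's choice),
*sparse1* (2 h [oral only], 20, 24 h after the last of multiple doses) and
*sparse2* (the same times after a single dose). Default dosing is 100 mg
q24h; typical parameters CL = 2–4 L/h, V = 20–70 L, K_a = 1 /h — mid-range
small-molecule values.

What the fixtures do **not** emulate: below-quantification censoring,
covariate effects, inter-occasion variability, lag times or transit
absorption, and dropout. Passing recovery tests therefore demonstrates
correctness of the estimators under the stated model, not robustness to
real-data pathologies.

## Test and experiment scale

Recovery and sweep experiments in the test-suite and acceptance script use
small cohorts (4–30 subjects) and the 2-compartment/MM grids (28–56 nodes);
these sizes were chosen so the entire suite runs in seconds while every
experiment still has a unique, well-identified optimum. The three-compartment
grid (1568 nodes) is validated for construction and by its degenerate
reductions rather than by full sweeps.

## Known limitations

* One-compartment linear assumptions underlie all Part-1 methods; outputs on
  multi-compartment or nonlinear data are starting values, not estimates.
* The steady-state CL formula and the first-point V_d both carry documented
  biases that grow with k_e·τ and the sampling delay respectively.
* λ_z on sparse oral data may include the absorption peak (flagged); the
  resulting half-life is rough and NCA refuses it.
* Flip-flop kinetics, very long (months) or very short (<1 h) half-lives are
  untested regimes.
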
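# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `meromipd`, in the spirit of a package methods appendix. It
states no empirical number that the test suite or `scripts/acceptance.py`
does not itself compute.

## Structural model and its solution

Drug amounts in a linear mammillary model with central volume Vc, clearance
CL and peripheral exchanges (Q₂, Vp₂), (Q₃, Vp₃) follow x′ = A x + u(t), with
u(t) the summed zero-order infusion rate into the central compartment. Dose
starts/ends and requested times partition time into segments of constant
input; within each segment the exact update is x(t+Δ) = x_p + e^{AΔ}(x₀ −
x_p) with x_p = −A⁻¹u. One- and two-compartment models use explicit
scalar/spectral forms (the 2×2 case via its eigenvalue pair −α, −β and
spectral projectors, vectorised across parameter batches — the same code
path serves single fits, VPC replicate batches and grid searches); the
three-compartment model uses `scipy.linalg.expm`, which remains stable if
eigenvalues (nearly) coincide, and the two-compartment path falls back to
`expm` when its discriminant underflows. Negative prediction times are
rejected; times before the first dose yield exactly zero.

`predict_concentration_ode` integrates the same system segment-by-segment
with DOP853 at rtol 1e-12 / atol 1e-13, carrying a cumulative-elimination
state for mass-balance checks. It exists purely as an independent oracle:
tests compare the two paths on randomized parameter/dose draws and require
≤1e-6 relative agreement wherever the concentration exceeds 1e-6 of the
profile maximum — below that the comparison measures the integrator's
absolute-tolerance floor, not the analytic solution.

## Model specifications

A `ModelSpec` carries typical values θ, covariate relations, the
between-subject covariance Ω of log-scale random effects η (individual
parameter pᵢ = θᵢ · covariate factors · e^{ηᵢ}, the log-normal NONMEM
convention), and a residual model with variance σ_add² + (σ_prop·f)².
Covariate relation forms: linear-proportional (x/ref), power ((x/ref)^k),
exponential, additive shift, and categorical factor. Ω must be symmetric
PSD; relation targets must exist in θ.

**Bundled library.** The 18 literature-derived adult-ICU meropenem configs
carry the published typical clearances/volumes and covariate *names*. The
source publications' exact covariate equations and variance components are
not reproduced here; the configs default to linear-proportional scaling on
the renal marker with the source population's median renal value as
reference, placeholder weight/albumin/age/APACHE/CRP/RRT forms, Ω = diag(0.3²,
0.25²) on (CL, Vc) and combined residual error (20% proportional, 0.5 mg/L
additive). Every config says so in its `source_note`. Two sources print no
renal median; 80 mL/min is assumed and noted. A published model with an
epithelial-lining-fluid compartment is encoded as a plasma-side
three-compartment model. Consequently the bundled configs support
*structural* and *directional* analyses (compartment counts, renal
sensitivity, regimen simulation shape); quantitative claims in the tests
always use fully specified synthetic models.

## MAP Bayesian forecasting

`PopPKModel.fit()` minimises OFV(η) = Σⱼ[(c_j − f_j(η))²/σ²ⱼ + ln σ²ⱼ] +
ηᵀΩ⁻¹η — −2·log posterior up to a constant — over the support observations
(chronologically first k usable samples by default, configurable by label).
BLQ samples (< 0.174 mg/L) are never support and are excluded from PE%
pooling. A singular Ω falls back to a pseudo-inverse with a warning.

The optimiser advances five starts (η = 0 plus four seeded N(0, 0.5²)
perturbations) *in parallel* by damped Newton steps on batched
finite-difference gradients/Hessians (step capped at norm 5; non-finite
trial objectives treated as +∞; only improving steps accepted, so the
incumbent objective trace is non-increasing), then polishes the best point
with L-BFGS-B on a batched FD gradient. Tolerance 1e-8 on the objective,
2000-evaluation budget, deterministic given the seed. Correctness is pinned
against an exhaustive 1-D grid search (step 1e-4) and scipy Nelder-Mead
refinement in the tests. The posterior covariance reported by
`MapResults.cov_params()` is 2H⁻¹ from a central-difference Hessian at η̂.

Two behaviours worth knowing:

- **Shrinkage at supports.** With realistic residual error (~20%
  proportional) the posterior mode deliberately leaves sub-σ residuals at
  the support points rather than chase noise; the "individual prediction is
  closer to the support than the population prediction" property is
  therefore guaranteed only in likelihood-dominated regimes, where the test
  suite asserts it (5% residual error, ≥95% of support points over 200
  seeded draws).
- **Scale misspecification is MAP-correctable in principle.** A pure
  clearance halving can be compensated by η_CL ≈ ln 2 when the support
  contains a trough; what keeps the halved model failing the ±30% IQR rule
  at k = 2 in the acceptance run is the prior pull (ln 2 ≈ 2.3 prior SDs),
  patients whose troughs are BLQ (leaving only weakly CL-informative
  supports), and the heteroscedastic weighting of the inflated predictions.

## Validation metrics

PE% = (ĉ − c_obs)/c_obs × 100 (signed); RMSE = √(mean PE%²); a model/k cell
is "acceptable" when the PE% interquartile range lies within ±30%
(closed interval; quartiles by linear interpolation between order
statistics, the numpy default — documented because decisions near the
boundary depend on it). PE pooling is per-observation across patients;
±20% is drawn as a reference line in the box plot helper. Evaluation
scopes: `subsequent` (non-support observations, the forecasting read-out
and default), `all`, and `holdout` (observations beyond the first three
usable ones — the *same* set for every k ≤ 3 and therefore the right
comparator when studying how forecasts improve with the number of support
samples; the subsequent-scope sets are non-nested across k and their IQR
widths can permute by tenths of a percentage point from sampling noise).
At 500 virtual patients the improvement is decisive from k = 0 to k = 1 and
marginal beyond — consistent with the clinical reading that the first
trough carries most of the individualisation information and two samples
(trough + peak) add volume information.

## Visual predictive check

Each of the (default) 500 replicates redraws η per patient from Ω and
residual noise per observation from σ at the original times, doses and
covariates, with the same non-negativity floor the observation model uses.
Observations are binned on **time after the end of the most recent
infusion**; default bins (0–1], (1–6], (6–15] h separate peaks,
intermediate samples and troughs for intermittent q8h/q12h dosing. Per bin
and stratum the observed 5th/50th/95th percentiles are compared with the
across-replicate 95% interval of the same within-replicate percentile; an
observed line above its band flags model underprediction, below it
overprediction. Bins with < 2 observations are flagged unstable, never
silently dropped; an observation assignable to no bin is an error. For
coverage studies `meromipd.cohort.day2_sampling_bins()` provides 40 fine
bins aligned with the day-2 sampling windows so that "fraction of bins
covered" has real granularity; per-bin coverage of a calibrated 95% band is
~95% and misses are positively correlated across bins (shared cohort etas),
so seed-level variation of a few bins is expected.

## Typical-patient simulation

Three archetypes of the standard septic ICU patient (male, 55 y, 80 kg TBW,
70 kg IBW, 180 cm, albumin 25 g/L, APACHE II 24, CRP 194.5 mg/L — the CRP
is the study-cohort median, included so that every bundled model resolves)
differ only in renal function: impaired 20, normal 100, augmented 200
mL/min. The archetype writes its renal value to *every* renal marker a
model may read (CG, CKD-EPI, MDRD) and back-derives serum creatinine by
inverting the CG equation, so creatinine-parameterised models respond to
the archetype too; supplying the renal value directly was chosen over
deriving it from a fixed creatinine because the two cannot be reconciled
simultaneously for all three archetypes. Profiles are population-typical
(η = 0, no residual noise) for 1000 mg q8h infused over 0.5 h on a 0.05-h
grid augmented with the exact infusion-end instants; the steady-state
window is 30–40 h (from the fourth dose at 24 h), summarised by C_max and
C_min. Models without renal covariates produce identical rows across
archetypes and are flagged.

## Synthetic cohort generator

The generator emulates a 20-patient ICU day-2 TDM study: covariate
marginals are scaled-beta distributions fitted *exactly* (via the Beta
quantile function) to published (median, min, max) summaries — age 64.5
(56–70) y, weight 80 (40.4–100) kg, height 175 (155–195) cm, creatinine 108
(33–464) µmol/L, albumin 25 (12–38) g/L, APACHE II 22.5 (9–33), CRP 194.5
(16–495) mg/L — with 80% male, 30% RRT, independent covariates except the
deterministic renal couplings (CG/CKD-EPI/MDRD computed from the sampled
demographics). Regimens are drawn from {1 g q12h, 1 g q8h, 2 g q12h}
(2–4 g/day, 0.5-h infusions, 48-h horizon); the five samples bracket the
24-h dose with uniform jitter in the stated windows (trough and peak 15–30
min, ±15 min on the +1 h/+3 h draws — nominal clock times scatter in
practice); per-sample retention 0.86 reproduces 86 samples per 20 patients
in expectation. Observations are prediction × residual noise, floored at
zero, BLQ-flagged below 0.174 mg/L (the value is retained with the flag,
never dropped). True etas are returned for recovery and calibration tests.

**Generator model** (the study conditions for all pipeline-level tests):
two compartments, CL 10 L/h × (CRCL/80)^0.75, Vc 12 L × (TBW/70), Q 15 L/h,
Vp 12 L; Ω = diag(0.30², 0.25²) on (CL, Vc); combined residual 20%
proportional + 0.1 mg/L additive. These sit at the centre of published
adult-ICU meropenem estimates (typical CL ≈ 5–17 L/h, Vss ≈ 16–35 L,
BSV on CL commonly 25–45%, proportional residual error ~15–30%) and were
fixed before any pipeline result was computed.

What the generator does **not** emulate: inter-occasion variability,
time-varying covariates or intra-dialysis clearance changes (the RRT flag
is recorded for stratification; an optional RRT clearance factor defaults
to off because no effect size is assumed), correlated covariates beyond
the renal couplings, and the bimodal concentration split reported in some
real ICU cohorts. Passing tests therefore demonstrate the *pipeline's*
correctness and calibration under its own assumptions, not the clinical
performance of any published model on real patients.

## Datasets and problem sizes

Datasets are NONMEM-style CSVs (ID, TIME, AMT, RATE, DV, EVID, MDV plus BLQ,
LABEL and covariate columns; missing DV as "."; 10-significant-digit
formatting makes write→read→write byte-stable). Pipeline-scale runs use 500
virtual patients, 500 VPC replicates and 100 oracle cases per compartment
count; these sizes give stable quartiles and percentile bands while keeping
the full suite and the acceptance script each within a few minutes on one
CPU. All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); fits are deterministic given the seed.
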
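# Methods

## Structural models

All models are linear mammillary systems solved in mg / L / h with
concentrations reported in ng/mL (central amount / V1 × 1000). Supported
absorption inputs: intravenous bolus; first-order depot; two parallel
first-order depots receiving fractions `frac1` and `1−frac1` of the
bioavailable dose (rates `ka1 ≥ ka2`, the ordering enforced for
identifiability); a transit chain; and a zero-order release window
followed by first-order uptake. Optional features:

- **Enterohepatic recirculation (EHC).** A fraction `f_bile` of central
  elimination accumulates in a gallbladder compartment; the gallbladder
  stays shut until `t_empty` hours after the most recent dose and then
  empties into the absorption depot at first-order rate `k_bile`. This is
  the standard gallbladder-loop construction; the valve switch is a
  segment boundary for the integrator, never a discontinuity inside a
  step. Conservation (recycled mass ≤ f_bile × cumulative hepatic
  elimination) is asserted in tests via bookkeeping states.
- **Exponential dose effect on F.** `F_eff = F · exp(−θ_dose (D − D_ref))`,
  normalized so `F_eff = F` at the reference dose; values above 1 are
  clamped with a warning.
- **Transit absorption.** `n_transit + 1` series compartments all at rate
  `ktr = (n_transit + 1)/MTT`, the last acting as the absorption depot,
  so the chain's mean transit time equals MTT exactly. `n_transit` is
  fixed per preset (default 3), not estimated.

**Numerics.** The reference path integrates with LSODA at
rtol 1e−10 / atol 1e−12; doses, zero-order release windows and
gallbladder openings restart the integration at exact event times. The
tolerances are set so that the solution matches textbook closed forms to
better than 1e−6 max relative error over 0–120 h (measured ~1e−7); with
the looser 1e−8/1e−10 the decayed tail drifts to ~6e−6, which would
violate that bound. For feature-free structures with instantaneous doses
a matrix-exponential (eigendecomposition) path gives the exact solution
and is used automatically inside the likelihood, where it is orders of
magnitude faster; the two paths are cross-checked in tests, and the
textbook closed forms used as oracles are written independently from the
printed formulas (Bateman equation with its ka = ke limiting form,
mono/biexponential iv disposition via the quadratic-root
parameterization).

## Population layer

Strain covariate effects are multiplicative fold-changes on typical
parameters, matching how such effects are reported ("x-fold higher CL").
"0.71-fold lower F" is read as F × 0.71, not F reduced by 71%; both
readings are expressible in configuration, and the presets use the ×
reading consistently. Matched effects are applied in sorted order so the
result is bitwise order-independent. Between-subject variability is
lognormal (`θ_i = θ_pop · e^η`, `η ~ N(0, ω²)`), preserving medians;
residual error is combined proportional + additive
(`y = c(1+ε_p) + ε_a`), with negative observations floored at zero and
flagged.

## Estimation

Naive-pooled maximum likelihood: no random effects enter the likelihood
(BSV exists only in the data generator), so animals sharing strain,
dosing and sampling schedule have identical predictions and the
objective caches one profile per such group. The OFV is
−2 Σ log φ(y; pred, σ(pred)) with σ² = (σ_prop·pred)² + σ_add²; a purely
proportional error model with a zero prediction raises an error
instructing an additive floor. Positive parameters are estimated on the
log scale (unit-bounded ones with an upper bound at 1) by L-BFGS-B with
optional seeded multi-start jitter (default 5 starts; the pipeline uses
2 with preset initial values). Relative standard errors come from the
central finite-difference Hessian of the OFV (cov = 2H⁻¹; on the log
scale the SE of the log is the relative SE); a singular Hessian yields
missing RSEs rather than guesses.

Nested models are compared by dOFV against χ² quantiles; one extra
parameter is significant at p < 0.01 when dOFV < −6.64. In benchmark and
pipeline use the extended model is initialized at the base optimum, which
also guarantees the nesting monotonicity (OFV never increases with an
added parameter).

Gallbladder parameters (`f_bile`, `k_bile`, `t_empty`) are held at preset
values during fitting: emptying time and rate are weakly identified from
sparse serial sampling, and fixing poorly-identified recirculation
parameters is standard practice.

With proportional error the pooled-ML optimum is not exactly the
generating truth on noise-free data (the prediction-dependent variance
rewards slightly smaller predictions); the exact self-consistency check
in the tests therefore uses a constant (additive) error model, where the
optimum coincides with truth and the OFV sits at the error-model floor.

## Translation to human

Allometric scaling multiplies clearance-like symbols (CL, Q) by
(BWT/30 g)^0.75 and volume-like symbols (V1, V2) by (BWT/30 g)^1.0. Rate
constants, fractions, F and MTT are not scaled — the scaling law names
only clearances and volumes. Scaling always starts from the mouse
reference; a second scaling of an already-scaled parameter set raises.
Only typical values cross species: no between- or within-subject
variability is extrapolated (asserted structurally — the mouse-scaled
simulation path refuses BSV or residual-error models).

Simplification for translation removes EHC and the dose effect on F;
the caller re-fits before scaling. The fisogatinib presets additionally
change the disposition structure between variants (one-compartment final,
two-compartment optimized), encoded as printed without inferring why.

Tablet dissolution: a zero-order release of the dose over the in-vitro
>95% dissolution time (0.75 h lorlatinib and brigatinib, 0.5 h
ribociclib), or, where the transit absorption makes a release window
unavailable (fisogatinib), +0.375 h on MTT. The printed dissolution time
is used directly as the release duration. Ionization correction
(fisogatinib, basic pKa 3.79): F_human = F_mouse · fBH⁺(pH 1.75)/fBH⁺(pH 3.5)
≈ F_mouse × 1.50, clamped at 1 with a warning; applied in the optimized
(translation) variant only, reproducing the partially-corrected pathway.

## Virtual humans and exposure

Weights are N(70, 17) kg truncated at 50 kg by rejection (clipping would
pile mass at the floor); the truncated mean ≈ 73.9 kg is checked against
the numerical truncated-normal expectation. The extrapolated path scales
each individual to their own weight and simulates the typical curve; the
reference path retains the reference model's BSV/residual error and
supports replicated simulation (500 × 50 by default in the comparisons;
the analysis driver uses 100 replicates without residual error so the
terminal-slope regression stays stable — a problem-size choice, the full
500 × 50 path is exercised by the same code). One fixed population per
seed is shared across replicates; replicates differ only through BSV and
residual error. The default grid is 0–120 h at 0.1 h (0–24 h for
fisogatinib comparisons); 80% prediction bands are the pointwise
10th/90th percentiles with linear interpolation.

AUC_inf is the trapezoidal integral plus C_last/λ_z, with λ_z from the
best log-linear fit (highest adjusted R²) over the final 3–5 positive
points; a non-positive terminal slope is an error naming the grid end.
Grid integration plus λ_z was chosen over model-analytic integration and
is validated against the F·D/CL identity to <0.5%. Cmax is the gridded
maximum. Fold-change ratios use inclusive 0.5/2.0 endpoints (a 2.0-fold
ratio passes, 2.1 fails); rounding to one decimal happens only at
presentation.

## Synthetic studies

The generator emulates the four two-strain mouse datasets: 94 (16 iv),
61, 71 and 49 animals; sampling schedules chosen so observation totals
match the reported 658 (112 iv) and 366 exactly and approximate 414 and
270. Bodyweights are N(30 g, 2 g) truncated at 20 g (only the 30 g median
is reported). Doses are fixed nominal mg per animal (0.3/0.75–1.5/2.25/1.5
mg, equivalent to typical mg/kg gavage doses at 30 g); fixed nominal
dosing keeps prediction groups well-defined for the pooled likelihood
and matches common gavage practice. Brigatinib uses two dose levels so
the exponential dose effect on F is identifiable. Default residual error
is 15% proportional + 1 ng/mL additive (≈ LLOQ/2 at a 2 ng/mL LLOQ);
default BSV ω² = 0.1 on CL and 0.05 on V1. Mouse typical parameter
values in the presets are synthetic stand-ins at plausible mouse scale —
the original per-study estimates are not published in machine-readable
form — while covariate folds, doses, dissolution times and ionization
inputs are the reported values.

What passing tests on these studies do show: the solver, likelihood,
LRT rule, scaling and corrections, simulation and comparison machinery
are internally consistent and statistically calibrated. What they do not
show: agreement with the original estimates or with clinical exposure,
which would require the unpublished mouse estimates and the externally
published human comparator models (supplied by the user via
`ReferenceSpec`).

Benchmark designs: the fold-recovery benchmark uses the two-strain
design at the lorlatinib scale (40/strain oral + 8/strain iv, 7 serial
samples, 15% proportional error, true CL fold 1.34) with one-compartment
first-order kinetics — the benchmark pins the design and effect size;
the full dual-absorption structure is not needed to measure fold
recovery. Its sampling schedule (0.25–8 h) matches the benchmark
half-life (~1.9 h) so every sample sits well above the assay floor;
sampling many half-lives past extinction would re-introduce the floored
observations the error model does not describe. The null-calibration
benchmark uses 16/strain oral-only studies with F fixed (not
identifiable without iv data) over 500 replicates.

## Interfaces and provenance

Datasets follow NONMEM column conventions (ID/TIME/AMT/DV/EVID plus
STRAIN/BWT/DOSEGRP/ROUTE/BLQ), hours / mg / ng/mL fixed at the
interface. Below-LLOQ observations can be kept, dropped, or substituted
at LLOQ/2 on read. The pipeline stages (fit → simplify/re-fit → scale →
correct → simulate → compare) are plain library functions orchestrated
by `run_pipeline`; the numbered `analysis/` scripts are the user-facing
drivers, so no console-script CLI is shipped. Every report embeds the
seed, a config hash and the package version; a stage failure names the
stage and retains partial outputs. On-disk simulation curves are thinned
to ~120 points per individual; metrics always use the full-resolution
grid in memory.

## Known limitations

- Naive-pooled estimation ignores within-animal correlation; standard
  errors are approximate and no NLME (FOCE/SAEM) replication is claimed.
- EHC gallbladder parameters are fixed, not estimated.
- Single-dose regimens only; no steady-state, no inter-occasion
  variability, no continuous covariates beyond bodyweight.
- The 0.5–2-fold verdicts in the bundled analysis are against a
  synthetic comparator and demonstrate the machinery, not clinical
  accuracy.
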
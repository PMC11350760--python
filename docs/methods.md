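# Methods

## Structural and statistical model

Meropenem disposition is modelled as a linear two-compartment system with
zero-order infusion into the central compartment and first-order
elimination from it. With micro-constants k10 = CL/V1, k12 = Q/V1,
k21 = Q/V2, the hybrid rate constants λ1 > λ2 are the roots of
λ² − (k10+k12+k21)λ + k10·k21 = 0, and the central concentration under a
running infusion of rate R is the biexponential

    C(t) = (R/V1) · [ c1 (1 − e^{−λ1 t})/λ1 + c2 (1 − e^{−λ2 t})/λ2 ],
    c1 = (λ1 − k21)/(λ1 − λ2),  c2 = (k21 − λ2)/(λ1 − λ2).

Every dosing schedule — including a continuous infusion, encoded as
`infusion_duration == interval` — is the superposition of "infusion on"
terms at each dose start minus matching terms at each infusion end. The
solution is analytic (no truncation error); an independent stiff-ODE
integration is used in the test suite as an oracle, agreeing to < 0.1 %.

Steady state is computed in closed form by summing the dose superposition
as a geometric series per eigenvalue, written with only decaying
exponentials for overflow safety. A simulation route (≥ 10 terminal
half-lives of doses, last interval kept) cross-checks the closed form and
serves as the automatic fallback when the eigenvalue gap collapses; the
repeated-root limit form of the biexponential (used when
|λ1 − λ2| < 1e−10·λ1) covers the transient solution in that regime.

### Population model

Fixed effects and variability (the packaged default profile):
CL = 4.22·(eGFR/26.1)^0.25 L/h, Q = 7.84 L/h, V1 = 14.82 L,
V2 = 11.75 L; log-normal inter-individual variability on CL/V1/V2 with
log-scale SDs ω = 0.2675/0.2733/0.5705 (Q carries none and is fixed);
proportional residual error with SD σ = 0.1839. eGFR (mL/min) is the
renal covariate; when not supplied directly it is computed by the
Japanese 3-variable creatinine equation 194·SCr^−1.094·age^−0.287
(×0.739 for women), used unindexed — the flat 0.25 clearance exponent
makes downstream results insensitive to the indexing convention, and a
direct-eGFR input path bypasses the equation entirely.

## MAP (empirical Bayes) estimation

Individual η = (η_CL, η_V1, η_V2) minimize

    J(η) = Σ_j [ (y_j − f_j)²/(σ f_j)² + ln (σ f_j)² ] + Σ_k η_k²/ω_k²,

the NONMEM-style POSTHOC objective: proportional residual variance built
from the model prediction f_j (not the observation — this choice changes
estimates and is therefore stated explicitly), plus the log-variance
term, plus the Gaussian prior. Only systemic/pre-filter records with
positive concentrations are fitted; zero-concentration records are
logged and skipped (the proportional model is undefined at zero).
Optimization is Nelder–Mead from η = 0 with four additional seeded
starts (parameter tolerance 1e−9); non-convergence is flagged on the
result rather than raised. An empty observation set returns the prior
mode.

**Shrinkage.** A MAP estimate is pulled toward the prior mode by an
amount set by the data's information content. With the nine-point
schedule, η_V2 (ω = 0.5705, weakly informed by the central
concentration profile) shrinks strongly: noise-free round-trip
experiments show per-patient displacements up to several tenths for
large prior draws, even though the optimizer verifiably finds the
objective's minimum (J(η̂) < J(η_true) in every such case). Cohort-level
bias is small (mean η error per component well under 0.05 over 50 noisy
simulated patients). Consumers should read individual η̂ as posterior
modes, not unbiased recoveries — this is a property of the estimator,
not a defect of the implementation, and the test suite documents it.

Validation metrics on pooled (observed, predicted) pairs: R² against the
identity line, root-mean-squared error, mean absolute percentage error
(relative to the observation), and the fraction of prediction−observation
differences within their own mean ± 2 SD.

## PK/PD targets

%fT>MIC is the percentage of the steady-state dosing interval with free
concentration strictly above the threshold, computed on a piecewise-linear
profile with interpolated crossings. Default grid resolution is 0.05 h
(< 0.7 % of the shortest interval; refinement to 0.01 h moves %fT by
< 0.5 points). Free fraction fu defaults to 1.0 (meropenem protein
binding < 2 %; total plasma concentration treated as free), configurable.
The four standard targets are 40 %/100 % of the interval above 1× or
4×MIC; the toxicity flag marks steady-state troughs (end-of-interval,
pre-dose) strictly above 45 mg/L. %TAM tables default to the
steady-state interval; a transient 0–24 h window is available via
`window_profile` for summaries anchored to the sampling horizon.

## CVVH clearance

CL_CVVH = (Cti − Cto)/Cti · (QT − QF) + QF, averaged over the available
(typically three peak-time) pairs per patient. QT is not defined by the
clinical flow sheet this formula is usually quoted with; the default
takes QT = QB in L/h (150 mL/min → 9 L/h), overridable in
`FlowSettings`. Note the formula's nominal range is [QF, QT] for
0 ≤ Cto ≤ Cti, yet clinically reported per-patient clearances (≈ 0.2–2
L/h at QF = 1–2 L/h) fall partly below QF — implying Cto > Cti pairs.
The implementation therefore flags (warns on) negative extraction but
does not reject it, and the synthetic generator inverts the formula
exactly for any target in (0, QT].

## Monte Carlo PTA

5000 virtual subjects per regimen by default: covariates fixed at the
cohort means (age 63 y, weight 70.2 kg, SCr 3.4 mg/dL — weight enters no
model term and is carried as description only), sex alternating for an
exact 1:1 split, η i.i.d. from the log-normal prior, no residual error
on simulated profiles (standard PTA practice). Each subject's
steady-state interval is evaluated against the target per MIC; PTA ≥ 90 %
is the desirability cutoff. One master seed spawns per-regimen
substreams; all outputs embed the seed. For continuous infusions the
aggressive-target PTA reduces to the closed-form log-normal tail
P(CL < rate/(4·MIC)), which the test suite uses as an oracle (agreement
within 1 percentage point at n = 5000). Per-patient counterfactual
simulation re-predicts MAP-fitted patients under another regimen
(e.g. 3 g/24 h continuous) and reports attainment per MIC plus predicted
Css = (daily dose/24)/CL.

## Synthetic cohort generator

Stands in for the unreleased clinical dataset. Per patient: age
~ N(63, 13²) truncated to 15–100 y; weight ~ N(70.2, 14.1²) truncated
above 30 kg; SCr log-normal moment-matched to mean 3.4 / SD 3.2 mg/dL
(the reported mean ≈ SD with a 1.2–10.6 range indicates right skew, and
a normal would produce negative creatinine); sex Bernoulli with
P(female) = 2/9; true η from the population prior; observations =
model prediction × (1 + ε), ε ~ N(0, 0.1839²) redrawn below −0.99 so
concentrations stay positive; the nine-point schedule
(3, 5, 8, 11, 13, 16, 19, 21, 24 h) under 1 g q8h over 3 h. True CVVH
clearance is drawn log-normal moment-matched to 0.6 ± 0.7 L/h and
clipped to 0.2–2.0 L/h; filter pairs at the three in-schedule
end-of-infusion times (3, 11, 19 h) are constructed by exact inversion
of the clearance formula, giving a machine-precision round trip.

What the generator does **not** emulate: time-varying renal function or
CRRT settings within a patient, assay quantification limits,
within-patient correlation of residual errors, sampling-time deviations,
and any covariate–η correlation. Tests passing on this cohort therefore
demonstrate the correctness of the arithmetic and the estimator's
behaviour under the assumed model — not predictive performance on real
CRRT patients.

## Problem sizes and numerical choices

Defaults used by the analysis drivers and checks: 5000 subjects per PTA
run (the simulation design's stated size; a run takes ~1 s), 9-patient
cohorts for fit-level analyses, 50-patient cohorts for estimator
calibration, 0.05 h grids for all fractional-time metrics. Ties and
degenerate cases: strict inequality at threshold crossings (a profile
sitting exactly at MIC counts as *not* above), repeated-eigenvalue limit
form as above, trough defined at the end of the interval, toxicity
strictly above 45 mg/L. Clearance and flow units are L/h internally;
converters (`FlowSettings.from_clinical`) live at the I/O boundary.

## Known limitations

- Single population model with pluggable parameters; no alternative
  published CRRT models, no saturable elimination or nonlinear binding.
- The prior is fixed: no population re-estimation (FOCE/SAEM) and no
  uncertainty intervals on η̂.
- CVVH clearance is reported alongside, not fed back into, the
  population-model fit.
- No MIC-distribution (CFR) weighting; single-MIC grids only.
- The QT convention in the filter-clearance formula is an assumption
  (see above) and materially scales CL_CVVH.
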
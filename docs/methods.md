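# Methods

This note documents the model implemented in `ascvdsim`: its structure and
assumptions, the parameters that matter, what the synthetic inputs stand in
for, and the numerical choices made where the design was genuinely open.

## Model structure

The core is an individual-level state-transition model in one-year cycles.
States are *event-free*, *post-CHD*, *post-stroke* and *dead* (absorbing);
treatment states are *never*, *on-statin* and *discontinued* (absorbing).
Individuals enter event-free between ages 40 and 89 (default 45+) and exit
at death or after the cycle in which they are 89 — the cap reflects the
sparse data on the very old.

Each cycle executes a fixed within-cycle order, locked for reproducibility:

1. screening/initiation (and the end-of-first-year discontinuation draw,
   bookkept at cycle end);
2. annual ASCVD probability for event-free individuals, with treatment
   adjustment;
3. ASCVD event draw → type split → case-fatality draw;
4. diabetes-onset draw for non-diabetic survivors (statin-adjusted);
5. background all-cause mortality draw (multiplied for post-event
   survivors);
6. cost and utility accrual, discounted by cycle index (cycle 0
   undiscounted, no half-cycle correction);
7. risk-factor drift and age increment.

Two implementations share this contract: a scalar per-individual path that
follows the model diagram literally, and a vectorised cohort path used for
production runs. Both consume exactly six uniforms per cycle in fixed order,
so an n=1 cohort reproduces the scalar path bit-for-bit (tested), and
running different strategies from the same master seed yields common random
numbers: paired draws that cancel Monte-Carlo noise out of incremental
comparisons. Independent runs are available by varying the seed per
strategy.

## Hazards

**10-year risk.** The hazard source is a Cox-form equation,
`risk₁₀ = 1 − S₀^exp(LP − L̄P)`, with per-sex coefficient blocks over named
covariates (age; SBP with separate treated/untreated coefficients; TC;
HDL-C; WC; smoking; diabetes). Coefficient sets are pluggable JSON; the
risk engine validates that every declared covariate is computable from a
profile. The equation is primary-prevention only: it is never applied to
post-event individuals.

**Annual conversion.** The 10-year risk is converted to an annual
probability assuming a constant hazard over the decade:
`p₁ = 1 − (1 − p₁₀)^{1/10}`, algebraically identical to converting through
the rate `−ln(1−p₁₀)/10`. The identity `(1−p₁)¹⁰ = 1−p₁₀` holds to 1e−12
across the unit interval (tested).

**Event typing and treatment effects.** A composite event is CHD with
probability 29.46% and stroke otherwise. Because the statin effects are
type-specific odds ratios (0.70 CHD, 0.81 stroke), the annual composite is
first split into type components by the fixed shares, each component is
odds-adjusted while on treatment, the event draw uses the summed adjusted
probability, and the type draw uses the adjusted conditional share. For
untreated individuals this reduces exactly to the 0.2946 cut on a uniform.
Odds-scale adjustment (`p' = OR·odds/(1+OR·odds)`) was chosen over
risk-scale multiplication because the parameters are published as ORs; the
diabetes effect (OR 1.21) is applied the same way for consistency.

**Case fatality** is a lookup by event type × sex × age band (34–44 …
75–84). The published bands stop at 84; ages 85–89 reuse the 75–84 value — a
conservative extension in the absence of data.

**Background mortality** applies to everyone who has not died of an event
that cycle; post-event survivors face the background rate multiplied by 2.0
("more than double" is stated without a precise value; exactly 2.0 is the
default and the multiplier is configurable). Recurrent ASCVD events are off
by default — the risk equation is primary-prevention only — with an
`allow_recurrence` switch that reuses the same annual hazard and does not
stack long-term decrements beyond the larger of the two.

**Statin-induced diabetes.** Incident diabetes while on statin is counted as
statin-induced. A deliberate design choice: incident diabetes (of either
kind) never updates the diabetes covariate of the risk equation, which
reflects baseline status only. The modelled mechanism is that the diabetes
side effect acts through costs and quality of life alone; letting some
incident diabetes raise ASCVD risk while exempting on-statin cases would
make a null treatment (all ORs = 1) produce systematically different arms —
a classification artefact, not a treatment effect. With ORs at 1 the treated
and untreated arms are bit-identical under common random numbers (tested).

## Treatment strategies and adherence

A strategy is a 10-year-risk initiation threshold (15%, 10%, 7.5%, or none)
plus optional named direct-initiation predicates (e.g. LDL-C ≥ 4.9 mmol/L),
all defaulting off. Eligibility is re-screened every cycle for untreated,
event-free individuals — risk factors drift with age, so initiation age is
endogenous. The tie-break is inclusive: risk exactly at the threshold
initiates. At the end of the first treated year each initiator discontinues
with probability 0.40 (a single lifetime draw; survivors adhere for life);
discontinuation is absorbing, removes both statin cost and effect
immediately (no legacy effect), and discontinued individuals never
re-qualify. Only moderate-intensity therapy is modelled.

## Costs and utilities

All amounts in 2022 CN¥, healthcare-payer perspective, discounted at 3%/yr
(same rate for costs and QALYs). Defaults: statins 1,149.75/yr;
hospitalisation 22,611 (AMI) / 13,983 (stroke); first post-event year
5,255.85 / 2,652; later post-event years 585.87 / 565 (one outpatient visit
per year for life); annual diabetes-management cost configurable, default 0
until a sourced value is supplied. A cycle ending in an ASCVD death accrues
hospitalisation only; a background-death cycle accrues nothing.

Utilities are age-specific weights minus **additive** decrements, floored at
zero: acute decrements (CHD 0.439, stroke 0.92) in the event cycle only,
long-term decrements (AMI 0.107, stroke 0.266) every later post-event year,
and a configurable diabetes disutility (default 0). Additive-with-floor was
chosen over multiplicative because the parameters are published as negative
utility weights; the near-zero utility of a stroke event year is then
coherent. Death cycles contribute no utility.

## Frontier, CEAC

Strategies are sorted by cost; strictly dominated ones (another strategy no
more costly and no less effective, strictly better on one axis) are removed;
extended dominance then iteratively removes any strategy whose incremental
ICER exceeds that of the next step, until frontier ICERs are nondecreasing.
The implementation is tested against an independent oracle: the set of
strategies that maximise net monetary benefit `λ·QALY − cost` for some
willingness-to-pay λ ≥ 0, enumerated by sweeping the candidate crossing
points (1,000 random instances). CEACs report, at each λ, the probability
across PSA draws that a strategy maximises NMB, ties split equally; decision
rules are evaluated at λ = 85,700 (1× 2022 GDP per capita) and 257,100 (3×).

## Sensitivity analysis

**PSA.** Each draw samples one parameter vector and holds it fixed across
strategies and individuals (parameter uncertainty only; the simulation seed
is shared across draws and strategies). Families: beta and gamma
parameterised by method of moments from (value, SE); lognormal for odds
ratios with ln-scale σ = SE/value (delta method) and μ chosen so the
arithmetic mean equals the point value. Distributions whose published row
lacks a standard error (the costs' gamma rows, the diabetes OR's beta row —
the latter is not implementable as printed for a value above 1 in any case)
fall back to fixed with a warning; explicit overrides are accepted. All
(value, SE) distributions reproduce their moments at 1e5 draws (tested).

**One-way DSA.** A single parameter is set to each bound (published SE →
value ± 1.96·SE clipped to support; otherwise ±20%), everything else at
base, common random numbers; the tornado orders parameters by ICER range. A
parameter with no model influence produces a zero-width bar (tested).

## Validation procedures

*Internal*: per sex × 10-year age band, the analytic mean 1-year CHD and
stroke probabilities at baseline are regressed against the mean simulated
first-cycle frequencies in the untreated arm (averaged over replications so
small old-age groups do not dominate with binomial noise); the R² of that
regression exceeds 0.9 on a 40,000-person synthetic cohort (tested).
*External*: a report-only comparison of simulated age-sex incidence and life
expectancy against any user-supplied reference table. The engine itself is
verified against a deterministic cohort-Markov recursion for identical
constant-hazard individuals: mean life expectancy, discounted QALYs and
discounted costs agree within 3 Monte-Carlo standard errors at n = 100,000
(tested).

## Synthetic inputs: what they stand in for, and what they do not show

Several inputs of an applied analysis of this kind come from restricted
national survey microdata and reference tables that are not redistributable.
The package ships clearly labelled synthetic stand-ins, all overridable:

- **Risk-equation coefficients** (`data/china_par_style_synthetic.json`):
  same functional form and covariates as the published China-PAR equation,
  plausible effect magnitudes (e.g. ln-hazard +0.061/yr of age for men),
  baseline 10-year survival 0.944 (men) / 0.975 (women), and mean linear
  predictors computed at the default population's covariate means. *Not* a
  transcription of the published coefficients.
- **Baseline cohort marginals**: truncated Gaussians for age (mean 59,
  SD 9.5), SBP (132/130 mmHg), TC, HDL-C, LDL-C, WC, with smoking 46%/5%,
  diabetes 10%/12% and antihypertensive treatment 15%/18% (men/women) —
  literature-plausible values for middle-aged/elderly Chinese adults.
  Correlations default to independence (no joint structure is published); a
  Gaussian-copula correlation matrix can be supplied.
- **Age trends**: deterministic linear drift (SBP +0.5–0.6 mmHg/yr, TC
  +0.010–0.012, HDL-C −0.002, LDL-C +0.005–0.006, WC +0.1 cm/yr), residual
  SD 0 by default; factors are floored at clinical minima (HDL-C ≥ 0.3
  mmol/L etc.) so decades of drift cannot produce impossible values.
- **Background mortality**: per-sex Gompertz curves anchored at plausible
  Chinese adult rates (men ~0.002 at 40, ~0.06 at 80). No ASCVD-death
  fraction is subtracted by default (configurable), so ASCVD mortality is
  mildly double-counted at the margin.
- **Age-specific utility weights** (0.96→0.82 men, 0.95→0.80 women by
  decade) and **diabetes incidence** (0.4–1.2%/yr by age).

Consequently, passing tests demonstrate that the *machinery* is correct —
probabilities are transformed, combined, accrued, discounted and ranked as
specified, and recover configured parameters — and that the comparative
statics (threshold ordering of eligibility, events, diabetes cases, costs)
behave as the model predicts. Absolute QALY, cost and ICER levels
characterise the synthetic calibration, not the Chinese population; applied
use requires substituting sourced inputs via the documented interfaces.

## Problem sizes and numerics

Default analyses use 10,000 individuals; verification runs use what their
precision requires (two-arm OR recovery: 1e6 person-cycles per arm;
adherence: 1e5 initiators; event split: 1e6 events; Markov-oracle agreement:
1e5 individuals; frontier oracle: 1,000 random instances). Acceptance bands
are 3 Monte-Carlo standard errors throughout. Uniform draws are compared
with strict `<` against probabilities; the eligibility tie-break is `≥`;
probabilities are clipped to [0,1] after odds adjustment only through the
algebra itself (the transform cannot leave the interval). The 7-step cycle
order above is fixed; there is no half-cycle correction.

## Known limitations

- No recurrence by default, so long-run event burdens are understated for
  survivors; the `allow_recurrence` switch is a crude sensitivity handle,
  not a calibrated secondary-prevention model.
- No secondary-prevention statin therapy, dose titration, high-intensity
  arms, or combination lipid therapy.
- Diabetes complications, societal costs, productivity and equity are out of
  scope; diabetes cost/disutility default to 0 until supplied.
- The synthetic calibration above; absolute outputs are not national
  estimates.
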
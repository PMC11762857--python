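# ascvdsim

Individual-level cost-effectiveness microsimulation of **statin initiation
thresholds** for the primary prevention of atherosclerotic cardiovascular
disease (ASCVD) in middle-aged and elderly Chinese adults.

The question the package addresses: at what 10-year ASCVD risk should statin
therapy begin — 15%, the 10% guideline threshold, or 7.5%? Lower thresholds
prevent more coronary (CHD) and stroke events but cost more and cause more
statin-induced type 2 diabetes. The package simulates individual life
courses under each initiation rule, accrues discounted costs and
quality-adjusted life years (QALYs), and ranks the strategies by incremental
cost-effectiveness ratio (ICER) against Chinese GDP-per-capita
willingness-to-pay benchmarks (1×: CN¥ 85,700; 3×: CN¥ 257,100 per QALY).
It is written for health economists and epidemiological modellers who want a
tested, scriptable alternative to spreadsheet/TreeAge-style decision models.

## The model

Each individual is simulated in annual cycles from baseline (age 45+, no
ASCVD history) to death or age 89:

1. **Risk.** A Cox-form 10-year composite ASCVD risk (China-PAR style)
   `risk₁₀ = 1 − S₀^exp(LP − L̄P)`, with a per-sex linear predictor `LP` over
   age, SBP (treated/untreated), TC, HDL-C, WC, smoking and diabetes, is
   converted to an annual probability by the DEALE constant-hazard identity
   `p₁ = 1 − (1 − p₁₀)^(1/10)`.
2. **Events.** Composite events split 29.46% CHD / 70.54% stroke; case
   fatality is an event × sex × age-band lookup; survivors of a first event
   face doubled background mortality and no recurrence (configurable).
3. **Treatment.** Statins initiate when the 10-year risk reaches the
   strategy threshold (screened annually); 40% of initiators discontinue
   after the first treated year, the rest adhere for life. On treatment the
   annual CHD, stroke and diabetes probabilities are adjusted on the odds
   scale (OR 0.70, 0.81 and 1.21 respectively); statin-induced diabetes
   affects only costs and quality of life, never ASCVD risk.
4. **Economics.** Costs (statins CN¥ 1,149.75/yr, hospitalisation, post-event
   care) and utilities (age-specific EQ-5D weights minus acute and long-term
   event decrements, floored at 0) accrue each cycle and are discounted at
   3%/yr. Strategies are ranked by the ICER ladder with strict and extended
   dominance; probabilistic sensitivity analysis (PSA) feeds
   cost-effectiveness acceptability curves via net monetary benefit.

Baseline cohorts are generated synthetically (configurable per-sex marginals
with age-linear risk-factor drift) or loaded from CSV.

## Worked example

```python
import ascvdsim as a

model = a.StatinPolicyModel.from_synthetic(n=10_000, seed=42)
results = model.run(seed=42)
print(results.summary())
```

prints

```
Statin initiation-threshold cost-effectiveness microsimulation
cohort n = 10,000   seed = 42   discount rate = 3.0%

strategy         eligible%   CVD/pp   SID/pp     QALYs      LE        cost  status                      ICER
no-treatment          0.0%    0.246   0.0000    13.232   80.51       3,201  on-frontier
threshold-15         57.6%    0.232   0.0288    13.260   80.56       4,979  on-frontier               62,548
guideline-10         75.0%    0.227   0.0483    13.280   80.60       6,376  on-frontier               70,891
threshold-7.5        83.7%    0.225   0.0624    13.286   80.61       7,429  on-frontier              161,388

optimal at 1x GDP/capita (85,700): guideline-10
optimal at 3x GDP/capita (257,100): threshold-7.5
```

Reading the table: as the initiation threshold drops 15% → 10% → 7.5%, the
fraction of adults ever eligible for statins rises, CVD events per person
(`CVD/pp`) fall, statin-induced diabetes cases per person (`SID/pp`) rise,
and mean discounted cost rises. Each `ICER` is the incremental cost per QALY
of that strategy versus the previous step on the frontier; the closing lines
apply the two GDP-based willingness-to-pay rules. Results above use the
packaged *synthetic* default calibration (see `docs/methods.md` for what is
synthetic and why), so the absolute numbers characterise the synthetic
population, not a national estimate — the directional structure is the
modelled content.

The same analysis is available from the shell:

```bash
ascvdsim simulate --n 10000 --seed 42 --out results/
ascvdsim psa --n 2000 --seed 42 --draws 200 --out results/
ascvdsim dsa --n 2000 --seed 42 --out results/
```

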
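# hfscreen

Cost-effectiveness modelling of heart-failure (HF) screening in older
patients with type 2 diabetes.

Roughly a quarter of community-dwelling type-2-diabetes patients aged 60+
carry unrecognized heart failure, most of it with preserved ejection
fraction (HFpEF), for which — unlike HF with reduced ejection fraction
(HFrEF) — no prognosis-modifying drugs existed at the time the underlying
Dutch evaluation was done. `hfscreen` implements the full decision-analytic
pipeline for asking whether it pays to look for these cases: a Markov cohort
state-transition model of HF detection and progression, incremental
cost-effectiveness analysis over six screening strategies, probabilistic
sensitivity analysis (PSA) with acceptability curves, and scenario grids for
hypothetical HFpEF treatment effectiveness. It is aimed at health-economic
modellers and methods researchers who want a tested, scriptable version of
this class of model rather than a spreadsheet.

## The model

Eleven mutually exclusive health states: *diabetes without HF*, NYHA classes
I–IV each split into *detected* and *undetected* HF, and two absorbing death
states (HF death, other-cause death). The cohort starts at age 60 and is
advanced in 3-month cycles until extinction (or age 110). Per cycle, in
order: death (background mortality from a Gompertz life table; HF mortality
per NYHA class and detection status, converted to cycle scale as
p_cycle = 1 − (1 − p_year)^0.25), HF incidence (diabetes-without-HF →
NYHA II undetected), then NYHA movement via the third power of a monthly
NYHA transition matrix, age-scaled above 65. Detection status changes only
through screening events: an initial screen at cycle 0 (strategy-specific
per-NYHA sensitivity and specificity) and an annual EMR/symptoms
reassessment; screen positives get an echocardiography (a perfect arbiter),
new diagnoses an ECG stress test.

Value accrual follows the standard cohort bookkeeping

- QALYs = Σ_cycles Σ_states occupancy × utility × 0.25 × (1.015)^(−t),
- costs = Σ_cycles (state costs + event costs) × (1.04)^(−t),

with EQ5D-based state utilities and incremental HF costs (zero for
diabetes-without-HF). Strategies are compared by incremental
cost-effectiveness ratios (ICER = ΔC/ΔE) after removing strongly and
extendedly dominated options; the PSA samples beta (test accuracies,
utilities), variance-equals-mean gamma (costs) and Dirichlet (baseline NYHA
prevalence) distributions and summarizes draw-wise net monetary benefit
NMB = λ·E − C into cost-effectiveness acceptability curves.

The inputs that the underlying publications do not report numerically (the
monthly NYHA matrix, the life table, hospitalization hazard ratios, drug
unit costs) are produced by a seeded synthetic-data module, including a
derivative-free calibration that searches the NYHA-matrix generator for
given life/QALY expectancy targets.

## Worked example

```python
from hfscreen.reporting import run_base_case, render_base_case

table, cea, results = run_base_case("dutch_men")
print(render_base_case(table))
```

```
 strategy life_years  qalys   cost            dominance  comparator delta_qalys delta_cost   icer
        0     15.402 10.993 11,002         nondominated         NaN
        1     15.445 11.087 11,723         nondominated         0.0       0.094        721  7,646
        2     15.445 11.087 11,731 extendedly_dominated         NaN
        3     15.445 11.088 11,749 extendedly_dominated         NaN
        4     15.445 11.088 11,771   strongly_dominated         NaN
        5     15.445 11.091 11,783         nondominated         1.0       0.003         61 17,607
```

Reading it: strategy 0 (no screening) is the reference; screening adds a few
hundredths of a (discounted) QALY per person. Strategies 2–4 (physical exam,
NT-proBNP, ECG add-ons) are dominated — they cost more than the simple
EMR/symptoms check (strategy 1) without buying additional QALYs — so the
frontier runs no-screening → EMR/symptoms (≈ €7.6k per QALY gained) →
direct echocardiography (≈ €17.6k per QALY). At a willingness to pay of
€20,000/QALY screening is cost-effective. The same qualitative picture
(frontier 0 → 1 → 5, three dominated strategies) holds for the women's
fixture and matches the published Dutch analysis; absolute levels depend on
the synthetic stand-ins for the unpublished inputs (see
`docs/methods.md`).

The command-line interface exposes the same pipeline:

```bash
hfscreen base-case --config dutch_men
hfscreen psa --config dutch_women --n 10000 --seed 1
hfscreen scenario --config dutch_men --rho-step 0.1
hfscreen synth --seed 7 --out-dir synthetic/
```

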
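# Methods

## Model structure and assumptions

`hfscreen` is a deterministic Markov cohort (state-transition) model: at
every cycle the cohort is a probability mass over eleven mutually exclusive
health states — diabetes without heart failure (HF), NYHA I–IV each in a
detected and an undetected variant, and two absorbing death states (HF
death, other-cause death). Expected fractions move between states through a
per-cycle transition matrix; no individual-level (first-order Monte Carlo)
simulation is performed, so all results are cohort expectations.

Cycles are 3 months (the usual diabetes consultation interval) and the
horizon is lifetime: the run stops when the alive mass falls below 1e-8 or
the cohort age passes 110 years, whichever comes first. Both the mass
threshold and the age cap are configurable; the closed-form life-expectancy
tests raise the age cap to infinity so the geometric-series comparison is
exact to 1e-6.

Within a cycle, events compose in a fixed order chosen for reproducibility
(alternative orderings differ at O(cycle-length²)):

1. **Death.** Background (non-HF) mortality applies to every alive state;
   HF states additionally face HF mortality. The two death probabilities are
   additive competing risks within a cycle: the HF-death entry of a row is
   exactly the cycle-converted HF mortality, the other-death entry the
   cycle-converted background mortality, and survivors are the remainder
   (an assembly error is raised if the two exceed 1).
2. **Incidence.** Survivors of the diabetes-without-HF state develop HF at
   the cycle-converted incidence rate (times a configurable diabetes
   multiplier, default 1.0 — exposed as a calibration knob because the
   population incidence is reported without a diabetes-specific factor).
   New HF always enters at NYHA II undetected.
3. **NYHA movement.** Conditional on survival, the cohort moves among NYHA
   classes within its detection stratum via the third matrix power of a
   monthly NYHA transition matrix.

Annual probabilities p are converted to cycle scale under a constant-hazard
assumption, 1 − (1 − p)^0.25, which preserves the 0 and 1 boundaries and
composes exactly back to p over four cycles.

**Ageing.** Background mortality is an age-indexed annual table. HF
mortality and NYHA worsening are scaled by an age-band multiplier (bands
60–70 / 70–80 / 80+ in the shipped fixtures, reference age 65): worsening
probabilities are multiplied by the band ratio, improvement probabilities
divided by it, and the diagonal re-closes each row. If scaling pushes a
row's off-diagonal mass above 1 the row is renormalized and a warning is
recorded — this happens only under extreme calibration trials, not under
the shipped defaults.

**Screening.** Detection status changes only through screening events,
applied to the state distribution at cycle start: the chosen strategy once
at cycle 0, and the EMR/symptoms profile every fourth cycle thereafter (for
screening strategies; usual care screens never). Only the
diabetes-without-HF state and undetected NYHA states are screened —
detected patients are under cardiology care, the dead are dead. Per NYHA
class, sensitivity × (undetected mass) moves to the detected state;
(1 − specificity) of the no-HF mass is referred to echocardiography, which
is treated as a perfect reference standard, so false positives cost an echo
but are never misdiagnosed. The direct-echocardiography strategy sends every
screened person to echo. Costs per event: the GP-level screen is charged for
every screened person (the tariff prices the strategy, not the positives),
the echo per referral, and an ECG stress test per new diagnosis. Whether the
annual reassessment re-incurs the full €6.39 EMR/symptoms tariff is an open
tariff question; the default does, and `annual_screen_gp_cost` overrides it.

**Treatment effect.** Detected HF is a mix of an HFrEF share (1 − f) whose
guideline therapy carries mortality hazard ratio h (default f = 0.826,
h = 0.90), and an HFpEF share f receiving a fraction ρ of that effect
(default ρ = 0: no HFpEF benefit). The mixed hazard multiplier is
m(ρ) = (1 − f)·h + f·(1 − ρ·(1 − h)). The recorded detected-state
mortalities already embed the base-case mix, so the engine scales them by
m(ρ)/m(0) on the hazard scale — at ρ = 0 they are used verbatim; scenario
analyses sweep ρ over 0…1.

## Valuation

QALYs accrue as occupancy-weighted utility × 0.25 years per cycle,
discounted at the effects rate (default 1.5 %/year); costs (state costs
plus screening/diagnosis event costs) discount at the costs rate (default
4 %/year). Discounting is evaluated at cycle start; a mid-cycle
(half-cycle-corrected) option exists but is off by default, as is standard
when the choice is not reported. Life expectancy is reported undiscounted
(a discounted variant is also returned). State costs follow an incremental
convention — diabetes care itself is not modelled, so diabetes-without-HF
and death states cost nothing. HF state costs are read directly from the
recorded per-NYHA annual costs; an alternative derived path rebuilds them
from a base hospitalization/nursing cost weighted by per-NYHA
hospitalization hazard ratios, a detected/undetected mortality-ratio
adjustment, and a detected-only medication component.

A subtlety worth recording: the published expectancy table's QALY/LY ratio
(≈ 0.84) exceeds what 1.5 %-discounted QALYs could reach given utilities
≤ 0.868, so those published QALY expectancies must be undiscounted. The
analysis pipeline nevertheless discounts QALYs at 1.5 % as the stated
methods prescribe; only the calibration targets (below) are matched against
undiscounted QALYs.

## Incremental analysis

Strategies are ranked by QALYs (ties broken by lower cost). A strategy is
strongly dominated if another is at least as effective and strictly
cheaper, or strictly more effective and no dearer — so exact QALY ties with
higher cost are strongly dominated, while exact (QALY, cost) duplicates are
kept and flagged as ties. Extended dominance is removed iteratively:
an interior candidate whose incremental ratio is not below that of the next
segment is excluded, leaving a frontier with strictly increasing ICERs. A
zero QALY difference raises a dedicated undefined-ICER signal rather than
dividing. ICERs are kept unrounded internally; the report renderer rounds
to whole euros and 3-decimal QALYs.

## Probabilistic sensitivity analysis

Each PSA draw samples every uncertain input once and evaluates *all*
strategies on that same draw (common random parameters — required for
meaningful incremental clouds), at the default sample size of 10,000.

- **Test accuracies** (sensitivities, specificities): beta with
  pseudo-counts (TP, FN) reconstructed from the cohort dimensions (581
  patients, 27.7 % HF prevalence, cases split over NYHA classes by the
  baseline prevalence mix), so the mean equals the recorded proportion.
  Exact 0.000/1.000 cells are degenerate and stay fixed.
- **Costs**: gamma with variance equal to the mean (shape = mean,
  scale = 1).
- **Utilities**: method-of-moments beta around the recorded mean with a
  configurable standard error (default 0.02, chosen as a typical EQ5D
  group-mean SE at these group sizes since only means are recorded).
- **Baseline prevalence**: one Dirichlet over the nonzero cells with
  concentrations proportional to counts; draws are rescaled to the base
  block total, so the prevalence mass is redistributed, never inflated.
- **Incidence and mortality**: fixed, as in the source evaluation.

Every distribution is mean-centred on its base value (verified to 1e-9 in
the tests), so cloud means match the deterministic base case up to
Monte-Carlo error and model nonlinearity; the suite checks agreement within
3 standard errors at 2,000 draws — a sample size chosen to keep the full
test run under a minute while leaving the 3-SE check sharp. Draws producing
an invalid parameter set are rejected and redrawn with a logged count (none
occur under the defaults). Acceptability curves report, per
willingness-to-pay value, the fraction of draws in which each strategy has
the strictly highest net monetary benefit, exact ties split equally.

## Synthetic inputs and calibration

Four load-bearing inputs are consumed from sources that print no numbers,
so the `synthetic` module generates plausible, seed-deterministic versions:

- **Monthly NYHA matrix**: worsening mass above the diagonal
  (intensity × decay^(distance−1)), improvement mass below (including
  NYHA IV → I), diagonal as remainder; optional lognormal jitter. The
  shipped default (worsening 0.04/month, improvement 0.02/month, decay
  0.18) is a hand-tuned, version-frozen fixture: it lands the model's life
  and QALY expectancies within a few percent of the published values while
  preserving the published qualitative frontier (no-screening →
  EMR/symptoms → echocardiography, the other three dominated) in both
  genders. A pure least-squares fit to the expectancy targets alone drives
  the matrix to clinically implausible monthly worsening (> 0.5) and
  destroys that structure, which is why it is not the default.
- **Life table**: Gompertz, m(a) = anchor·exp(rate·(a − 60)), anchored at
  the recorded annual probabilities at 60 (0.010 men, 0.007 women), rate
  0.092 (mortality doubling ≈ 7.5 years, typical of 60+ populations).
- **Hospitalization hazard ratios and drug costs**: fixed plausible
  defaults (HRs 1.0/1.2/1.8/5.0 over NYHA I–IV; Dutch generic-level annual
  drug costs) feeding the derived-cost path.
- **Patient table**: per-patient utility (moment-matched beta) and cost
  (variance-equals-mean gamma) draws whose group means converge to the
  recorded summary statistics; used for validation exercises.

`calibrate_nyha_matrix` searches the generator's (progression, improvement,
decay) space — seeded random scan plus Nelder-Mead in log/logit space,
capped at a model-evaluation budget (default 250; each evaluation runs two
full lifetime cohorts, ≈ 15 ms) — minimizing the squared deviation of
no-screening and EMR/symptoms life-years and (undiscounted) QALYs from the
supplied targets. Four scalar targets cannot identify twelve free matrix
entries: the result is a best fit with its achieved loss, and no uniqueness
is claimed. On targets generated by the model itself the search recovers
them to loss ≤ 1e-6; on the published men's expectancies it reaches within
0.05 life-years.

## What the synthetic conditions do and do not show

Passing tests demonstrate internal correctness (conservation of cohort
mass to 1e-9 per cycle, equivalence with explicit matrix powers to 1e-10,
closed-form life-expectancy agreement to 1e-6, mean-centred PSA, normalized
CEACs, monotone scenario grids) and qualitative agreement with the
published Dutch evaluation under plausible stand-ins for its unpublished
inputs. They do not validate the stand-ins themselves against real Dutch
life tables, real NYHA transition data, or patient-level EQ5D
distributions; absolute cost and QALY levels shift with those inputs even
though the dominance structure is robust across the ranges explored.

## Known limitations

- No acute-exacerbation hospitalization events, end-of-life cost
  surcharges, or rapid pre-death NYHA progression; like the source
  evaluation, the model lets patients die from any NYHA state.
- Full screening attendance and full medication compliance are assumed;
  no test–retest correlation, no incidental echo findings.
- No correlation between sampled parameters beyond the Dirichlet block.
- No value-of-information (EVPI/EVPPI) analysis.
- The women's published table is internally inconsistent at its printed
  precision (one strategy prints one more thousandth of a QALY than the
  strategy said to dominate it); computations on those printed cells
  therefore place it on the frontier, as the tests document.
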
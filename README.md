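# lungscreen

A Markov cohort cost-effectiveness model for **risk-factor-based low-dose CT
(LDCT) lung cancer screening in current smokers**, written for health
economists and screening-policy analysts who want a transparent, testable
re-implementation of this class of decision model outside proprietary
decision-tree software.

## The model

A closed cohort of current smokers enters at age 40 and is followed in
3-month cycles to age 85 through 12 health states: no lung cancer; five
preclinical (asymptomatic, undiagnosed) cancer stages I/II/IIIA/IIIB/IV;
five post-diagnosis states of the same stages; and death. Per cycle,
disease-free individuals develop preclinical stage-I cancer with probability

    p_onset = 1 − (1 − incidence(age) × RR(pack-year stratum))^(1/4),

preclinical occupants progress, present clinically, or die using tabulated
per-cycle probabilities, and diagnosed occupants face a constant
stage-specific per-cycle fatality (derived from two-year survival *S* as
`1 − S^(1/8)`). Annual risks are converted to cycle risks throughout by
`1 − (1 − r)^(1/4)`.

A screening **strategy** is an age window plus a minimum pack-year
criterion: starting ages {40, 45, 50, 55, 60, 65} × stopping ages
{69, 74, 79} × {≥20, ≥30 pack-years} give 36 strategies, evaluated against
no screening together with the three Chinese guideline strategies
(2018: 50–74/≥20; 2021: 50–74/≥30; 2022: 45–74/≥20). LDCT rounds occur
every 4th cycle inside the window, detecting preclinical disease with
sensitivity 0.8913 and producing false positives (specificity 0.9436) that
carry a one-cycle disutility of 0.063. Round costs combine the scan
(USD 53.94), the early-recall repeat scan, and the immediate-referral
diagnostic workup (USD 333.89), using age-specific baseline-round rates.

Costs (2021 USD) and QALYs are discounted at 5 %/year with a half-cycle
correction. Strategies are compared by the incremental cost-effectiveness
ratio ICER = ΔC/ΔE; the package removes absolutely and extendedly dominated
strategies, builds the efficiency frontier, and selects the optimal
strategy at a willingness-to-pay threshold (multiples of per-capita GDP)
by maximal net monetary benefit `WTP × E − C`. One-way sensitivity
analysis, probabilistic sensitivity analysis (beta/gamma method-of-moments
sampling, common random numbers, CEAC), and overdiagnosis / participation /
regional scenario analyses are included.

Two inputs of the original analysis have no public release — the age/sex
life table and the baseline preclinical state distribution — so the
`synthetic` module generates labelled synthetic stand-ins (a capped
Gompertz mortality curve; an entry distribution with 0.4 % preclinical
mass). Absolute cost/QALY totals therefore depend on these fixtures; the
ICER/frontier arithmetic is validated against published totals injected as
inputs.

## Worked example

```python
import lungscreen as ls

params = ls.default_parameters()           # tabulated base-case inputs
life = ls.make_life_table(seed=0)          # synthetic life table
baseline = ls.make_baseline_distribution(seed=0)

outcomes = ls.run_grid(params, life, baseline)   # 36 + 3 strategies + comparator
frontier = ls.build_frontier(outcomes)
for o in frontier.frontier:
    icer = frontier.frontier_icers.get(o.label)
    tail = f"{icer:10.2f}" if icer is not None else ""
    print(f"{o.label:>14s}  {o.cost:8.2f}  {o.qalys:.5f}  {tail}")
print("optimal at 3x GDP:", ls.optimal_at_wtp(frontier, 3 * 12551))
```

prints

```
  No screening    838.62  14.87723
    65-74-30py   1214.91  14.89869    17537.12
    60-74-30py   1462.70  14.91245    18013.22
    60-79-30py   1552.90  14.91721    18945.76
    55-79-30py   1801.37  14.92966    19949.79
    55-79-20py   2299.69  14.95035    24086.17
    50-79-20py   2663.72  14.96246    30071.91
    40-79-20py   3572.19  14.98523    39888.01
optimal at 3x GDP: 50-79-20py
```

Each frontier row shows the strategy label (start–stop–pack-year
criterion), total discounted cost per cohort member (USD), total discounted
QALYs, and the ICER versus the previous efficient strategy; the last line
applies the decision rule at three times national per-capita GDP
(3 × USD 12,551 = USD 37,653 per QALY). Under the synthetic fixtures the
qualitative structure of the published analysis emerges: every screening
strategy costs more and yields more QALYs than no screening, frontier
ICERs rise steeply as the window widens, 20-pack-year strategies dominate
the effective end of the frontier, and no strategy is cost-effective at
1 × GDP.

A command-line interface exposes the same pipeline:

```
lungscreen basecase              # grid + frontier (CSV/JSON)
lungscreen owsa                  # tornado of one-way ICER ranges
lungscreen psa --seed 1 --n 10000
lungscreen scenarios             # overdiagnosis / participation / regions
lungscreen synth                 # emit the synthetic input fixtures
```

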
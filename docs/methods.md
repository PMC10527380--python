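# Methods

## Model structure and assumptions

The model is a deterministic Markov cohort (state-transition) model with 12
states — no lung cancer, preclinical stages I/II/IIIA/IIIB/IV, diagnosed
stages I/II/IIIA/IIIB/IV, death — run in 3-month cycles from age 40 to 85
(180 cycles). It assumes:

* **Stage frozen at diagnosis.** Post-diagnosis disease is not modelled
  explicitly; a diagnosed occupant carries the stage at which they were
  detected, with a constant per-cycle fatality, per-cycle treatment cost
  and utility for that stage. IIIA and IIIB share the stage-III cost and
  utility but have distinct fatalities (0.0720 vs 0.1262 per cycle).
* **Memoryless preclinical progression.** Per-cycle progression,
  clinical-presentation and preclinical-death probabilities are constant
  in time and age; only onset (incidence × relative risk) and other-cause
  mortality vary with age.
* **Competing risks within a cycle.** Other-cause death is applied first
  at the life-table per-cycle rate; the surviving mass is then allocated
  across the tabulated disease-specific exits, with "stay" as the
  residual. Preclinical cancer-death rates originate from a disease model
  already net of background mortality, so they are treated as
  cancer-attributable and are not double-counted with the life table.
* **Event order.** Screening (every 4th cycle inside the strategy window)
  is applied to the start-of-cycle occupancy, before that cycle's
  transition. A fixed order is required for reproducibility; none is
  canonical.

## Cohort semantics

All strategies are compared on a **common cohort**: current smokers with at
least 20 pack-years, mixed over the 20–29 and ≥30 pack-year strata by
population weights derived from smoking prevalence and stratum proportions
under a 50/50 male/female base population (the eligible cohort is ~98 %
male; the sex mix also weights the sex-specific life tables and is
overridable). A ≥30-pack-year strategy screens only the ≥30 stratum; the
20–29 stratum runs unscreened. This is the only construction under which
all strategies and a single no-screening comparator are coherent on one
cost-effectiveness plane. `blend_strata` additionally reports the
per-eligible-person mixture for a strategy's own eligible population
(for a ≥30 criterion, exactly the ≥30-stratum run).

## Rewards, discounting, half-cycle correction

Cycle QALYs are Σ occupancy × utility / 4, with utility 0.933 for
disease-free *and* preclinical (asymptomatic) states, 0.84/0.79/0.79/0.77
for diagnosed I/II/III/IV, and a false-positive disutility of 0.063 lasting
exactly one cycle (0.063/4 QALYs per event). Cycle costs are per-cycle
treatment for diagnosed occupants (charged for the remaining lifetime; the
printed per-cycle figures are taken to embed maintenance care), plus event
costs: screening rounds (scan 53.94 + early-recall repeat scan +
immediate-referral workup 333.89, with baseline-round rates keyed to the
starting age and nearest-lower-age lookup between grid points) and one
diagnostic workup per detection or clinical presentation.

Discounting uses the annual 5 % rate in cycle units, factor
`1.05^(−cycle/4)`. The half-cycle correction is the state-membership form —
cycle rewards use the mean of start- and end-of-cycle occupancy — and is
switchable (`half_cycle=False`) for audit; event costs are charged at the
cycle they occur.

## Parameters

All inputs live in one YAML file (`data/parameters.yaml`): each is a base
value, a [min, max] range and a distribution family (beta for
probabilities/utilities, gamma for costs and relative risks, fixed for
quantities excluded from PSA). Conventions adopted where the source table
is silent:

* **Preclinical progression ranges.** The table assigns these rows a beta
  distribution but prints no range; the footnote convention (±20 %) is
  applied to construct their ranges.
* **Discount rate.** 5 %/year base; OWSA range 0–8 %/year (the customary
  Chinese pharmacoeconomic-guideline span); excluded from PSA.
* **Incidence and background mortality** are fixed in both OWSA and PSA
  (no distribution is assigned to them).

## Synthetic inputs

Two inputs have no public release and are generated synthetically:

* **Life table** — Gompertz curve `q(age) = min(0.7, level·A·e^{B·age})`
  anchored at q(40) = 2 × 10⁻³ and q(80) = 6 × 10⁻², female = 0.8 × male.
  It is a fixture with the right shape (monotone, convex in log), not a
  demographic estimate.
* **Baseline state distribution** — 99.6 % disease-free at entry, 0.4 %
  preclinical mass split 50:20:10:10:10 across stages I…IV, matching the
  low single-round detection fractions of community LDCT programmes.
* **Regional incidence multipliers** — labelled synthetic profiles (east
  shifted younger and higher; west low, especially under 60; south mildly
  high; north mildly low) combined with the published regional per-capita
  GDP figures (USD 15,234 south / 17,520 east / 8,941 west / 7,326 north;
  12,551 national) for willingness-to-pay thresholds.

Consequently **absolute** cost and QALY totals are properties of the
fixtures, not reproductions of the published totals; tests validate the
engine on exact structural oracles (analytic matrix powers, geometric
survival sums, mass conservation, zero-discount identities) and on the
qualitative dominance structure (wider windows cost more and yield more),
while the ICER/frontier/decision arithmetic is validated exactly on the
published cost/QALY totals injected as inputs. Passing tests therefore
demonstrate correctness of the machinery and the qualitative behaviour,
not calibration to Chinese national data.

## Sensitivity analyses

* **OWSA** re-runs the two-strategy comparison with one parameter pinned at
  each bound; the tornado ranks by |ICER_hi − ICER_lo|.
* **PSA** fits beta/gamma distributions by method of moments with mean at
  the base value and SD = (max − min)/(2 × 1.96) (the printed range read
  as a 95 % interval); infeasible beta moments fall back to a
  range-rescaled beta, then to a point mass, with a logged warning.
  Parameters are drawn independently (no correlation information exists);
  one joint draw per iteration is applied to every strategy (common
  random numbers). The CLI default is 10,000 iterations; the test suite
  uses 2,000 (and 100 for the degenerate point-mass check) to keep the
  default run fast — Monte-Carlo error at these sizes is bounded in the
  tests themselves. CEACs report the fraction of iterations in which each
  strategy has maximal net benefit; ties split evenly.
* **Joint feasibility.** Bound or sampled values can push one state's
  per-cycle exits past a joint sum of 1 (stage IV sums to 0.9562 at base).
  The sensitivity analyses therefore project such a row's exits back onto
  the simplex (scale to sum 1); the base-case engine instead raises a
  model-inconsistency error naming the row, as a guard against malformed
  inputs.

## Scenarios

* **Overdiagnosis** (detection relative risk 1.15, overdiagnosed share
  18.5 %): overdiagnosed cases are indolent lesions drawn from the
  disease-free mass — their survival follows the no-cancer counterfactual
  (other-cause mortality only) while they accrue the diagnostic workup,
  stage-I treatment cost per cycle and stage-I utility. Detection of true
  preclinical disease uses sensitivity × 1.15 capped at 1; the
  overdiagnosed mass is sized so that it is 18.5 % of all screen
  detections. This makes overdiagnosis a pure harm, raising costs and the
  ICER and shifting the optimal window older — the reported direction.
* **Participation** (35.6 % scenario value): the attendee fraction of
  every round is scaled; attendance is redrawn independently each year
  (non-attenders are not permanently lost — the source is silent).
* **Regions**: incidence multiplied by the synthetic profile; optimal
  strategy chosen at 1/2/3 × regional GDP.

Scenario wrappers are pure transforms — re-running the base case after any
scenario reproduces it exactly.

## Numerical choices

Transition matrices are built vectorised over all 180 cycles and verified
row-stochastic to 1e−10; occupancy mass (including the overdiagnosed
compartment) is conserved to 1e−12. ICERs are compared at full precision
and rounded to 2 decimals only for reporting (costs 2 dp, QALYs 5 dp).
Ties in (cost, QALYs) keep the strategy with fewer screening rounds, then
the narrower eligibility, then the earlier label — a deterministic,
least-intervention rule. Equal sequential ICERs (collinear strategies) are
kept on the frontier. The engine is fully deterministic; all randomness
(PSA only) flows through one seeded `numpy` generator.

## Known limitations

* Former and never smokers are out of scope; eligibility is age + pack-years
  only (no risk-prediction-model eligibility).
* Screen detection preserves the current preclinical stage (no additional
  stage shift beyond earlier detection), and post-diagnosis fatality is
  constant per cycle (no tunnel states or cure fraction).
* Nodule-level management (size cut-offs, Lung-RADS) enters only through
  aggregate early-recall / immediate-referral rates; radiation-induced
  cancers are not modelled.
* The synthetic life table, baseline distribution and regional profiles are
  placeholders: regional and absolute-total outputs indicate qualitative
  behaviour, not calibrated policy estimates.
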
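# Methods

## Model structure

The disease course is a discrete-time Markov chain over four mutually
exclusive DAS28-defined health states: remission (DAS28 ≤ 2.6), low
(2.6 < DAS28 ≤ 3.2), moderate (3.2 < DAS28 ≤ 5.1) and high disease activity
(DAS28 > 5.1); boundary scores belong to the lower state.  Time advances in
cycles of 0.25 years over a default horizon of 20 cycles (5 years).  The
end-of-cycle state is sampled from a 4×4 row-stochastic matrix indexed by
the treatment step in use at the cycle start — the model's central
assumption is that transition probabilities depend only on the current
state and current treatment, not on history, calendar time or patient
covariates.

### Treatment sequencing

A strategy is an ordered escalation ladder of drug steps plus a taper
ladder ending in a medication-free step.  Internally the reversed taper
ladder and the escalation ladder form one *full ladder* from
medication-free up to the most intensive drug, and the treat-to-target
protocol is a deterministic automaton on ladder positions, applied at the
start of every cycle after the first (patients enter on the first
escalation step and keep it for the first cycle):

1. remission increments a sustained-remission counter; when it reaches
   `sustained_remission_cycles` (default 2, i.e. 6 months) the patient
   moves one position down — from an escalation step this lands on the
   preceding drug, from the first escalation step on the reduced-dose taper
   rung, and from the last taper rung on medication-free — and the counter
   resets;
2. non-remission moves the patient one position up (escalation while on
   active treatment, re-escalation after a flare) and resets the counter;
   after the last escalation step fails, patients remain on it.

Medication-free is absorbing under continued remission.  A flare from
medication-free re-escalates one position by default; the alternative of
jumping directly to the step on which sustained remission was last achieved
is available per strategy (`flare_from_free="last_effective"`), since
protocols differ and the choice is not determined by the protocol
description itself.  Any number of escalation/taper rungs, costs and
transition keys can be configured; two presets (step-up, initial
combination) are built in.

### Rewards, half-cycle correction, discounting

Utilities attach to health states (annual weights; one cycle contributes
utility × 0.25 QALY), drug costs attach to treatment steps, and societal
state costs follow

  state cost per cycle = sick days × workforce participation × day cost +
  healthcare consumption cost,

with a default day-of-absence cost of €230 and workforce participation 0.7.
Because transitions can occur at any point within a cycle, state-attached
rewards use the half-cycle (within-cycle) correction: the mean of the
start- and end-of-cycle value.  Drug cost is not corrected — treatment is
fixed within a cycle by construction.  Both corrections can be switched off
(`half_cycle_utilities` / `half_cycle_costs`).  Costs and effects are
discounted at separate annual rates (defaults 4% and 1.5%), compounded per
cycle as (1+r)^(−0.25k); annual stair-step compounding is available via
`discount_compounding="annual_step"`.  The defaults give the closed-form
check: zero rates with unit utilities yield exactly 5.0 QALYs.

### Engines

`simulate_cohort` is a vectorised Monte Carlo microsimulation (default
5,000 patients).  All randomness derives from one generator seeded by the
run configuration; each patient consumes a fixed slice of the draw sequence
(one uniform for the initial state, one per cycle), so a patient's
trajectory does not depend on execution order.  `cohort_expectation`
propagates the occupancy distribution exactly over the finite expanded
space (ladder position × remission counter × health state, plus the
last-effective step where that option is active), applying identical
reward, correction and discounting rules; it serves as a noise-free oracle
the microsimulation is tested against (agreement within Monte-Carlo
standard error at n = 5,000) and as a fast deterministic mode for
comparisons.  A guard rejects expanded spaces above 10^5 cells.

The initial state distribution defaults to 60% moderate / 40% high,
reflecting a DAS28 > 3.2 inclusion criterion; any 4-vector can be supplied.

## Estimation

Visit records (patient id, visit day, DAS28, treatment key, EQ-5D-3L
responses, interval healthcare cost, sick days) are paired into 3-monthly
transitions: for each visit, later visits of the same patient with a gap in
[45, 137] days (91 ± 46, i.e. 3 ± 1.5 months) are candidates and the one
closest to 91 days is taken, ties resolved toward the earlier visit.  The
transition is labelled by the treatment key at the earlier visit.
Probabilities are sample proportions per (treatment key, source state);
source states never observed under a key fall back to a self-transition
row.  Stability over calendar time is checked per row with a Pearson
chi-squared homogeneity test of destination counts before vs after the
median source day; rows with expected cell counts below 5 or with all
transitions on one side are flagged untestable rather than tested.  An
optional label-to-key map pools raw treatment labels (e.g. several dose
levels of one drug) onto a single treatment step before counting, and a
stratified workforce-participation table (e.g. by age and sex) collapses to
the model's scalar via `participation_from_table`.

Per-state utilities are the arithmetic means of tariff-valued EQ-5D
responses grouped by the concurrent DAS28 state; per-state costs and sick
days are the analogous means.  The tariff is a configuration input —
either a full 243-profile lookup or the usual additive decrement form with
any-problem constant and N3 term; the bundled `example_tariff()` is
explicitly synthetic.  Tariff values below 0 (worse than death) are
permitted; the full-health profile anchors to 1.

## Probabilistic sensitivity analysis

Transition rows are given Dirichlet distributions with concentrations equal
to the observed counts plus a unit prior (sparser rows therefore carry more
uncertainty; the prior keeps draws proper).  Utilities, healthcare costs
and sick days are fitted per state by maximum likelihood over candidate
families (normal, gamma, logistic, beta, Poisson), skipping inapplicable
candidates, and selected by the Anderson–Darling statistic computed from
the fitted CDF; chi-squared goodness of fit and skewness/kurtosis are
recorded alongside.  For discrete candidates the probability integral
transform uses the midpoint CDF so their A² values remain comparable with
continuous families on tied count data.  Zero-variance samples degrade to a
flagged point mass.

The PSA draws state utilities and costs from the distributions fitted to
*patient-level* samples.  This follows the described procedure literally
and produces intervals dominated by between-patient spread rather than
standard-error-of-the-mean uncertainty; both interval bases are therefore
reported — percentiles of outer-draw means and percentiles over pooled
individual patients — and neither is privileged.

`run_psa` performs a two-level simulation (default 2,000 outer draws × 200
inner patients): each outer iteration draws one parameter realisation used
by *both* strategies (common parameter draws), simulates each strategy's
inner cohort, and records paired means.  Utility draws are truncated at 1
by resampling; cost and sick-day draws are floored at 0 (gamma/Poisson
draws never need it).  Outputs: per-strategy means and 2.5–97.5%
intervals, the incremental sample cloud, CE-plane quadrant fractions, CEAC
over a willingness-to-pay grid covering €20,000–€100,000, and the ICER of
pooled means with a dominance label.  On the CE plane "cost-effective at
λ" means ΔC ≤ λ·ΔE (the net-benefit rule), which treats all four quadrants
consistently; quadrant assignment puts axis points west/south so fractions
sum to exactly 1.

ICERs are reported from unrounded internals and rounded only for display
(currency to 2 decimals, QALYs to 3); a negative ICER is always
accompanied by its dominance label, since the sign alone cannot distinguish
a dominant from a dominated comparator.

## Synthetic data

The generator emulates a treat-to-target registry: patients enter DMARD-
naive with DAS28 > 3.2 (60/40 moderate/high), are seen every 91 days with
uniform jitter (default ±10 days), and their states evolve by the true
matrix of the treatment step assigned by the same protocol automaton the
engine uses.  DAS28 values are uniform on the occupied state's interval
(high capped at 8.6) so they classify back to the generating state; EQ-5D
responses are per-dimension categoricals, interval costs Gamma and sick
days Poisson, all state-conditional.  Optional missing-completely-at-random
dropout stresses the pairing window.

Scenario truths give every non-remission row the same per-cycle
remission-entry probability r and the remission row stay probability
q = 0.80, so the stationary remission share is r/(r + 1 − q) in closed
form: r = 0.25 (step-up-like, share 0.556) vs r = 0.307 (combo-like, share
0.606) encodes the ~5-percentage-point remission advantage of initial
combination therapy; NULL_EQUAL makes both strategies identical for null
testing.  State-conditional cost means (€250/400/700/1,100 per quarter from
remission to high), sick days (0.5/1.5/4/8 per quarter), drug costs
(csDMARD steps €15–95, biologics €2,900 per quarter) and the synthetic
tariff were chosen once as plausible 2016 Dutch magnitudes.

What the generator does *not* emulate: patient heterogeneity in transition
probabilities, protocol deviations, informative dropout, secular drug-price
or care-price changes, mortality, and HAQ-DI-style progressive
deterioration (long-term tight-control cohorts show stable low disability,
so a deterioration assumption was deliberately not built in).  Passing
tests therefore demonstrate internal consistency and correct parameter
recovery under the model's own assumptions, not external validity on real
registry data.

## Numerical choices and problem sizes

- Cycle and window in days: 3 months = 91, 1.5 months = 46.
- Zero-count transition rows: identity fallback for point estimates,
  +1 Dirichlet prior for PSA draws.
- Row-stochasticity is enforced to 1e-9; occupancy rows sum to 1 to 1e-9.
- The test suite uses two 500-patient × 20-visit synthetic cohorts for
  estimation checks, 5,000-patient cohorts for engine-oracle agreement, 20
  seeded replicates for the dominance property, and 200 × 100 for the
  degenerate-PSA collapse; the acceptance script runs a 1,000 × 200 PSA.
  Transition-recovery error bounds (< 0.05 max absolute error) are asserted
  on rows with ≥ 500 observed transitions, where the binomial standard
  error (≤ 0.022) makes the bound a better-than-2σ criterion; sparser rows
  cannot meet it on sampling grounds alone.
- All simulations are reproducible from a single integer seed; PSA outer
  draws use spawned substreams so results do not depend on loop order.

## Known limitations

- Transition matrices are time-homogeneous within a treatment step; the
  chi-squared stationarity report flags, but does not model, drift.
- The PSA interprets patient-level distributions as parameter uncertainty
  (see above); a standard-error-based PSA would give much narrower
  intervals.
- Estimation treats visits as interval observations only through the
  pairing window; no interval-censored continuous-time estimator is
  provided.
- Costs are taken as already price-indexed; no friction-cost method or
  out-of-pocket expenses.
- Only pairwise strategy comparisons (no multi-way efficiency frontier).
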
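# Methods

## Model structure

Both arms share one state template over eight treatment-pathway states
(initial allocated treatment; well on allocated treatment; symptomatic on
allocated treatment; change to the other treatment; well on the other
treatment; no treatment; surgery; post-surgery), advanced in monthly cycles
for 24 months. "Other" resolves per arm: in the LNG-IUS arm a change means
starting usual medical treatment and vice versa. Structural constraints are
enforced at construction: well-states and post-surgery are absorbing; no
path returns to the allocated treatment once it is left; the symptomatic
state cannot transition to well-on-allocated; surgery lasts exactly one
cycle; a change state must be occupied for at least one cycle before
well-on-other is reachable.

The initial state has no "remain" probability in the source tables, so its
dedicated row is applied exactly once, as the transition out of the initial
state at the end of cycle 1 (`settings.initial_row_cycles`, default 1,
re-applies it for k cycles for exploration). The initial row's printed
symptomatic destination is taken at face value; the stated assumption that
first-cycle movers do not become symptomatic is treated as a data-coding
rule already reflected in the counts, not as an extra structural zero.

## Transition parameters

Non-fixed rows are parameterised by observed transition counts; the
deterministic probability is `count / row total` and the same counts serve
as Dirichlet concentrations in the PSA. Count-derived rows agree with the
printed three-decimal probabilities for every internally consistent row
(verified in the tests) while summing to one exactly, which printed rows do
not (two first-cycle rows print to 1.001 and 0.999). One row is internally
inconsistent in the source: the LNG-IUS-arm no-treatment row prints
(0, 0.984, 0.016) but carries counts (1, 540, 10). There the printed vector
is used deterministically and the counts only in the PSA, both retained in
the configuration.

## Utilities and QALY accrual

Per-state annual utilities come from EQ-5D-3L or SF-6D instrument tables,
with Beta(α, β) PSA parameters per state and arm. One printed value is
irreconcilable with the rest of the table: "well with LNG-IUS" is printed
as 0.98 but its own Beta(1169, 297) has mean 0.797, and with 0.98 the
LNG-IUS arm's total QALYs overshoot every published total by ~0.23. The
packaged default therefore uses the Beta mean (flag `use_beta_mean`; the
printed value remains available by removing the flag). Surgery utilities
are "linked to post-surgery": never sampled independently, a surgery draw
is the post-surgery draw scaled by the ratio of the point values.

Each cycle contributes one twelfth of the end-of-cycle occupancy-weighted
utility, discounted at the cycle end. In addition, the reference
configuration accrues one undiscounted entry month at baseline in the
initial state (`settings.entry_month_accrual`, default on). This
25-time-point accrual — baseline plus 24 month-ends, each worth one month —
is the only convention that reproduces all four published per-arm QALY
totals (EQ-5D 1.580/1.513, SF-6D 1.198/1.200) to ±0.002; with it off the
model follows the strict 24-cycle reading and satisfies the exact
closed form QALYs = horizon/12 at zero discount rate and unit utilities.
No half-cycle correction is applied. Discounting is 3.5% per year, applied
as a smooth per-cycle factor `(1.035)^(−t/12)`; an annual-step convention
(year 1 undiscounted) is available as `settings.discount_convention`.

## Costs

All costs are 2011 GBP from a UK NHS perspective. Attachment rules
(each a named, configurable ledger entry):

* entry (cycle 0, whole cohort): GP consultation £26.67; plus the LNG-IUS
  insertion bundle (GP 20 min £53.33, nurse 20 min £17.00, device £88.00,
  sterile pack £21.63) in the LNG-IUS arm;
* reviews charged to occupancy still on the allocated treatment: 6-week
  review (≈ cycle 1) in the LNG-IUS arm, 3-month review (cycle 3) in both
  arms, GP 10 min each;
* discontinuation charged to flow out of the allocated-treatment states
  into change/no-treatment/surgery: £38.94 (GP + nurse + removal pack) in
  the LNG-IUS arm, £26.67 in the usual-treatment arm;
* surgery £1720.18 charged to inflow into the surgery state;
* switching: inflow into "change to other" is charged the other
  treatment's initiation (full insertion bundle when changing to LNG-IUS;
  a consultation when changing to usual treatment);
* prescriptions: the six listed drug pack prices are averaged with equal
  weights (the original prescribing mix is not recoverable) and treated as
  a ~3-month supply — several of the listed products are genuinely
  quarterly packs (Cerazette 3×28, Microgynon 3×63, 12-weekly
  Depo-Provera). The per-cycle charge (pack/3 ≈ £2.76) attaches to
  start-of-cycle occupancy of medical-treatment states: drugs are
  dispensed at treatment initiation for the month ahead. Both the
  months-per-pack and the timing are configurable; a monthly full-pack
  charge raises the usual arm's total by ~£80 and was rejected because it
  is pharmacologically implausible for these products and inconsistent
  with the published totals.

Under these defaults the deterministic base case gives £441.31 / £337.02
per woman (LNG-IUS / usual), incremental cost £104.30 (rounding to the
published £100), and an EQ-5D ICER of £1,580 per QALY against the published
£1,600 — which is itself inconsistent with the published rounded values
(100/0.067 ≈ 1493), having been computed on unrounded totals.

## Sensitivity analyses

* **SA1** replaces means by medians. Medians are not published; they are
  populated from estimation (synthetic or user data) or configuration, and
  the transform errors if any are missing.
* **SA2** applies the national costing-template staffing: by the literal
  reading (default) a practice nurse carries out the 10-minute initial
  consultation and insertion; a second documented reading keeps a GP
  present at 10 minutes alongside the nurse. Both add the 6-week nurse
  review (LNG-IUS only) and annual GP follow-up at months 12 and 24 for
  women on any treatment. Because a nurse is cheaper than a GP, every
  reading lowers the LNG-IUS arm's cost relative to base — the published
  SA2, whose costs *rise* in both arms and whose ICER increases to £1,640,
  evidently used the template's own unit prices, which are not published.
  This model reports what the described changes actually imply
  (ICER ≈ £740 under the default reading).
* **SA3** assigns questionnaires dated on a treatment-change day to the
  prior state instead of the new one. The generator's convention is that
  such a questionnaire reflects the month just lived, i.e. the prior
  state, so base-case (subsequent-rule) state means are mixed with a
  little inflow from their upstream states. The packaged deterministic SA3
  inverts that mixing in closed form — the large-sample limit of
  re-estimation under the prior rule — by solving the linear system that
  maps clean means to subsequent-rule means over the observation months
  (surgery, having a one-cycle dwell and no stayers, is eliminated via its
  linkage to post-surgery; otherwise the system is singular). A
  data-driven mode applies the paired shift estimated from supplied
  pathways instead, and converges to the closed form as the cohort grows
  (tested at 40,000 women). EQ-5D SA3 gives an ICER of ≈ £1,612 (published
  £1,560; the published text and table themselves disagree, £1,510 vs
  £1,560). The SF-6D SA3 ICER is not reproducible even in sign: it divides
  by a QALY difference in the fourth decimal, below the resolution of the
  three-decimal published utilities.
* **SA4** swaps the utility instrument to SF-6D; per-arm costs are
  bit-identical to base case.

## Probabilistic sensitivity analysis

1000 draws by default. Per draw, all non-fixed transition rows (including
the first-cycle row) and all utilities are redrawn jointly; fixed rows and
costs are never perturbed (no cost distributions are published). States
appearing in both arms' utility tables are sampled independently per arm,
matching the tables' separate (α, β) pairs. CEAC probabilities are the
fraction of draws with positive incremental net monetary benefit; exact
ties count half to each arm, so the two curves sum to one identically.
Note that because transition draws move surgery and switching flows, the
incremental *cost* also varies across draws even though unit costs are
fixed — at a zero threshold the probability that usual treatment is
cost-effective is therefore slightly below 1 (≈ 0.99), not exactly 1.

## Synthetic trial generator

The generator emulates the study conditions: women are simulated through
the truth transition model for 24 monthly cycles (default 285 per arm,
matching the 571 randomised in the source trial) and questionnaires are
drawn at months 0, 6, 12 and 24 from Beta distributions with mean equal to
the occupied state's utility and variance `d·m(1−m)` with dispersion
`d = 0.04` (individual-level SD ≈ 0.09 at these utility levels, a
realistic between-woman spread for preference-based instruments; the
source reports no individual-level noise model). Optional
missing-completely-at-random dropout is off by default. The generator does
not emulate contraceptive-preference strata, exclusion criteria,
informative dropout, or within-woman correlation of repeated
questionnaires — so recovery tests demonstrate estimator consistency under
the model's own assumptions, not robustness to real-data violations of
them.

Verification sizes (chosen to make Monte Carlo error small relative to the
tolerances): transition-probability recovery at 5,000 women (±0.02);
full simulate→estimate→rebuild loop at 5,000 women per arm (±2% on
discounted costs and QALYs); cohort engine versus an independent
individual-level microsimulation at 200,000 women per arm (within 3 Monte
Carlo standard errors); distribution sample means at 10,000 draws (±0.01).

## Numerical choices and edge cases

Occupancy conservation is enforced to 1e-9 every cycle. QALY accrual sums
with `math.fsum` and divides by 12 once, so the zero-rate unit-utility
closed form is exact in floating point. Dirichlet sampling treats zero
counts as structural zeros (excluded from the draw, always zero in the
sample). Beta method-of-moments fitting falls back to a flagged Beta(1, 1)
when the sample variance is zero or exceeds the Bernoulli bound. Utility
estimation averages per observation by default; per-woman averaging is
available. States with no observations are flagged, never silently
defaulted. Equal QALYs with unequal costs yield an explicit "equal effect,
cheaper arm preferred" verdict rather than a dominance claim; the report
layer prints it as dominance with a footnote flag, mirroring the published
table style.

## Known limitations

The published base-case cost attachment is under-specified; the defaults
here were chosen from the documented alternatives as the reading that is
clinically sensible and consistent with the published totals, and each is
individually switchable. The published SA2 cannot be reproduced from
published inputs (see above). Five-year extrapolation, societal costs,
baseline-imbalance adjustment, instrument scoring algorithms
(EQ-5D tariffs, SF-36→SF-6D) and subgroup analyses are out of scope;
utilities are consumed as state-level weights.
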
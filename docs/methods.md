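# Methods

## 1. The cohort engine

Both models are discrete-time Markov cohort models evaluated by expectation:
a state-occupancy vector is propagated through per-cycle transition matrices
and multiplied by per-cycle rewards on independent named channels.  The
engine (`carecase.engine`) is generic; the two clinical models are thin
builders that emit a `TransitionModel` (states, absorbing set, cycle-indexed
transition law) and a `RewardSchedule` (state rewards, one-off transition
rewards, death-cycle fraction).

**Reward timing.**  Rewards are credited at the end of each cycle on the
post-transition state; one-off transition rewards are credited on the flow
taking that transition.  There is no half-cycle correction.  Consequently a
survival channel paying 1 per live cycle under a constant death hazard p
yields the geometric sum Σ_{t=1..n}(1−p)^t — with p = 0.01 over five years,
4.85199 — and this closed form is asserted in the tests as the no-disease
limit of the screening model.

**Death-cycle utility credit.**  A transition from a live state into an
absorbing state additionally credits `death_cycle_fraction` (default 0.5) of
the source state's current utility reward: people who die during a cycle
still accrue part of that period's quality-adjusted time (half a year, or 15
days of a month).  The fraction applies to the utility channel only; the
survival/life-expectancy channel deliberately counts whole completed cycles.
The 0.5 default is exact for the asthma model's stated 15-days rule and is a
documented convention for the annual screening model, where no fraction is
published.  Only QALY *levels* are sensitive to it; scenario differences are
not.

**Numeric conventions.**  Config-supplied probability vectors may deviate
from sum 1 by at most 1e-6 (printed-table rounding); they are then rescaled
exactly, and transition rows must sum to 1 within 1e-12 at validation.
Larger deviations are errors, never silently renormalized.  A per-cycle
discount-rate parameter exists and defaults to 0 (the shipped analyses apply
none).

**Micro-simulation oracle.**  `run_microsim` simulates individual
trajectories of exactly the same process (same matrices, same reward
tensors), deterministically for a given seed.  Because transition one-offs
are expected values conditional on (cycle, source, destination), the
simulator's means converge to the cohort expectations; the test suite
asserts agreement within 3 standard errors at n = 200,000 for every shipped
model configuration.  This is the package's standing defence against
book-keeping errors in either evaluation route.

## 2. Breast-cancer screening model

**States.**  `well_<pattern>` for the four persistent screening patterns
(annual; biennial; sporadic = one mammogram in five years; none),
`remission_I..IV` by stage at diagnosis, `progressive`, `dead`.  Annual
cycles, horizon five years.  The initial distribution is the pattern mix for
the scenario's two-year screening rate.

**Pattern mix.**  The tabulated mixes are used for the 70% and 80% scenarios.
Other rates solve {sum = 1; biennial = 2·annual (observed 2:1 ratio);
annual + biennial + 0.4·sporadic = rate; sporadic:none = 0.270:0.138}.
The 0.4 factor is the probability that a once-in-five-years screener falls
inside a two-year measurement window.  Rates below ≈0.265 are infeasible
(annual would go negative) and raise an error naming the binding constraint.
Biennial women screen in cycles 1, 3, 5; sporadic screening is implemented
as 1/5 of the sporadic group per cycle (uniform phase — the source fixes the
pattern but not its phase, and a uniform phase privileges no year).

**Incidence and stage at diagnosis.**  Detection is per *cycle type*, not a
flat pattern attribute: in a screened cycle, cancers are found per mammogram
(.003 annual/biennial, .005 sporadic) with the screened stage distribution
(annual/biennial: the Jacobellis–Cutter distribution; sporadic: the Yood
managed-care distribution); in any unscreened cycle — including biennial
off-years and the 4/5 of sporadic women not screening that year — cancers
surface clinically at .008 with the markedly later unscreened distribution
(.04/.32/.43/.13/.08).  This screened-vs-unscreened asymmetry *is* the
stage-shift mechanism, and the higher clinical-detection rate reflects the
prevalent pool of undetected disease.

**Diagnosis year.**  A diagnosed woman is treated within the cycle: she
incurs the stage-specific initial treatment cost, a treatment disutility
(−.10/−.20/−.25/−.25 as a transition reward), stage-specific missed work
days, and the treatment-year employment probability.  The year ends in
remission (probability .975/.94/.81/.66 by stage), or in non-remission,
which resolves through the progressive-disease death probability .79 —
death that year, else the progressive state.  In-situ diagnoses carry no
cancer mortality, return to the well state, and default to zero treatment
cost (none is published; configurable).

**Later years.**  From `remission_s`, recurrence occurs with probability
1 − continued-remission(s); a recurrence ends in cancer death with
probability rate_s / (1 − c_s), derived so the annual cancer death rate out
of remission equals the published per-stage calibration exactly
(.0075/.03/.126/.264) — the printed flat .79 cannot reproduce those rates
and is applied to the progressive state instead, where it is labelled.
Recurrence survivors enter `progressive` (utility .40, employment .56,
$33,000 and a treatment-year's missed days per year, death hazard .79).
Other-cause mortality .01/year applies to everyone first.

**Absenteeism.**  Missed days in the treatment year are the published
44.5-day mean split by stage severity (11/34/46/69/92 days for in
situ/I/II/III/IV; the split is a package assumption chosen so the base-case
expectation is ≈44.5; progressive years use the stage-IV value).  Days are
weighted by the employment probability of the state in which they occur:
the day estimates come from women remaining employed, and women who leave
the workforce are costed separately through the turnover channel (expected
exits = diagnosis and progression events weighted by 1 − employment
probability, × $14,627 each).  Absenteeism cost = days × 8 h × $21.31.

**False positives (variants only).**  Each mammogram in a cancer-free woman
triggers $533 of follow-up with probability .10.  The rescreen variant
raises a woman's subsequent per-cycle screening probability by 10% relative
after a false positive; at the cohort level this is tracked as a
prior-false-positive fraction per pattern, and only binds for the sporadic
pattern (annual/biennial per-cycle probabilities are 0 or 1).

**Sensitivity variants I–IV** interpolate the screened stage distributions
between the pessimistic corner of the published ranges
(.04/.32/.43/.13/.08 — coinciding with the unscreened distribution, i.e. no
stage-shift benefit) and the optimistic corner (.21/.57/.16/.04/.02), at
weights 0, 1/3, 2/3, 1.  The originally published variant definitions are
not available in full; interpolation preserves the intended
pessimistic-to-optimistic ordering, which corner *combinations* do not
(improving only the sporadic distribution lowers the measured gain, because
raising the screening rate moves women out of the sporadic group).  The
variants are reconstructions and are labelled as such.

## 3. Asthma medication model

**States.**  (medication status on/off) × (event category this month: none,
office-visit exacerbation, ER/urgent-care, admission) plus `dead`; monthly
cycles, horizons 12–60 months.  Event categories are mutually exclusive
within a month, with "none" taking the residual probability.  Medication
halves event probabilities (.27/.0382/.0035 on medication vs
.53/.0756/.0069 off).

**Month sequencing.**  In month 1 the assigned medication status applies and
events are drawn; from month 2 onward, next month's status follows the
persistence law conditioned on (status, event category last month), then
events are drawn under the new status.  Asthma deaths occur only out of the
ER (.0002) and admission (.0014) branches; other-cause mortality is
.0001/month; the death month accrues half the pre-death monthly utility and
carries the event's cost and missed days as one-off rewards.

**Persistence and scenario rates.**  The published persistence sets were
chosen so the cohort-level use rate stays essentially constant at each
scenario rate; the 70% and 90% sets are published alongside the 80% base
and ship as presets (their lumped fixed points are .708/.806/.903 — the
slight upward drift from each starting rate matches the intended
gradually-rising adherence).  For other rates (including the 60% scenario)
the package keeps the base with-medication persistence and rescales the
off-medication restart probabilities after exacerbation-level events so the
lumped two-state chain r' = rS + (1−r)G has its fixed point at the scenario
rate.  These solved tables are reconstructions; holding persistence fixed
across scenarios instead would let every scenario drift to the same ≈.806
fixed point and erase the scenario separations entirely.

**Rewards.**  Monthly utilities by (status, event) are taken as published
(they are consistent with daily utilities .92/.91/.72 on a month =
30/365-year scale, asserted in the tests).  Adults have 21.67 attendable
days/month (2080-hour work year), children 15 school days/month (180-day
school year smoothed over 12 months; seasonality is out of scope).  Missed
days per event month: 3 (exacerbation), 4 (ER), 7 (admission).  Direct cost
= event cost (155.44 / 1,080 / 13,512) plus $112 in every month spent in a
medication-using state.  Child indirect cost applies a configurable
parent-workday ratio (default 1.0 — one parent work day per school day
lost).

## 4. Economics

Absenteeism cost is linear: days × hours/day × hourly wage (8 × $21.31
defaults).  Annual turnover cost = 33% × wage × 2080 h = $14,627 (rounded
only for reporting).  Business-case rows report deltas (improved − baseline),
so savings are negative; totals are always computed from components.  The
asthma rows of the comparison table follow the published convention of
reporting exacerbation-related cost savings in the direct column, with the
net figure (after added medication cost) carried in the metadata.  Full
precision is kept internally; rates print to 5 decimals and money to 2 only
at the reporting layer.  No discounting is applied.

## 5. Known gaps and limitations

* **Life-expectancy level.**  The published base-case five-year life
  expectancy (4.85705 at the 70% rate) *exceeds* the no-cancer ceiling
  Σ(1−.01)^t = 4.85199 implied by its own other-cause mortality under
  end-of-cycle accrual, so it cannot be reproduced exactly from the
  published inputs under any consistent accrual we could construct; this
  package's level (≈4.8417) reflects the cancer mortality needed to
  approach the published scenario *differences*, which are the
  decision-relevant quantities and are reproduced within their bands.
* **QALY level.**  With the half-cycle death credit, the model's QALY level
  sits slightly above its life-expectancy level (death years contribute ½ a
  utility unit but zero survival units).  The published QALY levels sit
  below life expectancy, implying no death-year credit in that channel
  despite the stated part-year rule; differences are insensitive to the
  choice.
* **Turnover attribution.**  The published with-turnover indirect delta
  (−$140) is not recoverable from any exit-counting scheme we constructed
  (ours gives ≈−$28); the turnover channel is computed from first
  principles and reported as such.
* **Under-specified splits.**  The stage split of the 44.5 mean missed
  days, the in-situ treatment cost (default 0), the within-year death
  fraction for the annual model, and the 60% persistence set are documented
  package assumptions, each exposed as configuration.
* The synthetic nature of the cohort — a fixed, fully employed,
  single-wage workforce with homogeneous risks — means passing tests show
  internal consistency and faithful parameter transcription, not predictive
  accuracy for any particular employer population.  Real claims data would
  add heterogeneity in wages, employment, severity, and adherence that the
  models deliberately average over.
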
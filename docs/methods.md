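# Methods

## Model structure and assumptions

The model is a cohort state-transition (Markov) model. The living state
space is the product of four NYHA functional classes with four treatment
lines — active drug (mavacamten ± BB/CCB), BB/CCB monotherapy, a septal
reduction therapy (SRT) tunnel occupiable for exactly one cycle, and
post-SRT — plus an absorbing dead state (17 states). The cohort enters at
age 42, 71.60% male, split 76.54% / 23.46% over NYHA II / III, entirely on
the arm's initial line (active drug in the treatment arm, BB/CCB in the
control arm).

Time runs on a mixed grid: ten trial-phase cycles of (4,2,2,4,2,4,2,4,2,4)
weeks matching the trial's clinical assessment points, then uniform 28-day
cycles (the dosing interval) to the horizon age of 100 years. Within a
cycle the engine applies death, then NYHA transitions of survivors, then
switching flows that take effect the next cycle. This order is a modelling
choice (the source analysis does not state one); it is fixed and documented
so results are exactly reproducible, and switching decisions use the
post-transition NYHA class, consistent with discontinuation being triggered
by an observed worsening in the cycle just completed.

### Transitions

* Weeks 0–30, treatment arm: the ten published interval matrices. States
  with no trial occupants are published as "NA" rows; they are stored as
  identity rows with an `observed = False` flag and the engine raises if
  mass would flow through a flagged row during the trial phase.
* Weeks 30–106, treatment arm: the final (week 26→30) matrix carried
  forward unchanged, NYHA IV row absorbing. No natural-progression overlay
  is applied in this window — the published 30–106-week matrix is used
  exactly as printed. (The source text is ambiguous on whether progression
  should also act here; we follow the printed matrix.)
* Beyond week 106, and for BB/CCB and post-SRT lines after week 30: an
  upper-bidiagonal natural-progression matrix — stay with 1−p, worsen one
  class with p = 0.0034 per cycle, NYHA IV absorbing. Improvement is
  impossible by construction, implementing the assumption that untreated
  NYHA class does not improve outside the trial phase.
* SRT tunnel: the published single-cycle surgical-efficacy matrix
  (III→II 0.3871, IV→III 0.3548), after which everyone moves to post-SRT.

One printed row (week 6→8, NYHA II: 0.0426/0.9362/0.0213) sums to 1.0001
due to rounding; observed rows are renormalised at construction when their
printed sum is within 5×10⁻⁴ of 1, which preserves the printed proportions
and restores row-stochasticity to 10⁻¹².

The annual natural-progression rate of 4.55% converts to ≈0.00356 per
28-day cycle under the constant-hazard formula, yet the published per-cycle
value is 0.0034; no standard convention reproduces it. The printed 0.0034
is taken as the canonical default, and the conversion formula is used only
for quantities with no printed per-cycle value (the SRT escalation and SAE
discontinuation rates, and the progression-rate bounds in the sensitivity
analyses, obtained by converting the annual 95% CI of 3.70–5.48%).

### Mortality

Background mortality comes from an age- and sex-specific life table,
weighted by the fixed baseline male fraction (no renormalisation as the
sexes die at different rates — a cohort-level approximation consistent with
a single weighted life table). The NYHA hazard ratios (1.00, 1.80, 4.12,
10.90) multiply the background hazard, not the probability:
`p_cycle = 1 − exp(ln(1−q)·hr·Δt/365.25)`. This keeps probabilities in
[0,1] even for HR 10.90 at old ages and makes NYHA I exactly
general-population mortality. Age is looked up by completed integer years
at cycle start. The SRT tunnel cycle adds an independent ~1.80% procedural
risk: `1 − (1−p_background)(1−0.018)`.

### Switching rules

During the first 30 weeks nobody switches. At the end of the week-30 cycle,
trial non-responders leave the active drug by post-transition class
(default 100% of NYHA III/IV, 0% of I/II — the published analysis applied
unprinted trial-based proportions; ours is the natural all-or-nothing
reading and is fully configurable). From week 30 on, each cycle:

* active-drug mass whose NYHA class worsened this cycle moves to BB/CCB
  (flow-level bookkeeping, exactly equivalent to per-patient memory because
  transition probabilities depend only on the current class and line);
* non-worsened active-drug mass moves to BB/CCB with the per-cycle
  equivalent of 5%/year (serious adverse events);
* BB/CCB mass escalates to the SRT tunnel with the per-cycle equivalent of
  the class-specific annual proportions (16.37/21.40/32.80/39.26%),
  evaluated at the post-transition class;
* tunnel mass moves to post-SRT. Post-SRT patients behave as BB/CCB
  patients and remain eligible for repeat SRT (configurable off), since the
  pathway returns them to BB/CCB-equivalent care and repeat procedures are
  not excluded.

### Outcomes

Start-of-cycle occupancy accrues the full cycle length (no half-cycle
correction by default; a config switch enables the mean-of-endpoints
variant). LYs sum alive occupancy × cycle years; QALYs weight by the NYHA
utilities (0.905, 0.845, 0.687, 0.687 — class IV assumed equal to III).
Both are discounted at 5%/year with the factor evaluated at cycle-start
time, and split by the NYHA class occupied during the cycle.

## Sensitivity analyses

**DSA** re-runs the two-arm comparison at each parameter's lower and upper
95% bound, all else at base case, ordering parameters by the width of the
incremental-QALY range (stable name tie-break). Bounds with no published CI
use SE = 10% of the point estimate; infeasible bounds are clamped to the
probability simplex with a logged warning.

**PSA** draws all parameters jointly per iteration: every observed
transition-matrix row from a Dirichlet with concentration = probability ×
effective sample size (54 for treatment-arm trial rows, 27 for control
rows — the trial arm sizes; 752 for the surgical matrix, the N of its
source study); proportions and utilities from Betas; hazard ratios from
Lognormals with median at the point estimate. Beta parameters are
initialised by moment matching (mean = point, SD = CI width/3.92) and then
refined so the fitted 2.5th/97.5th percentiles reproduce the published
interval — pure moment matching misses the skewed escalation-rate
intervals by up to ~4%, and the implied-percentile accuracy is the
property the tests enforce (<1% relative error). Parameters at a boundary
point mass (the week-30 NYHA III proportion of 1.0) admit no Beta and are
sampled degenerately with a warning. The published analysis used 5,000
iterations; the bundled driver defaults to 500 and the acceptance script to
400, which pins the PSA means to well within the Monte-Carlo noise of the
quantities reported.

## Synthetic inputs

Two inputs are generated because the originals are unavailable:

* **Life table.** Gompertz–Makeham hazards
  h(a) = λ + s·k_sex·e^{γa} with λ = 8×10⁻⁴/yr, s = 2.1336×10⁻⁵/yr,
  γ = 0.095/yr, and a male multiplier of 1.681 on the senescent term,
  calibrated once so life expectancy at birth is ≈80 (female) / ≈75 (male)
  years, emulating a modern Chinese national life table; qx capped at 1 and
  forced to 1 at age 100. It reproduces aggregate longevity, not the
  age-specific accident hump or infant-mortality structure of a real census
  table, so absolute LY levels carry that approximation.
* **Control-arm trial matrices.** For each of the ten intervals, rows with
  modest improvement probabilities (3–10%) before the week-18 plateau and
  stay/worsen-only rows (worsening ≤3%) after it, NYHA IV absorbing, all
  rows observed, deterministic in the seed. These are structural
  placeholders: passing tests demonstrate the engine handles the published
  pathway correctly, not that the control arm's true short-term dynamics
  are recovered.

Because of these stand-ins (plus the unprinted week-30 discontinuation
proportions), the published headline values are not exactly recoverable;
the test suite checks a plausibility band and sign constraints instead
(README).

## Validation

The central correctness property is agreement between two independent
implementations of the same rules: the cohort engine (deterministic mass
flows) and a 200,000-patient microsimulation that carries literal
per-patient memory (previous class, one-cycle tunnel, week-30 boundary) and
shares only the per-cycle probabilities. They agree within 3 Monte-Carlo
standard errors at the default parameter set and across 10 random valid
parameter sets. A degenerate configuration (identity matrices, HR ≡ 1, no
switching, no discounting) reproduces the life table's discrete life
expectancy from age 42 to 10⁻⁹, and natural-progression matrix powers match
brute-force path enumeration.

## Numerical choices and limitations

Mass conservation is enforced to 10⁻¹⁰ every cycle; the trace stops early
once alive mass falls below 10⁻⁹. Row-stochasticity is enforced to 10⁻¹²
after renormalisation. 365.25 days/year throughout. Costs and ICERs are out
of scope (no cost inputs exist in the parameter set), as are adverse-event
disutilities and re-estimation of matrices from patient-level data. The
carry-forward of the week 26→30 matrix to week 106 and the no-improvement
assumption afterwards are structural assumptions inherited from the source
analysis, not empirical claims of this package.
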
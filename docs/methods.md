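# Methods

## Model structure and assumptions

The decision problem is a two-strategy comparison (DRd vs KRd triplet
therapy in relapsed-refractory multiple myeloma) over a three-state Markov
cohort: progression-free (PFS), post-progression (PD), Death. Monthly
cycles, 120-cycle (10-year) horizon, whole cohort starting in PFS.
Assumptions inherited from the modelled treatment pathway:

- no treatment discontinuation before the planned duration (DRd 25 cycles,
  KRd 18 cycles); after the planned period, progression-free patients
  receive supportive care only;
- no recovery from PD, death absorbing;
- time-homogeneous (exponential) baseline hazards. Nothing about the
  shape of the underlying survival curves is published, so constant
  hazards are the minimal assumption and make hazard-ratio application
  exact rather than approximate.

Within a cycle the two competing exits from PFS are composed with death
taking precedence: `P(death) = 1 − e^(−r_d)`,
`P(progress) = e^(−r_d)(1 − e^(−r_p))`, `P(stay) = e^(−(r_p + r_d))`.
Rows are exactly stochastic, and the marginal death probability transforms
exactly under a hazard ratio (`1 − (1 − p)^HR`).

## Hazard identification and calibration

Three baseline hazards must be identified from a single published scalar
(the comparator arm's undiscounted restricted life-years, 3.52). Two
structural ratios close the gap, both exposed in configuration and covered
by the sensitivity machinery:

- `progression_median_months = 26` fixes the progression hazard
  (`r_p = ln 2 / 26 ≈ 0.0267`/month), an order of magnitude typical for
  modern triplet regimens in this population;
- `pd_to_pfs_mortality_ratio = 2` encodes excess post-progression
  mortality.

The remaining mortality scale is found by Brent root finding on the log
scale (bracket `[1e-6, 5]`/month, `xtol 1e-8`) against the cohort engine
itself; the calibrated comparator arm reproduces 3.52 life-years to
`1e-6`. Calibration is deterministic and idempotent, and parameter
recovery from synthetic targets is tested. The resulting baseline is
`r_p = 0.02666`, `r_die_PFS = 0.01545`, `r_die_PD = 0.03089` per month.

The overall-survival hazard ratio is applied to both death transitions;
the progression HR to the progression transition only. Strictly, a
progression-or-death HR also covers death-before-progression, so a config
switch (`hr_pfs_includes_pfs_death`) applies the PFS HR to PFS→Death
instead, with the OS HR then acting on PD→Death only. With the default
wiring the intervention arm yields 5.91 life-years against the published
5.86 (+0.9%) with no further tuning.

## Discounting

Annual rates are 7.2% (costs) and 3% (outcomes); life-years are reported
undiscounted. The compounding basis is configurable:

- `annual`: the conventional `(1 + r)^(−t/12)` per monthly cycle t;
- `per_cycle`: the annual rate applied once per cycle, `(1 + r)^(−t)`.

The shipped configuration uses `per_cycle`. Under conventional
compounding the model's discounted QALYs are ≈ 2.3 (KRd) and ≈ 3.6 (DRd),
far from the published 1.28 and 1.56, and no utility set bounded by the
published inputs can close that gap. Under per-cycle compounding the model
yields 1.17 and 1.51 — reproducing both published QALY totals to within a
few percent *and* their otherwise puzzling pattern of a lower QALY/LY
ratio in the longer-lived arm (longer survival is discounted more
heavily). We therefore treat per-cycle compounding as the convention the
published totals embody and make it the default, while noting it is not
the textbook convention; switching to `annual` changes only the discounted
totals, not the life-year results or any calibration.

Discounting uses end-of-cycle timing with 1-based cycle indices. A
half-cycle (trapezoid) correction is available (`half_cycle_correction`)
and off by default.

## Dosing and costs

28-day cycles; "once weekly" = 4 administrations per cycle, "every
2 weeks" = 2, "every 4 weeks" = 1, validated in tests against an
independent absolute-calendar-day enumeration (daratumumab totals 35
administrations over 25 cycles; carfilzomib 96 over 18; dexamethasone 4
and lenalidomide 21 per cycle in both arms). Each administration is
charged `units_per_administration` (default 1) of the unit price — the
"400 mg per kilogram" dosing phrase in the source is treated as an
erratum for the 400 mg vial, since weight-based vial counts are
irreconcilable with the published cost totals. No vial sharing, wastage or
body-size individualization.

Per-cycle cost = drug cost + configured per-cycle components
(administration, specialist visit, laboratory tests while on treatment;
a supportive-care basket in post-treatment PFS; visits, labs and a
fraction of imaging/radiotherapy in PD). Adverse events contribute an
expected cost (and disutility) per on-treatment cycle: AE probability ×
(AE treatment + toxicity management cost). Component frequencies are not
published; the shipped values are modest clinic-visit frequencies, and
their absolute level is absorbed by the cost-scale calibration below.

Lifetime costs are linear in every unit price — the property the tornado
analysis and the price-threshold search exploit.

**Cost-scale calibration.** The published lifetime totals ($15,370 DRd,
$15,106 KRd) are not decomposed, and a bottom-up costing of the stated
calendars makes the KRd drug bill roughly twice DRd's — the published
near-equal totals cannot be recovered from unit prices alone. Each arm
therefore carries a multiplicative cost scale calibrated (exactly, by
linearity) so its discounted lifetime total matches the published value;
the scales are frozen at base case and *not* refitted in sensitivity
analyses, so price uncertainty still propagates. Removing
`cost_target_usd` from an arm's configuration disables its calibration
(scale 1).

## Distribution fitting

Beta and gamma distributions are fitted by matching the mean exactly
(beta: mean-anchored concentration; gamma: mean-anchored shape) and
minimizing squared error of the 2.5%/97.5% quantiles against the published
95% CI over the one remaining free parameter (bounded scalar optimization
on the log scale). Disutilities are fitted as beta on |value| and negated
on sampling. Hazard ratios are lognormal with
`σ = log(high/low)/(2·1.96)` from the log-symmetric CI and the log-mean
shifted (`μ = log m − σ²/2`) so the arithmetic mean matches the point
estimate exactly. Parameters flagged `fixed` (age, sex, cycle length,
horizon, discount rates) never enter DSA or PSA.

## Sensitivity analyses

- **One-way DSA**: every varied parameter pinned to its 95% bounds
  (±20% when no CI exists), full pipeline rerun, entries ordered by the
  range of incremental NMB (ICUR carried as a secondary metric; the
  published tornado's metric is unlabeled). The two chemotherapy unit
  prices dominate the tornado, as published.
- **Price thresholds**: Brent bisection to $0.01 on incremental NMB
  (cost-effectiveness threshold) or incremental cost (dominance
  threshold); verified against the closed-form linear solve. At the
  shipped inputs the daratumumab price may rise only to ≈ $278 (from
  $274.20) before DRd stops being cost-effective, and a drop below
  ≈ $268 makes DRd strictly dominant — the same "a few dollars either
  way" knife-edge the published analysis describes.
- **PSA**: 10,000 draws (configurable), every varied parameter sampled
  independently (no correlation structure is published); hazard-ratio
  sampling can be disabled (`vary_hazard_ratios_in_psa`). Baseline
  hazards and cost scales are not recalibrated per draw — the calibration
  targets are point estimates, and uncertainty enters through the
  sampled HRs, utilities and prices. Invalid draws (out-of-range derived
  utilities/probabilities) are resampled with a logged count (none occur
  at the shipped inputs). At the default seed the acceptability at
  $1290/QALY is 0.54 (published: 55%), the CEAC switch point is ≈ $800
  (the source reports a switch point of ≈ 810, printed with a mixed
  currency symbol), and essentially all draws show a QALY gain. Roughly
  half the draws are costlier for DRd, whereas the source describes all
  draws as costlier; with near-equal arm cost totals and independent
  price sampling a sign-definite incremental cost is not reproducible,
  so quadrant shares are reported rather than asserted.

## Budget impact

Five years, no discounting, no inflation. Population projected at a
constant 1.20%/year (the rate implied by the published 2022→2023 ratio;
it reproduces all five published population figures within integer
rounding). Patient counts anchor on the published 2022 figures (4,267 MM
patients; 3,456 after the death-rate adjustment; 20% eligible → 691) and
scale with population growth; a `rates` mode recomputes counts from
incidence (1.8/100k) + prevalence (3.27/100k) instead, which yields 4,327
in 2022 — the published table is internally anchored, not rate-derived.
Published count rows are not perfectly self-consistent (2023 eligible
prints 700 where the unrounded chain gives 699.49; 2025 MM patients print
4,423 vs 4,422.5); tests assert only the exactly reproducible anchors.
Per-patient annual costs are back-solved from the published year-1
scenario totals ($14,845.73 KRd; $26,379.50 DRd) and are deliberately
distinct from the Markov model's lifetime totals (different time basis).
The published yearly scenario totals are carried in the configuration so
the yearly impacts and the 5-year total ($6,170,582) can be rebuilt
exactly; the model-mode totals agree with them to < 0.05%.

## Microsimulation oracle and synthetic data

`simulate_patients` draws per-patient categorical transitions from the
same matrices as the cohort engine, on the same cycle grid, so empirical
occupancy is an unbiased estimator of the cohort trace (verified at
n = 100,000 within three binomial standard errors per state and cycle, and
by a KS-style comparison of simulated time-to-death against the model's
discrete survival curve at α = 0.01). `generate_survival_dataset` emits a
two-arm patient-level event table (progression and death times, censoring)
embodying the configured hazard ratios; a discrete-time cause-specific
rate estimator recovers both HRs within Monte-Carlo error. All randomness
is drawn up front from one seeded generator, so results depend only on
(n, seed) and never on execution order. The generator emulates exponential
event processes with proportional hazards and administrative censoring
only — no covariates, recruitment staggering, informative censoring or
non-proportional effects, so passing oracle tests validates the engine's
arithmetic, not the realism of exponential survival for any actual trial
population.

## Numerical choices

- Root finding: Brent (scipy) on log-transformed scales; calibration
  tolerance 1e-8, price thresholds $0.01.
- Row-stochasticity enforced to 1e-12 at matrix construction and 1e-10
  along the cohort trace; death occupancy checked monotone.
- Ties in tornado ordering break alphabetically; failed DSA entries are
  flagged and sorted last rather than aborting the run.
- Undefined ratios (zero QALY/LY difference) are flagged
  (`icur_defined = False`, NaN value), never reported as infinities.
- Problem sizes: the shipped analyses run 120-cycle cohorts, a
  10,000-draw PSA, and oracle comparisons at n = 100,000 simulated
  patients (50,000 per arm for hazard-ratio recovery) — sizes at which
  Monte-Carlo error is well inside every asserted tolerance.

## Known limitations

- Exponential baselines cannot represent the shape of real
  progression/survival curves; any agreement with published quantities
  beyond the calibrated target is structural luck, and the DRd life-year
  agreement (within 1%) should be read with that caveat.
- The per-cycle discounting convention was inferred from the published
  totals, not stated by the source.
- The cost model reproduces published totals by calibration, not by
  bottom-up price arithmetic; absolute cost decompositions are therefore
  not interpretable, only price sensitivities.
- PSA assumes independence across all sampled parameters.
- The budget impact model has no dynamic prevalence, discounting or
  inflation, mirroring its source.
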
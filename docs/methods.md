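# Methods

## The surveillance model

`ceafollow` implements marker-triggered follow-up after curative colorectal
cancer resection. Serum carcino-embryonic antigen (CEA) is measured on a
fixed five-year calendar — every 3 months for the first three years
(*intensive* phase), every 6 months for years four and five (*extended*
phase) — and each value is interpreted **relative to the previous one**,
never against an absolute cutoff. The reason is the marker's distribution:
typical baselines sit around 2.0–2.5 (in the ledger's unit) but vary between
individuals by roughly 55%, so a value that is alarming for one patient is
normal for another, while a patient's own trajectory is comparatively
stable.

For consecutive values $c_{t-1}, c_t$ the engine computes the signed
relative rise $r_t = c_t/c_{t-1} - 1$ and classifies it:

* $r_t \le 0.20$ — *steady* (this includes every decrease): the
  consecutive-rise counter resets and the next routine draw is scheduled one
  phase interval ahead;
* $0.20 < r_t \le 0.40$ — *significant rise*: an early re-lab in exactly
  42 days; a second significant rise immediately following the first
  escalates to a CT alert;
* $r_t > 0.40$ — *large rise*: an immediate CT alert, whatever the interval
  since the previous draw.

Interpretation choices the rules leave open, resolved here once:

* **Strict inequalities.** A rise of exactly 20% is steady; exactly 40% is
  significant but not large. This reads the "> 20%" / "> 40%" notation
  literally.
* **Counter reset.** "Two times in a row" is taken at face value: any steady
  result, including a decrease, interrupts the run and resets the counter.
* **No interval qualifier on the large-rise rule.** The >40% trigger applies
  between any two consecutive measurements, not only those three months
  apart; the 6-week recheck therefore can itself trip it.
* **Second rise referenced to the elevated value.** The recheck's rise is
  computed against the already elevated previous value, not the pre-rise
  baseline — the conservative reading of "reference every measurement to
  the previous value".
* **First measurement is steady.** There is no reference value, so even a
  high first value cannot alert; it seeds the trajectory.
* **CT alert is absorbing.** Resumption of surveillance after negative
  imaging is a clinician decision outside the algorithm, so alerted
  patients leave the scheduling loop.
* **Discharge.** The phase interval is chosen by the measurement date; if
  the resulting due date would fall beyond month 60 the patient is
  discharged instead. Consequently a fully steady patient logs 15 routine
  re-lab recommendations and one discharge at the month-60 draw. Discharge
  is represented as its own recommendation action; like a CT alert it
  carries no due date.

Calendar arithmetic uses true calendar months with end-of-month clamping
(via `dateutil.relativedelta`); "6 weeks" is exactly 42 days. The protocol
calendar additionally carries one annual outpatient visit and CT scan
(months 12–60) and a colonoscopy at month 36; these do not interact with
the marker loop but are counted in workload and reporting.

## Synthetic cohorts

The generator produces the study conditions the engine was designed for,
with one pseudo-random stream per patient spawned from `(seed, patient
index)` so trajectories are reproducible independently of cohort size.

| parameter | default | meaning |
|---|---|---|
| `baseline_median` | 2.2 | median of the across-patient log-normal baseline (ledger unit) |
| `inter_cv` | 0.55 | between-patient coefficient of variation of baselines |
| `intra_cv` | 0.08 | within-patient multiplicative noise CV per draw |
| `recurrence_fraction` | 0.10 | probability of a recurrence (between the 9% and 13% arm rates) |
| `onset_window_months` | (3, 54) | uniform recurrence-onset window, leaving room for detection |
| `doubling_time_days` | 60 | doubling time of the recurrence-driven marker excess |
| `signal_amplitude` | 1.0 | marker excess $A$ at onset; the excess then grows as $A\,2^{\Delta t/d}$ |
| `adherence` | 1.0 | probability a scheduled draw occurs |
| `arm_split` | 0.75 | fraction assigned to the software arm (≈184/245) |

Baselines are log-normal with the stated median and CV
($\sigma^2 = \ln(1+\mathrm{CV}^2)$, median $= e^\mu$). Within-patient noise
is a unit-mean multiplicative log-normal factor — marker assays scale with
level, and this keeps values strictly positive. A recurrent patient's mean
trajectory is the baseline up to and including the onset date and
$\text{baseline} + A\,2^{(t-t_0)/d}$ strictly after it; exponential growth
is the standing kinetic model for a marker shed proportionally to tumour
burden. The paper-free choices here are `intra_cv` (no published
within-patient CV; 0.08 is a plausible assay-plus-biology figure and is a
config default, not a claim) and the onset window, amplitude and doubling
time, which were fixed once as round, clinically plausible values.

The simulation is **closed-loop**: after the first calendar draw at month 3,
each subsequent draw happens on whatever date the engine recommended, so
six-week rechecks shorten the sampling interval exactly when the trajectory
rises. A draw is skipped with probability $1-\text{adherence}$, in which
case the patient reappears at the next routine calendar date. The loop ends
at CT alert, discharge, or calendar exhaustion.

All simulated patients share one resection/enrollment date (default
2015-01-01, configurable). The engine is purely relative to resection, so
staggered enrollment would change no computed metric; a single anchor keeps
event logs easy to read.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: assay batch effects and laboratory switches,
non-CEA-shedding ("marker-negative") recurrences, benign CEA elevations
(smoking, hepatic disease), measurement-unit discrepancies, mortality and
competing risks, and imaging performance (a CT alert is treated as a
confirmed endpoint). Detection sensitivity near 1 under defaults is a
property of the simulated kinetics, not a clinical claim.

## Workload and outcome arithmetic

Conventional follow-up prices each of the 16 scheduled contacts at a
15-minute visit plus a 5-minute call: $16 \times 20\,\text{min} =
5.33\,\text{h}$ per patient, reported as 5.3 h (one decimal) and, for a
200-patient cohort, $1066.7 \to 1067$ h (nearest hour) — both roundings from
the same underlying computation. The software policy prices one annual
15-minute visit per patient plus 30 minutes of software work per week for a
reference cohort of 200, scaled **linearly** in cohort size from that
anchor (an extrapolation: the weekly cost is only known at 200). Over five
years and 200 patients: 250 h visits + 130 h software = 380 h, an annual
saving of $(1067-380)/5 = 137.4$ h.

Outcome percentages round half-up to the whole percent — with two
conventions matching how such tables are printed: an exact half percent
(1/8 = 12.5%) is kept at one decimal rather than misstated by half a point,
and the participation/consent rate is reported at one decimal
(184/245 → 75.1%). Percentages of an empty denominator are *undefined*
(`None`), never 0. Group hypothesis tests (chi-square, Mann-Whitney) are
deliberately out of scope: the package reproduces the arithmetic of the
follow-up policy, not the observational comparison.

Detection metrics score a closed-loop log against the hidden truth:
sensitivity (alerted recurrences / recurrences), false alerts (alerted
recurrence-free patients — impossible without within-patient noise), lead
time (alert date − onset date, defined only for true detections and
non-negative by construction when the trajectory is noise-free), and draws
per patient.

## Numerical and testing choices

* Rounding is decimal half-up (`decimal.Decimal`), not banker's rounding,
  because the reported figures are table entries.
* Ledger round-trips are exact: CEA values are written with full `repr`
  precision and re-parsed bit-identically; dates are ISO-8601.
* Equality thresholds in the rise classification are exact floating-point
  comparisons; the scale-invariance property is tested away from an
  $10^{-6}$ neighbourhood of the thresholds, where float rounding of
  ratios can legitimately flip a class.
* Stochastic tests pin seeds. The binomial check on recurrence counts pools
  five seeds against the exact central 95% interval of the pooled binomial,
  which tests the same distributional property with less single-seed
  variance. Problem sizes (100–1000 patients, 10⁴ Monte-Carlo draws) keep
  the full suite under ~10 s while leaving Monte-Carlo standard errors well
  inside the asserted tolerances.
* The worked single-patient oracle (onset month 12, 30-day doubling,
  alert at month 15 with a 90-day lead) is anchored at a 2017 resection:
  the months-12-to-15 span must not contain a leap February for the
  hand-computed 90-day lead to be exact.

## Known limitations

* The engine models a single analyte and a single decision pathway; visits
  to other specialties, which interfered with the deployed workflow, are
  not represented.
* The workload model is linear and deterministic; it ignores alert-driven
  extra work (CT scheduling, tumour-board time) and assumes the weekly
  software cost scales proportionally outside the 200-patient reference.
* Re-entry into surveillance after a negative CT is unspecified and hence
  unimplemented; alerted patients stay alerted.
* The ledger stores CEA in one consistent but unnamed unit; no unit
  conversion or range checking against reference intervals is attempted,
  since every rule is scale-invariant.
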
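# Methods

This document defines every rule the package implements, the parameter
defaults, the numerical conventions, and the scope of the synthetic-data
generator.

## 1. Data model

Four input streams, all plain CSV with ISO dates (see
`raclaims.data_model` for the exact column sets):

| stream | unit | key fields |
|---|---|---|
| fills | one pharmacy dispensing | drug, fill date, days' supply, quantity, strength (mg), route |
| infusions | one administration | drug, date, dose (mg) |
| procedures | one glucocorticoid joint injection | date |
| visits | one registry visit | date, TJC28, SJC28, ESR, patient global, physician global |

Domain objects are frozen dataclasses whose `__post_init__` enforces the
structural invariants (non-negative quantities, outcome visit inside the
10–14-month window, baseline within ±31 days), so an object that exists
is valid. Readers raise `SchemaError` for header problems and `RowError`
(with the 1-based row number) for value problems; writers emit sorted,
delimiter-stable rows so equal inputs give byte-equal files.

## 2. Treatment episodes (new-user design)

An **initiation** of a drug is a fill or infusion with no same-drug use
in the preceding 183 days (`LOOKBACK_DAYS`); a patient can re-initiate
after a gap of at least 183 days. An initiation becomes an eligible
**episode** when:

1. *(baseline, optional but default)* a registry visit falls within ±31
   days of the index date — the nearest one is the baseline visit
   (earlier date wins ties);
2. *(active user)* an oral fill of any drug falls 183–365 days before
   the index date, evidence the patient routinely obtains medication
   through the observed system — otherwise apparent "new use" may be an
   artifact of entering the system;
3. *(outcome)* a registry visit falls 10–14 **calendar** months after
   index (`dateutil.relativedelta`); the visit nearest the 12-month
   anniversary is the outcome visit. The episode runs from index to
   that outcome date.

Biologic episodes are built for abatacept, adalimumab, etanercept,
infliximab and rituximab. Nonbiologic DMARD episodes are built for
leflunomide, sulfasalazine and hydroxychloroquine among patients with a
methotrexate fill on or before the candidate index date: methotrexate
anchors RA therapy and is continued regardless of response, so MTX
starts never define an episode themselves. `one_episode_per_patient`
optionally keeps each patient's earliest episode (alphabetical drug on
ties).

Exclusion reasons are tallied, not silently dropped. Note that
mid-episode drug starts (switches, DMARD additions) are themselves
initiation candidates; they are normally rejected by the baseline-visit
predicate, which is the desired behavior.

## 3. Adherence

**Oral / self-injected drugs** (methotrexate, hydroxychloroquine,
leflunomide, sulfasalazine, etanercept, adalimumab): medication
possession ratio

    MPR = (sum of days' supply from fills in [index, outcome)) / (outcome − index)

capped at 1.0; **highly adherent** means MPR ≥ 0.80. The window is
half-open: a fill on the outcome date contributes nothing. By default
supply is *not* truncated at the window end (a fill near the end counts
in full, matching the usual claims-MPR convention);
`truncate_at_window_end=True` provides the clipped variant.

**Infused biologics**: observed infusion count is compared with the
count a labeled schedule would produce in the same window.

* Infliximab: loading at days 0, 14, 42, 98, then every 56 days.
  Adherent when observed ≥ expected (no allowance).
* Abatacept: every 30 days; one missed infusion allowed
  (observed ≥ expected − 1).
* Rituximab: dosed as infrequent cycles with no fixed annual schedule,
  so no adherence or escalation rule applies; rituximab episodes are
  treated as adherent and assessed only by the remaining criteria.

`expected_infusion_count` counts scheduled days in `[0, window_length]`
inclusive, so a 365-day infliximab window expects 8 infusions.

## 4. The effectiveness algorithm

An episode is **effective** iff highly adherent and *none* of the
following fire (all flags are recorded, not just the first):

1. **Biologic switch/add** — a *new initiation* (183-day rule) of a
   different biologic in `(index, outcome]`. A second biologic in
   continuous use since before the episode does not count.
2. **New DMARD** — a nonbiologic DMARD filled in `(index, outcome]`
   that was not filled in `[index − 183, index]`. The index date is
   included in the lookback so a DMARD episode's own index fill never
   flags itself.
3. **Dose escalation** of the index drug:
   * etanercept / adalimumab: mean weekly dose over any sliding 60-day
     window (evaluated via `numpy.convolve` over a per-day dose series)
     exceeds 75 mg / 30 mg respectively — i.e. sustained dosing above
     the standard 50 mg/week or 40 mg/2 weeks;
   * infliximab: any infusion dose, rounded **up** to the next 100 mg
     (vial size), at least 100 mg above the rounded-up first dose; or
     observed infusion count > 120% of the escalation-schedule
     expectation (loading 0/14/42 then every 56 days — the day-98
     loading dose is not part of the maintenance expectation);
   * abatacept: any dose at least 100 mg above the first (no rounding,
     since vials are 250 mg and weight-banding makes round-up
     misleading);
   * rituximab: not applicable.
4. **Glucocorticoid injections** — more than one *distinct calendar
   day* with a joint-injection procedure in `[index + 90, outcome]`.
   Multiple same-day injections are a single treatment encounter;
   injections in the first 90 days reflect bridging, not failure.
5. **Oral glucocorticoids** — for patients with no oral GC fill in the
   183 days before index (*naive*): more than 30 days supplied during
   `[index + 90, outcome]` flags initiation. For *prevalent* users:
   cumulative milligrams in the 183 days before the outcome date
   strictly greater than 1.2× the cumulative milligrams in the 183 days
   before index flags a dose increase (windows half-open at the
   anchor). A prevalent user whose baseline milligrams are zero is
   treated as naive rather than dividing by zero.

All thresholds live in the frozen `AlgorithmConfig` dataclass
(`mpr_threshold=0.80`, `lookback_days=183`, `injection_offset_days=90`,
`gc_naive_max_days=30`, `gc_dose_ratio=1.2`, `gc_window_days=183`,
`etanercept_weekly_limit_mg=75`, `adalimumab_weekly_limit_mg=30`,
`escalation_window_days=60`, `infusion_count_ratio=1.2`,
`dose_round_mg=100`), so sensitivity analyses change one object, not
code.

## 5. Clinical gold standard

4-variable DAS28-ESR:

    DAS28 = 0.56·√TJC28 + 0.28·√SJC28 + 0.70·ln(ESR) + 0.014·GH

with ESR floored at 1 mm/h (so the all-floor score is exactly 0) and GH
the patient global on 0–100. CDAI = TJC28 + SJC28 + PtGA/10 + PhGA/10
(globals stored on 0–100, giving the standard 0–76 range).

Primary definition: **effective** iff
(DAS28 at outcome ≤ 3.2 **or** baseline − outcome > 1.2, strictly)
**and** highly adherent to the index drug. Two LDA-only variants for
sensitivity analyses (no baseline needed): DAS28 ≤ 3.2 alone, or
CDAI < 11 alone, each still requiring adherence.
`improvement_strict=False` switches the improvement comparison to ≥;
note that for DAS28 values above ~3.2 a difference exactly equal to the
double closest to 1.2 is not even representable, so the distinction only
matters at low absolute scores.

## 6. Validation

* `confusion_matrix` joins algorithm and gold results on
  (patient, drug, index date) and refuses silently mismatched sets.
* Binomial CIs: Clopper–Pearson (exact, via `scipy.stats.beta`) by
  default; Wald; and `wald_pooled_n`, a Wald interval whose standard
  error uses a pooled denominator, matching reports that compute every
  metric's interval on the full sample size.
* Metrics with zero denominators are reported as absent (`None`), not
  NaN.
* `percent` rounds half-up through `decimal.Decimal` (Python's
  `round()` banker's rounding would turn 75.5 into 76 but 90.5 into 90).
* Misclassification bias: for observed response rate *obs*,
  `true = obs·PPV + (1 − obs)·(1 − NPV)` and
  `bias = (obs − true)/true`. At the reference operating point
  (PPV 0.76, NPV 0.90) the bias over observed rates 30–60% ranges from
  0.67% to 21%.
* `discordance_report` lists false positives/negatives with the flags
  responsible; `comorbidity_exclusion` drops episodes of patients
  flagged with pain-syndrome comorbidities that inflate DAS28 without
  reflecting inflammation.

## 7. Synthetic cohort generator

Each simulated patient is a latent **responder** (Bernoulli, default
prevalence 0.27) with one index drug drawn from a realistic drug mix.
The generator then works *backwards from the intended classification*:

* Registry visits are constructed to hit exact DAS28 targets (joint
  counts drawn, then patient global and ESR solved analytically), so
  the gold-standard classification equals the latent responder status
  by construction.
* Each algorithm component (non-adherence, switch, new DMARD,
  escalation, injections, GC) fails according to independent Bernoulli
  draws with separate probabilities for responders and non-responders
  (defaults chosen to mimic an imperfect real-world algorithm:
  responders occasionally flag, non-responders often do). Claims are
  then written that make exactly the drawn flags fire — e.g. a switch
  truncates the index-drug supply (also causing non-adherence, a real
  dependence), escalated fills double quantity from a set day, a GC
  dose increase writes 21% more milligrams before outcome than before
  index.
* Every patient's truth row records the latent status and the exact
  expected flag set; tests assert bit-exact agreement between the
  generator's intent and the classifier's output.
* `implied_performance` computes the analytic Se/Sp the failure
  probabilities imply (weighted over the drug mix, accounting for
  components inapplicable to some drugs, e.g. rituximab);
  `calibrate_misclassification` rescales the probabilities by bisection
  to hit a target (Se, Sp) — monotone in each multiplier, individual
  probabilities capped at 0.995, `ValueError` when a target is
  unattainable.
* `generate_paper_fixture` is a deterministic, hand-audited ~30-episode
  cohort probing every rule at its boundary (MPR exactly 0.80 vs just
  below, GC at exactly 120% vs 121%, infliximab round-up edge, one vs
  two injection days, abatacept missed-infusion allowance, etc.).

Scope and limits: the generator produces one episode per patient, fully
eligible by construction (plus the incidental mid-episode initiations
described in §2); it does not simulate censoring, death, coverage gaps,
coding error, or correlated comorbidity, and component failures are
independent given responder status except for the switch→non-adherence
dependence. It is a test harness with known ground truth, not an
epidemiologic microsimulation.

## 8. Numerical conventions

* All dates are `datetime.date`; month arithmetic uses
  `dateutil.relativedelta` (calendar months, not 30-day approximations).
* All randomness flows from a single integer seed through
  `numpy.random.default_rng`; derived seeds stay below 2³¹. Same seed ⇒
  byte-identical CSVs.
* Threshold comparisons follow the stated rule exactly: MPR ≥ 0.80,
  GC ratio strictly > 1.2, DAS28 improvement strictly > 1.2,
  CDAI strictly < 11, count ratio strictly > 1.2.
* Rounding for display is half-up (`percent`); internal math is never
  rounded.

## 9. Limitations

* Infusion-schedule expectations assume label dosing; real-world
  stretched intervals will read as non-adherence.
* The oral-GC dose comparison uses dispensed milligrams as a proxy for
  prescribed daily dose.
* The new-DMARD and switch rules cannot distinguish add-on for
  effectiveness reasons from add-on for tolerability.
* Validation metrics are only as good as the gold standard; registry
  visit timing (10–14 months) adds outcome-measurement noise that the
  generator's exact-visit construction does not model.
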
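# Methods

This note documents the models, conventions and design choices behind
`ptra`, in the order the pipeline runs: cohort data model, event
extraction, pair statistics, trajectory clustering, cluster
demographics, and the synthetic-cohort generator used to validate it
all.

## Cohort data model

A cohort is five comma-delimited tables (patients, visits, relapses,
MRI findings, treatment episodes). Dates are ISO-8601; ages are exact
day counts divided by 365.25, which reproduces the one-decimal age
granularity of clinical cohort reports. Birth date is stored rather
than age-at-baseline so that age at an arbitrary event date — needed
for control matching and cluster statistics — is exact.

Missing EDSS/FSS/course cells are empty in the tables and `None` in
memory. A missing score at a visit means that visit can neither anchor
nor confirm a score-change event; no imputation is attempted. Patients
with fewer than two visits are dropped at load time by default
(`drop_single_visit`), since a single recording can anchor no
within-patient sequence.

## Event extraction

Events are two-tier (main category / subcategory); each subcategory
belongs to exactly one main category, and a category without distinct
subcategories acts as its own. At the `main` analysis level, labels
collapse to the main category except that EDSS/FSS changes keep their
sign ("+EDSS", "-FSS"), which the score semantics require.

**Confirmed score changes.** A change in EDSS (half steps, 0–10) or in
any of the eight functional-system scores becomes an event only when
persistent: the next `confirmation_visits` (default 1) non-missing
recordings must differ from the *pre-change* value in the same
direction. They need not equal the changed value — the criterion is a
confirmed direction, not a confirmed level; requiring exact equality
would miss ongoing progression (3.0 → 4.0 → 4.5). The event is dated
at the first visit showing the change, and the running baseline then
moves to the changed value, so a later confirmed reversal emits a new,
opposite-signed event. When two or more functional systems change in
the same direction at the same visit, the per-system events are
replaced by a single merged "+FSS"/"-FSS" event; mixed directions merge
per direction.

**Course changes.** "to CIS" is emitted only when the first recorded
course is CIS (dated at the first visit); transitions are emitted when
the recorded course changes to RRMS or SPMS. Recorded course is taken
at face value — no inference from scores.

**DMT switches.** Every treatment start is an event labelled by the
drug's mode-of-action group (IFN/GLAT, CD20, OTH, TRF, DMF, FNG, NTZ,
ALZ, CLAD); repeated starts of the same group each count, because the
stream records treatment *changes*, not unique exposures. Unknown drug
names raise rather than drop silently.

**Index-treatment follow-up (cladribine).** Post-initiation disease
activity (EDA-3) comprises relapses (≥ 24 h of symptoms, and ≥ 30 days
from any infection/fever when an infection table is supplied —
otherwise the guard degrades with a warning), MRI activity, and
confirmed disability worsening (CDW). CDW baseline EDSS is the closest
recording within six months before or three months after initiation
(ties prefer the earlier side). A rise above baseline is CDW when
every later non-missing EDSS up to (and including the first beyond)
the 183-day sustain window stays above baseline; if follow-up ends
inside the window, the last available recording decides, which censors
optimistically but keeps short-follow-up patients evaluable. Six
months is fixed at 183 days. A patient with no EDA-3 event gets exactly
one NEDA-3 event dated initiation + the study horizon, so it sorts
after everything else; the anchor is the initiation date (the natural
zero of all follow-up windows), switchable to first visit. The last
pre-initiation DMT and the count of distinct pre-initiation DMT
*groups* ("<2 DMTs" / ">=2 DMTs") are emitted at the initiation date;
distinctness is by group, not product name, consistent with the
mode-of-action grouping.

## Pair statistics

Windows are half-open `[lo, hi)` in days; lag = date(B) − anchor(A),
and `lo` is inclusive so the long-term window `[365, 1826)` excludes
exactly the pairs the short-term window `[0, 365)` contains. Exposure
is anchored at each patient's *first* A: the statistic counts patients,
not event instances, and the first occurrence is the only
deterministic, unbiased single anchor.

**Matching.** Controls never have A anywhere in follow-up and match
their case on sex (never relaxed) and age. The control's pseudo-anchor
is the calendar date at which their age equals the case's age at
exposure. Stage 0 of the eligibility ladder requires that date to fall
inside the control's observed follow-up (zero age mismatch) *and* that
the control remain observable over the case's effective outcome window
`[lo, min(hi, case residual follow-up))`; later stages permit the
anchor to fall up to tol/2·tol/4·tol (tol = 5 years by default) outside
the follow-up, clamped to its edge, then drop the age constraint, and
as a last resort drop the residual-coverage requirement. Without the
residual-coverage rule, controls are censored by their own follow-up
more often than cases are by theirs, which biases RR upward for every
pair; with it, case and control observe outcome windows of identical
length by construction.

Controls are drawn *independently per case* (with replacement across
cases) by default. This is deliberate: each matched control then
contributes an independent Bernoulli outcome, so the resampled control
count carries the same dispersion as the exposed count, and the
empirical p-value is calibrated. Drawing a whole control set without
replacement from a finite pool gives hypergeometric counts whose
variance is shrunk by (N−n)/(N−1); when the never-exposed pool is not
much larger than the exposed set this makes the test sharply
anti-conservative. `with_replacement=False` remains available for
distinct-patient control sets.

**The empirical test.** Each pair's resampling stream is seeded from
(seed, A, B, window) via a CRC so results are bitwise-reproducible and
independent of evaluation order. The p-value uses the add-one
estimator `(1 + #{RR ≤ 1}) / (N + 1)`. An infinite RR (zero control
rate with nonzero exposed rate) counts as RR > 1 in the tally but is
excluded from the reported `rr_mean`/`rr_sd`, with the infinite
fraction reported separately; a 0/0 RR counts as RR ≤ 1
(conservative). The reported RR is the mean over resamples, with its
standard deviation alongside — on small cohorts single-draw RRs
fluctuate visibly. No multiple-testing correction is applied across
pairs: filtering is at raw RR > 1 and p < 0.01 per pair (thresholds 0
and 1 give the count-everything mode), and the evaluated pair count is
available for users who wish to post-correct.

**Direction selection.** When a pair and its reverse both exceed RR 1,
patients with both events are split by whether their first A strictly
precedes their first B (ties dropped); a two-sided exact binomial test
at 0.5 decides at α = 0.05. If significant, the majority direction is
kept (flagged `binomial`); otherwise the larger-RR direction is kept,
flagged `unresolved`.

**Known calibration properties.** The empirical p-value treats the
never-exposed pool's realized outcomes as fixed; their sampling noise
is not propagated. The test is therefore mildly anti-conservative when
the exposed set is a sizeable fraction of the cohort, converging to
nominal as per-label exposure shrinks. On null cohorts with ~20%
per-label exposure the measured rejection rate at p < 0.01 is ~1.5–2%
of all ordered pairs — inside the 99% binomial band of the calibration
suite, but users should treat borderline p-values on highly prevalent
exposures with care. Follow-up heterogeneity adds a second,
intention-to-observe confounding (exposure selects for long follow-up);
the residual-coverage matching rule removes most but not all of it.

## Trajectory graph and clustering

Surviving pairs become directed edges annotated with `n` (exposed
patients with the outcome), `pct` = 100·n/cohort and the mean RR;
edges below the minimum patient count (10, ~1% of the full cohort, in
the exploration design; 1 in the small-cohort design) are dropped.
Patient-count and display-RR filters commute, so their order is
presentation detail.

MCL runs on the symmetrized adjacency (max of the two directions —
flow simulation is direction-agnostic) with edge weights defaulting to
patient counts; self-loops are set to each node's strongest incident
weight, which damps the period-2 oscillation that would otherwise
dissolve two-node components into singletons. Expansion 2 and
inflation 2.0 (the algorithm's customary defaults) are exposed as
configuration. Iteration stops when the matrix change falls below
1e-8 (hard cap 200 iterations, error on non-convergence); entries
below 1e-12 are pruned each round. Clusters are read off attractor
rows and overlapping attractor systems are merged, so every node lands
in exactly one cluster and clusters never span disconnected
components.

Clusters with ≥ 3 events are written to DOT (one subgraph each,
intra-cluster edges only, optional display-RR cutoff); 2-event
clusters go to a side table sorted by RR; singletons are reported but
never drawn.

## Cluster demographics

A patient belongs to a cluster when they contribute to the
exposed-with-outcome count of any edge with both endpoints inside it —
the same patients the edge counts display. Age is taken at the
patient's first event on any in-cluster label (sample SD, ddof = 1).
The cluster's female proportion is compared to the full cohort's with
a one-sample Z-test carrying a finite-population correction, the
cohort being a finite population of which the cluster is a sample:

    z = (p̂ − p₀) / sqrt( p₀(1−p₀)/n · (N−n)/(N−1) )

with a two-sided normal tail. As N → ∞ this reduces to the classical
one-sample proportion test; at n = N the variance vanishes and the
test degenerates (p = 1 if the proportions agree, else 0, with a
warning). Applied to published cluster counts (148 F of 231 and 131 F
of 163 against 69.75% female, N = 985) it returns 0.0318 and 0.00124,
matching the printed 0.031 and 0.0012 to one unit in the last printed
digit.

## Synthetic cohort generator

The generator emulates the *statistical shape* of a tertiary-center MS
registry: sex drawn at 69.75% female; baseline age lognormal (median
43.1 y, σ = 0.32, matching the reported interquartile range);
follow-up lognormal (median 80.8 months, σ = 0.75); visit gaps
gamma-distributed (shape 2, mean 170 days, floor 14) so the median
visit count lands near 15; baseline calendar dates spread over 18
years. Per-label baseline hazards (events per patient-year) default to
values that give roughly ten extracted events per patient — the
density of the reference registry — while keeping per-label exposure
under ~45% so equal-size matched control pools exist; they are fully
overridable per label.

Event streams are piecewise-constant-hazard Poisson processes. A
`PlantedEffect` multiplies the outcome label's hazard by `hazard_ratio`
inside `[lag_lo, lag_hi)` after each trigger event (triggers are
simulated before outcomes; cyclic or self-exciting effects are
rejected). The closed-form relative risk over an observation window
with boosted overlap O and length D,

    RR = (1 − exp(−λ(D−O) − λhO)) / (1 − exp(−λD)),

is exposed as `expected_rr`, with `hazard_ratio_for_rr` inverting it;
both serve as ground truth for recovery tests and approach
1 + (h−1)·O/D as λ → 0.

EDSS and FSS visit series are synthesized *backwards* from the intended
change events: the score steps (±0.5 EDSS, ±1 FSS, clamped to range)
at the first visit on or after the simulated change time and holds
afterwards, so the extractor's confirmation rule is exercised rather
than bypassed — a change landing on a patient's last visit stays
unconfirmed, as in real data. Consequences worth knowing: score-change
event dates snap to the visit grid (recovery tests for planted effects
therefore use the exact-date relapse/MRI/treatment streams), and the
range clamps couple "+X" and "−X" streams (a decrease is impossible at
the floor), so null-calibration suites use one-sided score labels
only. Course dynamics are a simple CIS → RRMS → SPMS progression with
exponential transition times (0.7/y and 0.035/y); PPMS patients stay
PPMS. Scores are missing completely at random at 4%.

The small-cohort preset (`analysis2_config`) mirrors an
index-treatment follow-up study: 83 patients, all starting cladribine
shortly after baseline, 0–4 distinct prior DMTs, short follow-up
(median 20 months) and sparse activity hazards.

What the generator does **not** model: realistic MS natural history,
treatment effects on event rates, informative visit timing, secular
drift in diagnostic practice, or within-patient correlation beyond the
planted effects. Passing tests therefore demonstrate that the
*pipeline* is correct and calibrated under its stated assumptions, not
that those assumptions hold in any particular registry.

## Problem sizes in the test and acceptance suites

The suites are sized to run comfortably on one CPU: oracle-equivalence
checks use 50 micro-cohorts of 8–20 patients over all ordered pairs
and all three study windows; null calibration pools three 200-patient
cohorts with 16 independent labels (720 ordered pairs) at 500
resamples; planted-RR recovery uses 500 patients at 500 resamples; the
structural end-to-end run covers the six-experiment exploration design
(three windows × two category levels, minimum 10 patients, 250
patients, 150 resamples) and the count-everything small-cohort design
(83 patients, three horizons). The full default of 10,000 resamples is
the production setting, not the test setting.
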
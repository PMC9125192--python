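# Methods

## Scoring model

Each pSOFA domain maps one driving variable (plus drug state for the
cardiovascular and renal domains) to an integer 0-4 through fixed
thresholds. Two conventions needed fixing where the printed bands leave
gaps or ties:

- **Interval convention.** Categories are half-open and the healthy "0"
  category is closed at its printed boundary: PaO₂/FiO₂ ≥ 400, MAP ≥ 75,
  urine ≥ 0.5, platelets ≥ 200 and bilirubin ≤ 20 all score 0. The
  bilirubin bands print `<20` / `>20`, leaving exactly 20 unassigned; it
  is given the benign score, and the same rule applies at 32, 101 and 204.
- **Drug dominance.** Vasopressor- and diuretic-based scores (3-4)
  dominate measurement-based scores (0-2); the domain score is the
  maximum of the two pathways. Norepinephrine dose is in µg kg⁻¹ min⁻¹
  (the human SOFA convention); furosemide is the cumulative dose in mg
  within the monitoring window, with exactly 10 mg scoring 3.
- **Missing data.** Absent laboratory values never default to a healthy
  score: the result is flagged 3-domain-only. Absent online values are an
  error.
- The per-animal summary is the unrounded arithmetic mean of the hourly
  integer totals over the scoring window (default 16-24 h);
  classification always uses per-time-point totals, never the mean.
- Human-mode thresholds (MAP 70 mmHg, platelet bands 150/100/50/20, the
  dopamine/epinephrine/dobutamine dose bands) are provided for
  comparison. The human renal dose bands are not reliably documented for
  this adaptation and are therefore not offered; human mode reuses the
  urine-output bands.

## Therapy rules

The trigger engine is a pure function of (sample, therapy state, policy).
Defaults: norepinephrine starts when MAP ≤ 55 mmHg after ≥ 60 min of
ongoing crystalloid resuscitation ("decreased to 55" is read as ≤ 55, and
"did not respond" as still at/below the trigger after the minimum fluid
duration); furosemide 10 mg fires on urine < 0.25 mL kg⁻¹ h⁻¹ despite
fluids or ELWI > 10 mL kg⁻¹, repeatable while refractory; a fluid bolus
fires when SVI falls below the 35-45 mL beat⁻¹ m⁻² target. Norepinephrine
titration is not part of the protocol contract; the simulator starts at
0.05 µg kg⁻¹ min⁻¹ and doubles per unresponsive hour, a documented
assumption.

## Classification

Allocation happens at 18 h (configurable). Sepsis requires total pSOFA
≥ 2 (5-domain total when available, else 3-domain) and lactate
≥ 2 mmol L⁻¹ at allocation. Septic shock additionally requires
vasopressor dependence at allocation; a stricter mode also demands
documented pre-vasopressor hypotension (MAP < 65 on ≥ 2 consecutive
hourly samples) since "persistent hypotension" is not quantified in the
consensus wording. The fulminant humane-endpoint rule is conjunctive at
the 6-h check: lactate ≥ 2x and bilirubin ≥ 1.5x baseline AND SvO₂ and
albumin ≥ 20% below baseline (multiples configurable; explicit acute
respiratory/circulatory failure flags short-circuit). A trajectory ending
before allocation without a fulminant flag is an error, not a label.

## Oxygen dynamics

DO₂ and VO₂ default to the literal bedside formulas
`CO × [(1.38·Hb·SaO₂) + 0.003·PaO₂]` (and SaO₂−SvO₂ for VO₂) without the
dL→L unit factor; a `ml_per_min` mode applies the conventional ×10.
Extraction is reported as the physiological fraction ExO₂ = VO₂/DO₂ —
the ratio printed in the source material is typographically inverted, and
the extraction fraction is the quantity consistent with extraction rising
under increased demand; the literal inverse is available behind a flag.
SVRI divides by whichever flow the caller passes (CI for the indexed
form, CO for the raw form). SVI is CI/HR × 1000 so its units match the
35-45 mL beat⁻¹ m⁻² resuscitation target.

## Synthetic cohorts

The generator emulates the *statistical structure* of the study, not its
data: log₁₀ inoculum CFU is uniform over 5.8-10.2 (spanning the reported
6.2×10⁵-1.6×10¹⁰ range of total CFU in the 200-mL suspension); a latent
severity `coupling × (log₁₀CFU − min) + N(0, σ)` orders the inoculated
animals; study-flow quotas assign templates by that order (5/27
non-responders at the bottom, 3/27 fulminant at the top, 9/19 of the
remaining septic animals in shock). Quota assignment keeps label counts
exact per cohort while the coupling slope alone controls how strongly
outcome follows dose — at coupling 0 the outcome is independent of CFU by
construction, which is what the parameter-recovery tests exploit.

Trajectories are piecewise-linear class medians (anchors at 0, 6, 12, 16,
18, 20, 24 h) whose deviations from baseline are scaled by the
within-class severity quantile (0.85-1.15) and multiplied by lognormal
noise (CV 8% for most variables, 3% for MAP, 2% for saturations —
pressures and oximetry are less noisy than assays). Anchor values are
design choices placed inside the qualitatively described ranges (sepsis
3-domain averages ~1-3, shock ~5-9, TNF-α peaking at 6 h, IL-10 at 16 h,
leucopenia at 16 h, persistent lactate ≥ 2 and a late bilirubin rise only
in shock, bET/HMGB1 elevated only in shock over 16-24 h); they are not
asserted to be the study's medians. Supportive therapy runs in-loop over
the monitoring window, so vasopressor and diuretic states arise from the
simulated physiology through the same trigger engine the scoring
consumes; once norepinephrine runs, MAP is held near a severity-dependent
response level (68 − 16·u mmHg), so the most severe animals stay
hypotensive and escalate past the 0.1 µg kg⁻¹ min⁻¹ band. Hemoculture
CFU is lognormal around a severity-proportional mean, which produces the
blood-load-correlates-more-tightly-than-dose structure.

What the generator does **not** emulate: pharmacokinetics, mechanistic
cardiovascular coupling, inter-variable correlation beyond the shared
latent severity, missing-data patterns, or species composition effects.
Passing tests therefore demonstrate that the pipeline recovers structure
that is present by construction — they say nothing about biological
fidelity of any particular trajectory.

## Statistics

Spearman uses mid-ranks; p-values come from the exact permutation
distribution for n ≤ 9 and the t approximation otherwise. The regression
line and 95% band attached to each correlation are plain OLS on the
original scales, provided for figure reproduction only. Kruskal-Wallis H
and Friedman χ² come from scipy with tie correction; Dunn's pairwise
z-tests are computed from pooled (respectively within-block) mean ranks
with the standard tie-corrected variance and are reported unadjusted by
default, matching the behavior of the desktop statistics packages
historically used with these designs; Bonferroni and Holm are selectable
and the choice is recorded in the output. The survival sample-size
estimate is the Schoenfeld event count
`(z₁₋α/₂ + z₁₋β)² / (p(1−p) ln²HR)`; the event probabilities that turn
events into group sizes are explicit inputs echoed in the output, because
any published group sizes depend on an unstated mortality assumption.

## Problem sizes and numerical choices

Validation experiments use cohorts of 36 animals (the study size) for
classifier and structure checks and 100 inoculated animals x 20 seeds x 3
coupling values for parameter recovery; rank-test calibration uses 5,000
null replicates at n = 10 per group (Kruskal-Wallis) and n = 20
(Spearman). Cohorts used for CFU-correlation recovery are generated
without shams, since saline controls carry no inoculum and cannot enter
the correlation; animals terminated before the monitoring window
contribute their pre-window mean scores. Threshold grids in the scoring
equivalence check straddle every category boundary at ±1e-6. All
randomness flows through `numpy.random.default_rng` seeds; identical
config + seed reproduces every table byte for byte.

## Known limitations

- The latent-severity quota assignment means class proportions never vary
  across seeds; sampling variability lives in the CFU draws, the latent
  noise, and the measurement noise.
- Fulminant trajectories are sampled only at the coarse early grid
  (0/6/12 h), mirroring the pre-instrumentation sampling scheme, so the
  humane-endpoint rule sees at most three points.
- Human-mode renal scoring reuses the urine bands (see above).
- The classifier's default shock rule trusts vasopressor state at the
  allocation instant; with externally recorded therapy logs that carry
  gaps, the strict mode is the safer choice.
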
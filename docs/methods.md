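# Methods

## Indices and standardisation

Each Doppler exam carries three pulsatility-index (PI) replicates per
insonated vessel — umbilical artery (UA), middle cerebral artery (MCA),
and left/right uterine arteries (UtA) — taken at a gestational age (GA)
in the late-onset window [32, 37] decimal weeks.  The analysis uses the
arithmetic mean of the three replicates per vessel.  From the replicate
means:

- CPR = MCA-PI / UA-PI (low under cerebral redistribution),
- UPCR = (UA-PI + mean of left/right UtA-PI) / MCA-PI (high under
  combined placental strain),

with the algebraic identity UPCR = 1/CPR + UtA-PI/MCA-PI enforced to
1e-9 relative tolerance on every `IndexSet`.

PIs fall with advancing gestation, so values are standardised as
multiples of the GA-specific median (MoM).  Published studies rarely
print their reference equations, so the package ships piecewise-linear
median curves over [32, 37] weeks with magnitudes typical of obstetric
reference ranges (UA 0.97→0.87, MCA 1.95→1.56, UtA 0.66→0.62); the ratio
medians are derived from the vessel medians at the same knots so the two
possible standardisations stay coherent.  The same curves serve the
simulator and the analysis, which makes MoM logic exactly testable
(healthy MoM ≈ 1 by construction) at the cost of not representing any
particular external reference population.  Curves are plain data and can
be replaced wholesale.

Ratios are standardised as **MoM of the ratio** by default (compute
CPR/UPCR from raw PIs, then divide by that ratio's own median curve),
because the source tables print "CPR MoM"/"UPCR MoM" as single
quantities; `ratio_of_moms` is available as an explicit mode.  Group
tables and regressions analyse MoMs throughout; z-scoring is a trivial
downstream transform the package does not hard-wire.

Estimated fetal weight uses the classical four-parameter log10
regression on BPD, HC, AC and FL (cm → grams), strictly increasing in
each argument over the plausible third-trimester range; values outside
that range warn rather than fail.  The late-onset FGR classifier is the
consensus rule: AC or EFW below the 3rd percentile, or any two of
{AC/EFW < 10th percentile, growth crossing > 2 quartiles, CPR < 5th or
UA-PI > 95th percentile}.  Percentiles and the quartile-crossing flag
are precomputed inputs: the classifier is pure and does not re-derive
growth trajectories.

The composite adverse perinatal outcome is positive when any component
is present: stillbirth, emergency caesarean for fetal distress, 5-min
Apgar < 7, umbilical-artery pH < 7.10 (both strict inequalities, exactly
as defined), or special-care (NICU) admission.  A record with a missing
component cannot be evaluated and is routed to the `missing_data`
exclusion.  The exclusion filter applies reasons with the fixed
precedence early-onset disease > malformation > lost to follow-up >
missing data, and always conserves records (analyzed + excluded =
recruited).

## Synthetic cohort generator

The generator emulates a single-centre prospective cohort of pregnancies
with suspected growth restriction.  Its defaults are the study
conditions: 186 recruited; 72 excluded as 58 early-onset / 7 lost to
follow-up / 4 missing data / 3 malformation; 114 analyzed, of whom 37
carry the composite adverse outcome; outcome-component counts among the
adverse records of 16 emergency caesareans, 14 low Apgar, 4 acidotic cord
pH, 27 special-care admissions, 0 stillbirths; group MoM means/SDs of
UA 1.21±0.32 vs 1.48±0.48, MCA 0.84±0.19 vs 0.69±0.14, UtA 1.59±0.70 vs
2.23±0.53, CPR 0.69±0.24 vs 0.49±0.20, UPCR 1.74±0.73 vs 2.74±0.76
(normal vs adverse); and baseline characteristics (age, BMI, parity,
comorbidity prevalences, delivery data) matching the published group
summaries.

Design points, each chosen once:

- **Vessel-level simulation.**  Each analyzed record draws its
  (UA, MCA, UtA) MoM triple from a multivariate Gaussian truncated below
  at 0.05, with inter-vessel correlations (UA–UtA +0.3, UA–MCA −0.2,
  UtA–MCA −0.2) chosen as physiologically plausible — placental
  impedance couples the two supply-side vessels, cerebral redistribution
  opposes both; no published correlations exist, and the matrix is
  config-exposed.  Raw PIs are back-computed as MoM × reference median
  at the record's GA; each vessel then gets three replicates with
  multiplicative Gaussian noise (CV 5%, a typical sonographer
  triplicate variability), and the left/right uterine arteries split
  around their mean with an asymmetry SD of 0.08.
- **Moment-matched truncation.**  The pre-truncation Gaussian
  parameters are adjusted (fixed-point on the truncated-normal moment
  identities) so the *truncated* draws reproduce the configured group
  means/SDs.  Without this, the 0.05 floor biases the normal-group UtA
  mean upward by ≈ 0.025 — detectable at scale.
- **Derived ratios are approximate.**  CPR and UPCR are computed from
  the simulated vessels, so their group moments track the configured
  values only approximately (the adverse UPCR mean lands within
  sampling error of 2.74; the ratio SDs are inflated relative to the
  configured values because a ratio of correlated Gaussians is
  heavier-tailed than a Gaussian).  For questions posed directly at the
  marker level — e.g. "what AUC do the published UPCR group moments
  imply?" — the **index-marginal mode** simulates any single index as
  truncated group Gaussians with exactly the configured moments.
- **Exact-count outcomes.**  With the default configuration the
  component counts are allocated exactly among the adverse records
  (seeded allocation; every adverse record receives at least one
  component, no normal record receives any), so count-level summaries
  are reproduced exactly, not just in expectation.  Setting
  `outcome_counts: null` switches to independent Bernoulli draws from
  the conditional prevalences, with adverse records redrawn until they
  carry a component.  A configuration in which no component can occur
  in an adverse record is rejected as infeasible.
- **Substreamed randomness.**  One master seed spawns named substreams
  (characteristics, vessels, replicates, outcomes, excluded records,
  ordering), so extending one stage never perturbs another; identical
  configurations give byte-identical cohort CSVs.
- **Biometry and percentiles are schematic.**  BPD/HC/AC/FL follow
  linear GA trends with 2% log-normal noise at magnitudes typical of a
  growth-restricted third-trimester fetus; severe-smallness flags are
  drawn at the published group rates and the EFW percentile is drawn
  consistently with the flag.  Preeclampsia is modelled as a coin-flip
  subset of hypertensive disease.

What the generator does **not** emulate: ultrasound waveforms or images,
serial (longitudinal) exams, the delivery-decision protocol, real
reference-population median curves, within-woman correlation between
biometry and Doppler beyond the group structure, or the joint
distribution of outcome components (they are allocated/drawn
conditionally independently given adverse status).  Passing tests
therefore demonstrate that the *analysis machinery* is correct under a
cohort with the published group structure — not that the published
clinical findings generalise.

## Inferential statistics

All test statistics are computed in-package; `scipy.stats` supplies only
distribution tails and quantiles.

- **Welch t** with Satterthwaite degrees of freedom; the bootstrap
  variant (10,000 seeded resamples by default) recentres both samples on
  the pooled grand mean and reports the add-one-corrected two-sided
  resampling p.  Two zero-variance samples give p = 1 with a degeneracy
  flag.
- **Mann–Whitney U** counts ties as one half.  For pooled sizes ≤ 12
  the p-value is exact by full enumeration of label assignments, with
  two-sidedness measured as distance of U from its null mean; otherwise
  the tie-corrected normal approximation (no continuity correction) is
  used.
- **Pearson chi-square** for 2×2 tables, N(ad−bc)²/(r₁r₂c₁c₂), no
  continuity correction by default (this reproduces the published
  severe-smallness p = 0.016 from the printed counts); Yates' correction
  is exposed but off.  The exact option computes the permutation
  distribution of the statistic over all tables with the observed
  margins.  Note that this conditional exact p is discretely
  conservative for mid-range p (it can exceed the asymptotic p by ≫0.02
  even at N ≥ 100); the two agree closely in the significance-relevant
  tail, which is what the property tests assert.
- **Fisher's exact test**: two-sided p as the hypergeometric mass of
  tables no more probable than the observed one (with a 1e-9 relative
  tolerance on the probability comparison); a zero margin gives p = 1.
- **Cohen's kappa** (p_o − p_e)/(1 − p_e) for square agreement tables.

## Logistic regression and selection

`fit_logistic_irls` is plain Newton/IRLS from a zero initial vector with
step halving, iterating to gradient infinity-norm < 1e-8 (max 50
iterations).  Standard errors come from the inverse observed
information; 95% CIs are Wald, exp(B ± 1.96·SE), mirroring the B/SE/aOR
reporting convention.  Quasi-separation (any |B| > 15) and
non-convergence set flags instead of raising; rank-deficient designs
raise an error naming the collinear columns.  Likelihood-ratio tests use
G = 2Δℓ against the chi-square with df = parameter difference.

Backward-stepwise selection starts from the full model and repeatedly
removes the term with the largest single-term LR p exceeding
`alpha_remove` (default 0.10, a common stepwise default; ties broken by
design-column order), recording each removal.  `alpha_remove ≥ 1`
degenerates to removing everything down to the intercept.  The pipeline
fits eight candidate terms on the MoM scale, unstandardised.  Because
the synthetic UPCR is an exact function of the simulated vessels, the
eight-term design is highly collinear and the selected subset varies by
seed — the published single-marker selection depends on the real
individual-level data and is not a reproduction target.

## ROC analysis

The empirical AUC is the tie-adjusted Mann–Whitney probability (equal to
U/(n₀n₁) exactly, ties included — asserted against the rank
implementation on seeded tied data).  The binormal companion
Φ(Δμ/√(σ₀²+σ₁²)) gives the AUC implied by printed group moments.
DeLong structural components provide the AUC variance, Wald CIs
truncated to [0, 1] (zero variance flagged as degenerate), and the
paired z-test for two markers on the same subjects.

Youden cutoffs scan midpoints between consecutive distinct scores plus
±∞ sentinels; a subject is positive when its oriented score exceeds the
cutoff.  Markers for which lower values predict the adverse outcome
(MCA PI, CPR) are negated first so every reported AUC is ≥ 0.5, with the
orientation recorded.  J-ties are broken toward the cutoff with higher
sensitivity (screening context), then toward the lower cutoff —
deterministic.  Sensitivity/specificity and PPV/NPV carry exact
Clopper–Pearson binomial CIs; predictive values are computed at the
observed prevalence and satisfy the Bayes identity exactly at the chosen
cutoff.  Numeric cutoffs are internal quantities only — they are
GA-dependent and cohort-specific, so no clinical cutoff value is
asserted or recommended.

## Problem sizes and numerical choices

Calibration checks run the generator at 100× scale (18,600 records);
marker-level AUC reproduction simulates 120,000–150,000 pregnancies per
outcome group (Monte-Carlo SE on the AUC ≈ 0.001); logistic parameter
recovery uses 100 replicates of n = 5,000, and the stepwise
signal-recovery scenario 20 seeds of n = 2,000 with the removal
threshold at 0.001 (a family-wise choice: at the single-model default of
0.10, each of the 80 null term-tests would retain its term with
probability ≈ 0.10 by construction).  Report JSON rounds for display
only and keeps the headline AUCs at full precision; all randomness flows
from explicit seeds.

## Known limitations

- Reference median curves are internal defaults, not a population
  reference; absolute MoM values are only meaningful relative to them.
- The conditional exact chi-square p is conservative off the tail (see
  above).
- Derived-ratio moments (especially SDs) deviate from the configured
  marginal values by construction; use the index-marginal mode for
  marker-marginal questions.
- Published regression coefficients, sensitivities/specificities at
  unpublished cutoffs, pairwise AUC p-values and the sonographer kappa
  depend on the unshared individual-level data; the package reproduces
  the machinery and the count/moment-determined quantities, not those
  numbers.
- No serial Doppler modelling: each pregnancy carries one exam.
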
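# Methods

## Droplet-level quantification

A ddPCR well reports, per fluorescence channel, the number of positive
droplets `k` out of `n` accepted droplets. Assuming Poisson occupancy, the
estimated mean copies per droplet is `λ = −ln(1 − k/n)`, and concentration
is `λ / v` with droplet volume `v` (default 0.85 nL, ~20,000 accepted
droplets per well — instrument conventions, both configurable). Replicate
wells of one sample are pooled by summing counts before correction, which
is equivalent to treating the pooled droplets as one larger partition and
is how replicate merging behaves in practice.

The mutant variant allele frequency is computed from Poisson-corrected
copies, `VAF = 100·λ_mut/(λ_mut + λ_wt)`, not from raw droplet counts: at
the validated 20–30 ng input, wild-type occupancy is high enough
(~0.3 copies/droplet) that raw counts underestimate the wild-type channel
and overstate the VAF by ~10 % relative. The KRAS p.G12/p.G13 screening
assay pools seven variants into one mutant channel; it is treated as a
single pooled signal with one VAF and one cutoff pair.

**Uncertainty.** Reported intervals are nominal 95 % intervals per channel
combining two variance components on the log scale: Poisson sampling of
template molecules into the reaction (relative variance `1/copies`) and
binomial droplet partitioning (delta method on the positive fraction). A
zero count uses the exact Clopper–Pearson upper bound. The two channels
are combined conservatively (mutant-low with wild-type-high and vice
versa). Empirical coverage at single-well scale is 96–99 % across
0.5–10 % VAF. Published "±" half-widths of clinical reports are
reproduced qualitatively, not bit-exactly, since their computational
definition is not standardized.

`droplets_to_copies` raises a saturation error when every droplet is
positive (λ undefined); an input mass outside the validated 20–30 ng range
flags the measurement with a warning rather than failing, because the
cutoffs — not the arithmetic — are what the mass range validates.

## Cutoff estimation and verification

**LOB.** The limit of blank is the nonparametric (1 − α) percentile of
blank measurements at the 1-based rank position `p = (1 − α)·N_B + 0.5`
on the ascending sorted values, linearly interpolating between the
bracketing ranks (ties collapse naturally because interpolation acts on
the sorted values including duplicates). With α = 0.05 this is the
CLSI-style 95 %-specificity cutoff. At least 60 blanks are required for a
cutoff claim; fewer raises by default (a warn-only mode exists for
exploratory use). The identical machinery estimates the cfDNA
concentration cutoff from healthy-donor plasma.

The rank-based estimator is slightly conservative at N_B = 60: the
expected fraction of fresh blanks at or below the estimated LOB is
`E[F(X_(57.5))] ≈ 57.5/61 ≈ 94.3 %`, which the calibration suite
reproduces (94.4 % over 500 simulated cohorts) — within a percentage
point of the nominal 95 %.

**LOQ.** "Precision" and "trueness" are read as `100 − CV%` (CV with
sample standard deviation) and `100 − |relative bias|%` respectively —
the conventional CLSI-style definitions; the acceptance thresholds are
precision ≥ 80 % and trueness ≥ 90 % over ≥ 40 replicates per candidate
level. The estimator scans candidate levels in ascending order and returns
the lowest qualifying level at or above the LOB, supporting both a
multi-level search and validation of a single preselected level.

**Verification.** A cutoff passes clinical verification when the fraction
of independent healthy controls strictly above it is at most 15 %. Failed
analyses (missing values) are excluded from the denominator before the
fraction is computed. Strict ">" is used for exceedance everywhere,
mirroring the positivity rule below; boundary values are negative.

## Classification rules

* ctDNA status: NEGATIVE if VAF ≤ LOB; POSITIVE if LOB < VAF ≤ LOQ;
  QUANTIFIABLE if VAF > LOQ. All comparisons strict.
* Clonal-hematopoiesis filter: a positive plasma call with matched
  lymphocyte gDNA above the LOB is retained when the plasma VAF exceeds
  the gDNA VAF (the plasma signal exceeds what blood cells explain) and
  becomes CH_SUSPECTED otherwise. CH_SUSPECTED is a distinct state rather
  than a silent negative so downstream counts can report it; the
  gDNA-dominant branch is a documented extension — validated cohorts only
  exhibited the retained-positive case. Missing gDNA leaves the call
  unchanged but marked unchecked. The filter never upgrades a negative.
* cfDNA elevated iff concentration > 5.6 ng/mL; CEA elevated iff
  > 2.5 ng/mL (non-smokers) or > 5 ng/mL (smokers). Unknown smoker status
  defaults to the non-smoker threshold (conservative toward detection).

## Longitudinal interpretation

* **MRD**: any ctDNA-positive plasma sample within 4–50 days after
  surgery (the sampling span of the validated workflow; configurable).
  No surgery or no sample in the window yields a not-evaluable result,
  not an exception.
* **Recurrence**: the first positive sample after at least one negative
  sample following curative treatment (surgery, else the first
  chemotherapy end). Lead time is the day difference to the next clinical
  recurrence event at or after the molecular call; calls without one are
  flagged unconfirmed. A single positive sample suffices by default, as in
  the validated workflow; repeated calls require an intervening return to
  negativity.
* **Trajectory**: consecutive-sample pairs during a chemotherapy interval
  (the latest pre-treatment sample anchors the first pair). CLEARED when
  crossing from above to at/below the LOB; pairs with both values in the
  sub-quantifiable band (LOB, LOQ] are NOT_EVALUABLE for direction; other
  pairs are RESPONSE/RESISTANCE when the change is significant — default
  rule: non-overlapping 95 % measurement intervals, falling back to a
  configurable minimum fold-change (default 2×) when intervals are
  unavailable — and STABLE otherwise. Direction flips under time reversal.
* **Marker concordance**: for each event (MRD assessment, clinical
  recurrence), each marker is scored as predictive, non-predictive, or not
  assessable (no valid measurement in the window). ctDNA uses its event
  calls directly. cfDNA and CEA count as predictive only if elevated in
  the event window *and* not elevated at every assessable visit of the
  timeline: a marker that never changes carries no event-specific signal,
  which is precisely why a flat-elevated cfDNA track cannot flag MRD or
  recurrence. The recurrence lookback window defaults to 90 days.

## Cohort statistics

Two-group contrasts use the two-sided Wilcoxon rank-sum test (exact for
small tie-free samples, normal approximation with tie correction
otherwise; statistic reported in rank-sum form). Three-group contrasts use
Kruskal–Wallis with chi-square reference and pairwise rank-sum follow-up
under Bonferroni correction (multiplier = number of pairs, capped at 1).
An all-identical pooled sample returns p = 1 by convention. Disease phases
(baseline / course of disease / follow-up after curative treatment) are
assigned by a tumor-evident state machine over the event timeline:
surgery and remission clear the evident state, metastasis, clinical
recurrence and progression restore it; samples before the first treatment
are baseline. Undetectable ctDNA enters phase statistics with its measured
VAF (usually exactly 0) — never an imputed small value. Repeated measures
per patient are treated as independent samples by default, matching the
validated workflow's sample counts; a per-patient-median aggregation mode
is provided.

## Synthetic data generator

The generator emulates the study conditions end to end: 20–30 ng input
drawn uniformly, 303 haploid genome equivalents per ng (configurable),
Poisson template sampling, binomial droplet occupancy, and per-assay blank
false-positive droplets — Poisson counts per well rather than a continuous
VAF distribution, matching ddPCR physics and producing the discrete,
tie-heavy blank sets the LOB machinery must tolerate. Default
false-positive rates (0.35 mutant droplets/well for the single-probe BRAF
assay, 4.0 for the 7-probe pooled KRAS assay) place the simulated noise
floor near the validated LOB magnitudes (≈ 0.02 and ≈ 0.11 % VAF).

Cohorts combine healthy donors (log-normal cfDNA, median 2.5 ng/mL) and
patients (median 11.6 ng/mL while tumor is evident) with stage-dependent
shedding probability and baseline VAF scale rising from UICC I to IV, on a
14-day visit grid over one year. Shedding surgery patients draw one of
three trajectory templates: cleared (negative after resection),
MRD-responder (residual signal decaying under adjuvant chemotherapy), and
recurrence (negative follow-up, then molecular positivity a configurable
lead — default 90 days — before the clinical recurrence event). A
configurable fraction of shedders carries an injected clonal-hematopoiesis
gDNA signal for filter-recovery tests. cfDNA and CEA tracks can be coupled
to the tumor-evident state or decoupled (phase-independent) to separate
marker specificity from study-design confounding.

What the generator does *not* emulate: fragment-length biology, GC bias,
pre-analytical degradation, assay cross-reactivity, or inter-patient
correlation structure beyond stage. Passing calibration tests therefore
demonstrates the estimators' statistical behavior under the assumed
physics, not clinical performance on real plasma.

## Reference cohort

A deterministic fixture encodes an 18-patient primary-surgery roster and a
9-patient chemotherapy-monitoring roster with the published per-stage
detection pattern (ctDNA 9/18, cfDNA 12/18, CEA 2/18 at baseline; MRD
3/18; pre-chemotherapy detection 7/9; one molecular recurrence 90 days
before clinical evidence). VAF magnitudes reuse printed values where
available; all other values are synthetic placements on the documented
side of each cutoff, since no per-sample data are deposited. The fixture
is pure code and regenerates bit-identically.

## Numerical choices and problem sizes

Tolerances: rank-position interpolation is exact arithmetic; interval
calibration targets are Monte-Carlo bounded (±1 percentage point at 500
cohorts × 10,000 fresh blanks). The acceptance script and test suite use
500 blank cohorts, 40-replicate LOQ sets over levels 0.1–1.0 % VAF, 200–
500 wells for recovery checks, and 1,000 permutations for type-I-error
calibration — sizes chosen so every check completes in seconds while
keeping Monte-Carlo error well inside the asserted tolerances.

## Known limitations

* The LOQ search grid is the caller's responsibility; a coarse grid
  returns a conservative (higher) LOQ.
* The VAF interval is approximate for 1–5 positive droplets (log-normal
  on a small count); it is conservative in the calibrations run here.
* Phase assignment assumes R0 resection clears the tumor-evident state;
  incompletely resected disease would need an explicit progression event.
* The recurrence detector pairs each molecular call with the next
  clinical event only; interleaved multi-lesion histories are out of
  scope.
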
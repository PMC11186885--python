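# Methods

## Scope

`tdpengine` implements a complete analysis pipeline for TDP-43-related
neuropathology in NACC-style multicenter autopsy data: a rule-based
classifier that assigns each fully assessed participant one of four TDP-43
categories (No TDP-43, LATE-NC with stage 1–3, ALS/FTLD-TDP with subtype,
Other TDP-43 with named reasons), availability/missingness analytics for
the registry as a whole, and association models linking the categories to
clinical diagnoses and co-pathologies.  Because the real data are
request-only, the package ships a seeded synthetic-cohort generator whose
defaults emulate the published landscape of the complete-case sample, so
every stage is exercisable and testable offline.

## The category rules

Assignment is strictly top-down over complete cases (all four brain
regions — amygdala, hippocampus, EC/ITC, neocortex — plus the FTLD-TDP
designation, the motor-neuron inclusion assessment, and HS-A all
performed):

1. **ALS/FTLD-TDP** — an FTLD-TDP designation or TDP-43-type motor-neuron
   inclusions, irrespective of anything else.  Subtype: FTLD-only /
   ALS-only / both.  A designated record with no regional TDP-43 anywhere
   keeps the category but receives a QC warning (possible entry error).
2. **No TDP-43** — no TDP-43 in any brain region and no designation.
   Spinal-cord-only TDP-43 stays here (the categories are defined on brain
   TDP-43); the finding is preserved in the rule trace.
3. **Other TDP-43** — brain TDP-43 plus a LATE-NC-exclusionary condition:
   CBD, CTE, acute/chronic TBI, Huntington disease, Guam/Kii parkinsonism,
   an FTD-related mutation, or an autosomal-dominant-AD mutation.
4. **Other TDP-43 (neocortical pattern)** — neocortical TDP-43 without
   TDP-43 in *both* the amygdala and hippocampus is not an admissible
   LATE-NC distribution.  Because this rule runs after the complete-case
   filter, "without" means assessed-and-absent, never not-assessed.
   An EC/ITC+neocortex pattern with neither amygdala nor hippocampus also
   lands here and is flagged in the trace rather than silently absorbed.
5. **LATE-NC** — everything remaining, staged: stage 2 = amygdala and
   hippocampus involved; stage 3 = additionally neocortex; stage 1 = any
   other limbic pattern (amygdala, hippocampus and/or EC/ITC).

"Not assessed" and "absent" are never conflated anywhere in the package:
the former excludes a record from complete-case analyses, the latter does
not.

## Statistics

* **Group comparisons** — Wilcoxon rank-sum for continuous variables
  (exact enumeration when both samples have n ≤ 8 without ties, otherwise
  the tie-corrected normal approximation without continuity correction, so
  identical samples give p = 1) and Pearson chi-square for categorical
  variables (no Yates correction by default; a switch enables it).
* **2×2 tables** — cross-product odds ratio with a Wald 95% CI on the
  log-odds scale; a zero margin is reported non-estimable; a single zero
  cell triggers the Haldane–Anscombe +0.5 correction.
* **Adjusted logistic regressions** — each dichotomized outcome on
  category indicators (reference: No TDP-43) plus age at death, sex, years
  of education, and last-visit-to-death interval; complete cases per
  outcome; maximum likelihood via statsmodels.  Dichotomizations are
  fixed: ADNC none/low vs intermediate/high; CAA, atherosclerosis,
  arteriolosclerosis and gross atrophy none/mild vs moderate/severe; Lewy
  bodies present in any region; dementia vs normal/MCI; clinical AD vs
  not-AD/no-impairment.
* **Multilevel models** — a varying intercept per contributing center.
  No installed Python package offers maximum-likelihood binary mixed
  models, so the marginal likelihood is integrated with 101-node
  Gauss–Hermite quadrature and maximized jointly over fixed effects and
  the intercept SD (L-BFGS-B, σ ≥ 0); fixed-effect covariance comes from
  the numerical Hessian at the optimum.  The implementation is
  cross-checked in the test suite against `lme4::glmer` (nAGQ = 25),
  agreeing to ~1e-3 on coefficients and SEs; 25 nodes proved insufficient
  for large clusters, which motivated 101.  With one center or σ → 0 the
  fit coincides with the single-level model; non-convergence is reported,
  never silently defaulted.
* **Post-hoc contrasts** — Wald tests on coefficient differences using the
  fitted covariance (fixed effects only for multilevel fits), p-values
  unadjusted.  No multiple-testing correction is applied anywhere, by
  design.
* **Report rounding** — percentages to the nearest whole percent (half
  up), odds ratios to one decimal; rounding is applied only at render
  time, all stored tables keep full precision.

## The synthetic cohort: what it emulates, and what it does not

The generator's defaults are a *stated world* drawn from the published
complete-case sample: category prevalences 62 / 27 / 9 / 2 % (No TDP-43 /
LATE-NC / ALS-FTLD-TDP / Other), subtype split 79 / 5 / 16 %
(FTLD-only / ALS-only / both), category-specific ages at death
(e.g. 84.0 ± 9.5 LATE-NC vs 71.5 ± 11.0 ALS/FTLD-TDP, truncated to
[40, 110]), APOE4 58% in LATE-NC vs ~32–39% elsewhere, and the full set
of co-pathology rates from the published group table.  Regional-presence
pattern tables per category encode the published pattern shares (LATE-NC:
typical stage 2 amygdala+hippocampus+EC/ITC 46%, amygdala-only 18% —
the printed shares sum to 101% from rounding and are renormalized here by
trimming amygdala-only; ALS/FTLD: all four regions 78%; Other: 29%
all-regions / 27% neocortical-violating / 44% temporal combinations).
Tables are validated at load: a LATE-NC pattern that is empty or violates
the neocortical rule is rejected, as is a nonzero FTD-mutation rate for
LATE-NC truths (definitionally impossible).

Missingness is measure-wise, not monotone, with three mechanisms:

* a record-level "no TDP-43 stain" gate (default 15%) that removes the
  regional, FTLD-TDP and antibody measures jointly — this produces the
  ALS+HS-A-only availability class seen in real data;
* per-measure logistic year-of-death trends (availability rising from
  2014 baselines of 0.80–0.95 at +0.15–0.18 logits/year for the
  stain-dependent measures) with per-center logit intercepts (SD 0.8);
* the outcome-conditional skip: from the split year (2019) onward, an
  assessed TDP-43-negative hippocampus drops the neocortical assessment
  with probability 0.15, emulating the staging-driven practice change.

Under the defaults roughly 40–50% of records survive the complete-case
filter, matching the real registry's order of magnitude.

Ground truth retains every pre-missingness value, so generator–classifier
consistency is exact by construction: on complete cases the classifier
recovers the true category, subtype and stage with 100% agreement for any
valid configuration — this is the central internal-consistency property,
and it is what a green round-trip test establishes.  It does **not**
establish anything about inter-rater variability, regional sampling
ambiguity (which EC vs ITC block, motor vs frontal "neocortex"),
FTLD-TDP subtypes A/B/C, longitudinal visit structure, or real-world
miscoding — none of which the generator models.  The separate
inactive-population generator plants follow-up and autopsy odds ratios
(FTLD vs AD follow-up OR 2.0, autopsy OR 1.8, etc.) with per-center
intercepts for the Part-I models; its OTHER_IMPAIRED autopsy OR defaults
to 1.0 (no published anchor).

Random substreams are allocated per center and consumed per participant
in cohort order, so enlarging one center never changes another center's
records; generation and missingness use disjoint seed sequences derived
from the single config seed.

## Numerical choices and degenerate inputs

* Truncated normals are drawn by rejection (acceptance ≈ 1 at all
  configured bounds; deterministic fallback to the clipped mean after
  1000 rejections, never reached in practice).
* Perfect separation and non-convergence in logistic fits surface as
  `estimable=False` results with a diagnostic note; odds ratios are never
  fabricated for degenerate categories.
* An empty stratum in the era-split availability comparison reports NaN
  proportions and an undefined test rather than raising.
* A cohort in which no record passes the complete-case filter skips
  Part II with an explicit run-log notice; Part I is still produced.
* Rank-sum variance of zero (all values tied) returns p = 1.
* The era split uses death year ≥ split_year as "during or after".

## Known limitations

* The multilevel model fits a single random intercept; random slopes and
  crossed effects are out of scope.
* The Other-TDP-43 reason list is a closed set tied to the coded flags;
  free-text pathology is not parsed.
* Venn/overlap outputs are tabular counts and proportions; no
  area-proportional layout is computed.
* The synthetic availability model treats measures as conditionally
  independent given the stain gate, year and center; real centers show
  richer correlation structure.
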
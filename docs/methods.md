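# Methods

This note documents the models, rules, and numerical choices behind
`crcdqi`: how the three instrument scores are defined, how the
psychometric evaluation statistics are computed, what the synthetic
cohort generator does and does not emulate, and where the design was
genuinely open.

## The instrument

The Colorectal Cancer Screening Decision Quality Instrument (CRC-DQI)
measures whether a patient's screening decision was (a) informed and
(b) concordant with the patient's own goals.  It consists of:

* **10 multiple-choice knowledge items** with one keyed answer each
  (start age, lifetime incidence and mortality per 100, test frequencies,
  complication rates, test accuracy, meaning of normal/abnormal results).
* **8 goals and concerns**, each rated for importance on an integer scale
  from 0 ("not at all important") to 10 ("extremely important"), plus a
  selection of the **top three** goals.
* Two **involvement** items (who made the decision; how involved the
  respondent felt).

The packaged default bank (`src/crcdqi/data/default_bank.yaml`) ships
this retained instrument.  Response records always store knowledge
answers as option *labels*, so reordering options in a configuration
cannot silently change scoring.

## Knowledge score

Each correct response earns one point; the score is standardized to
`100 * n_correct / n_items`.  Two rules matter:

* **Missing = incorrect.**  The denominator is always the full item
  count.
* **Half-completion cutoff.**  Respondents who answered fewer than half
  the items receive no total score.  With an odd item count the rule is
  read strictly: the 5-item brief form requires at least 3 answered
  (`ceil(n/2)`).

Respondents without a total score are excluded from cohort means.  When
every score is defined, the cohort mean equals 100 x the mean per-item
difficulty for *any* joint correctness pattern (both sides count the same
correct answers over the same denominator).  This conservation identity
is what lets published per-item correct counts reproduce published arm
means exactly, and it is property-tested against randomized correctness
patterns with fixed column sums.

Displayed percentages use round-half-up at the precision of the
corresponding published table (integers for item tables, one decimal for
rates); machine-readable outputs always keep full precision.

## Concordance score

A logistic regression of screening group — colonoscopy (1) vs some other
test (0) — on the raw 0-10 goal ratings is fit by unpenalized maximum
likelihood over respondents aged 50+ who have been screened and have
complete ratings on the model goals.  Seven of the eight retained goals
enter as covariates (the sedation goal is excluded by default;
configurable).  Because ratings enter raw, `exp(beta)` is the odds ratio
of colonoscopy per one-point increase in a goal's importance.

Each respondent aged 50+ then receives a predicted probability
`p = logistic(intercept + sum(beta_g * rating_g))` and is classified:

* `p > 0.5` and had a colonoscopy -> **match**;
* `p <= 0.5` and had some other test -> **match**;
* never screened -> **not a match**, by definition, though the
  respondent still receives `p` and an implied preference (these feed
  the never-screened preference summary);
* otherwise -> not a match.

The tie at exactly 0.5 is deliberately an other-test preference and is
enforced bit-exactly.  The concordance score is the percentage of
matches among all eligible respondents — never-screened included — and
every report prints the numerator and denominator, because summary
percentages without denominators are ambiguous.

Numerical choices: Newton-Raphson, log-likelihood tolerance 1e-8, at
most 100 iterations.  Complete separation (detected via the fitter's
separation signal, a singular Hessian, or a diverging coefficient norm
> 50) is an error recommending fewer covariates or explicit
penalization — penalization is never applied silently.  Covariates with
zero variance in the fit subset are dropped from the optimization and
reported with coefficient 0; a cohort with constant ratings therefore
yields slope 0 everywhere and an intercept equal to the log-odds of the
colonoscopy base rate.  Missing model-goal ratings: complete-case for
fitting; at classification time a single missing rating is imputed with
the fit-subset median, and a respondent with more than one missing
rating is flagged and excluded from the eligible denominator (with a
logged warning).  Imputation can therefore never influence the fitted
coefficients.

## Decision-quality indicator

A respondent shows *high decision quality* when both:

* **informed** — knowledge score at or above a threshold.  The default
  rule takes the threshold from the mean knowledge score of a designated
  decision-aid reference cohort; an explicit override is accepted.  The
  comparison uses the unrounded score and is boundary-inclusive
  ("at or above").
* **matched** — their concordance classification is a match.

The cohort summary is the percentage flagged high-quality.  Two
invariants are property-tested: the high-quality rate never exceeds
either component rate, and raising the threshold never increases it.

## Psychometric evaluation

* **Retest reliability**: ICC(2,1) — two-way random effects, absolute
  agreement, single measurement — computed from the ANOVA mean squares,
  with the F-distribution 95% confidence bounds (McGraw & Wong).  The
  form is recorded in every result; the conventional adequacy target is
  0.7.  The ICC form had to be chosen (the convention for test-retest
  of a single administration); zero between-subject variance is reported
  as ICC 0 with a warning rather than an error.  The implementation is
  cross-checked against an independent reference implementation to 1e-9
  in the test suite.
* **Discriminant validity**: Welch (unequal-variance) two-sample t-tests
  on knowledge scores, with the difference in means and its 95% CI.  The
  Welch form was chosen because pooling assumptions are not defensible
  across arms/samples of different sizes and variances.
* **Construct validity**: Fisher's exact test (two-sided) on the 2x2
  table of high decision quality against a doctor-made decision,
  reported with both group proportions and a Wald interval for their
  difference.  The exact p-values are verified against a full
  hypergeometric enumeration on small tables.
* **Feasibility**: mean per-respondent missing-item fractions for the
  knowledge and goal scales, overall and by administration mode; modes
  are compared by a Welch t-test on the respondent-level fractions
  (respondent-level comparison keeps the unit of analysis honest).
  Response rate = responders/invited when an invited count is supplied.
* **Item retention screen**: knowledge items are flagged *too easy*
  above 85% correct; goals are flagged for *ceiling* when more than 50%
  of ratings sit at 10/10, but survive with a retain flag when named in
  the top three by at least 10% of respondents; goals below that
  endorsement floor are flagged as drop candidates; inter-item
  correlation above |r| = 0.8 flags redundancy.  All thresholds are
  configurable; flags are a pure function of (data, thresholds) and
  nothing is deleted automatically.
* **Brief form**: the five-item short form uses identical scoring rules.
  Reported are the Pearson correlation between brief and full scores
  (over respondents with both defined) and, when retest data exist, the
  brief score's ICC.  The published short form was never itemized, so
  the default subset — the first five knowledge items — is an explicit
  convention flagged in every report.

No internal-consistency coefficient is computed: the knowledge items do
not measure a single underlying construct, so alpha would be
meaningless.  No multiplicity correction is applied across the validity
hypotheses.

## Synthetic cohorts

The generator exists so that every statistic has a known-truth test
without any respondent-level data.  A `CohortSpec` fixes:

* cells of (n, arm, mode) and an age distribution (clipped normal);
* per-item correctness probabilities — the shipped presets
  (`online_da`, `online_control`, `clinic`, `provider`) use the
  published per-sample proportions, e.g. 150/163 for the start-age item
  in the decision-aid arm;
* per-goal importance distributions: a discretized, clipped normal with
  an added point mass at 10.  For the three goals with observed ceiling
  behavior the masses are calibrated so the total share of 10/10 ratings
  is about 64% (know whether you have cancer), 57% (find cancer early),
  and 56% (avoid bleeding/tear);
* a true logistic preference structure with coefficients on the
  published odds-ratio scale (1.83 per point for knowing, 0.70 for
  avoiding the tube, ...) and an intercept (0.25) placing the
  colonoscopy share among the screened near 70%;
* a never-screened fraction (assigned independently of the ratings),
  mode-specific missing-completely-at-random rates, and involvement
  probabilities.

Screening assignment has two regimes: `logistic` (observed test is
Bernoulli at the true predicted probability — realistic, and the regime
under which maximum-likelihood refitting recovers the truth) and
`threshold` (observed test follows the implied preference, contradicted
with probability `decision_noise`; at noise 0 a cohort is fully
concordant by construction — the regime for exactness tests).

**Retest generation** uses a replay-or-redraw scheme: each retest value
repeats the test value with probability kappa and is otherwise a fresh
draw from the same marginal.  Covariance algebra gives the population
test-retest correlation — and hence ICC(2,1), since the marginals are
identical — exactly kappa, for binary item responses and discrete
ratings alike.  A latent-score-plus-occasion-noise model was considered
and rejected: discretization and ceiling masses attenuate its ICC in a
distribution-dependent way, so targets would need per-measure
calibration.  With replay-or-redraw, the targets (0.67 for the knowledge
score; 0.47-0.87 per goal) are hit without calibration, which the
recovery tests confirm.

Randomness: one seed sequence per cohort, split into fixed named
substreams (demographics, goals, screening, knowledge, involvement,
missingness, retest), so toggling missingness never perturbs the
upstream draws.  Identical specs produce byte-identical cohorts.

What the generator does **not** emulate — and therefore what passing
tests do not establish about real data: knowledge items are independent
given the arm (no per-respondent ability correlation, so internal
consistency of synthetic knowledge scores is lower than in real
respondents); goal ratings are independent across goals (no real
goal-goal correlation structure; a correlation knob is out of scope);
missingness is completely at random; demographics do not confound
knowledge; never-screening is independent of goals, whereas real
never-screened respondents plausibly differ systematically.

## Problem sizes in the checked examples

The test suite and the acceptance script use simulation sizes chosen to
make Monte-Carlo error small relative to the tolerance being checked:
n = 2000 (single cohort) for 10% odds-ratio recovery, 100 cohorts of
n = 500 for coefficient-mean and Wald-coverage properties, 5-20
replicates of n = 1000 pairs for ICC targets (+-0.05), and 200
replicates at the published arm sizes (163/175) for the knowledge
contrast interval.  Deterministic arithmetic (scoring, concordance and
DQI summaries, response rates) runs at the published denominators
exactly.

## Known limitations

* The published study's respondent-level quantities (fitted coefficient
  values, observed ICCs, the clinic-sample mean, the brief-full Pearson
  correlation of 0.89) depend on the raw survey data and are covered by
  parameter-recovery properties, not by exact reproduction.
* The published summary denominators are mutually inconsistent by one in
  places (150 vs 151 eligible online respondents; 52 vs 53
  never-screened).  The package takes no side: each computation reports
  its own exact denominator.
* The brief-form subset is a convention, not the published selection.
* Separation handling is detection-plus-error; a penalized fallback
  (e.g. Firth) is deliberately out of scope.
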
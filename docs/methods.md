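# Methods

## The estimation problem

A volunteer web panel is a non-probability sample: joining is a choice, and
whatever drives that choice (here: minority sexual identity, liberal and
risk-tolerant attitudes, drinking, smoking, youth, recent partner
acquisition) also drives many outcomes of interest.  A probability
reference survey with trusted design weights provides the benchmark.  PSA
assumes that, conditional on the auxiliary variables entering the
propensity model, panel membership is ignorable; under that assumption
matching the panel's propensity distribution to the reference removes the
self-selection bias.  Nothing in the machinery tests the assumption — the
synthetic scenarios below are built precisely so that it holds (or fails in
a known way), which is what makes parameter recovery checkable.

## Pipeline

1. **Base weights.**  The reference survey keeps its supplied standard
   weights.  The panel gets initial weights by post-stratifying the full
   gender x age-group cross-classification to census margins ("age and sex"
   and "age-within-sex" coincide under the full cross-classification, which
   is why it is used); cell weight = census proportion / sample proportion,
   normalised to mean 1.  Normalisation is cosmetic: PSA ratios and odds
   ratios are invariant to rescaling either survey's weights (tested).
2. **Staged propensity models.**  Per gender, five cumulative stages
   (demographics; + sexual identity; + lifestyle; + attitudes; + sexual
   behaviours).  Each stage runs backward stepwise selection starting from
   the previous stage's selected variables (forced) plus the stage pool.
3. **Subclassification.**  Fitted probabilities for all participants of
   both surveys are pooled and cut at the quintiles of the unweighted
   combined score distribution; per-subclass PSA ratios multiply the panel's
   initial weights.
4. **Evaluation.**  Weighted prevalences, ORs vs the reference, absolute
   ORs, small/moderate/large classification, and the mean absolute OR over
   the configured outcome set (22 by default).
5. **Variance.**  Bootstrap replicate weights (below).

## Model-fitting choices

* **Weighted fits.**  Coefficients maximise the weight-multiplied binomial
  log-likelihood (statsmodels GLM with frequency weights; IRLS, tolerance
  1e-8, max 100 iterations).  Survey weights are not frequencies, so naive
  likelihood-based inference is invalid; all selection tests are joint Wald
  tests per variable on the HC0 sandwich covariance.
* **Whole-variable selection.**  Multi-level categoricals enter and leave
  as blocks (one joint test over their dummies), matching how selected
  variables are reported per stage.
* **Determinism.**  Ties on p-values remove the variable later in the
  candidate ordering; level coding sorts levels lexicographically with the
  first as reference.  Stepwise is otherwise invariant to candidate order
  (tested).
* **Separation.**  A candidate whose coefficient exceeds 12 in absolute
  value (odds ratio > 1e5) is treated as separating and removed with a
  warning: an unbounded coefficient gives degenerate 0/1 scores that break
  subclassing.  A forced variable cannot be removed and will surface as a
  convergence failure instead.
* **Missing data.**  Fitting is complete-case with respect to the stage's
  variables.  A participant missing any model covariate gets a missing
  score and falls back to their age-within-sex cell weight — the same value
  post-stratification assigned them.

## Subclassing details

* Quintile boundaries are the smallest score whose empirical CDF reaches
  20/40/60/80% of the combined **unweighted** scores ("equally sized
  subclasses" read as equal participant counts; weighted quintiles are
  available as an option).  Scores equal to a boundary go to the lower
  subclass.
* Coincident boundaries (heavily tied scores, e.g. when a stage selects a
  single categorical variable) merge into fewer, wider subclasses, each tie
  group wholly inside one subclass.  With all scores equal (intercept-only
  model) there is a single subclass with ratio 1 and the adjustment passes
  the initial weights through unchanged.  A subclass containing no panel or
  no reference participants (non-overlapping score distributions) is an
  error, not a silent fix.
* The construction forces the PSA-weighted panel subclass distribution to
  equal the reference's weighted distribution exactly; the test suite
  asserts agreement to 1e-12 at every stage.

## Bootstrap variance

Panel members are resampled with replacement (same size; the panels are
unclustered volunteer samples), and each replicate reruns
post-stratification, a refit of the stage's coefficients with the selected
variable set held fixed, pooled quintiles, PSA ratios and final weights.
Redoing stepwise selection per replicate is available as an option but off
by default.  The reference survey never varies: it is the benchmark and its
uncertainty is deliberately ignored.  Replicates hitting an empty
post-stratification cell or subclass are dropped and counted; more than 10%
failures aborts.  Replicate b is seeded by the pair (seed, b), so enlarging
B extends the replicate stream without reshuffling.  B defaults to 500
(stabilises an SE to a few percent relative error); the packaged variance
analyses use B=300, which keeps a full 2-gender, 6-weighting run around two
minutes on one CPU.

The SE of an outcome's absolute OR is the sample standard deviation of the
replicate absolute ORs; the average SE across outcomes is the precision
metric.  The SE is also computed on the log-OR scale, and the bias-precision
trade-off is assessed there: the absolute-OR SE shrinks mechanically as the
adjustment pulls ORs towards 1 (larger ORs have larger SEs), so the
absolute-scale stage-5/age-sex ratio can sit below 1 even while the weights
have clearly become more variable.  On the log scale the default scenario
shows the expected inflation (ratio ≈ 1.4); both scales are reported.

## Synthetic scenarios

The generator emulates the *structure* of the real evaluation: all
variables categorical/binary (so every population quantity has an exact
enumeration oracle over the discrete cells), a finite population of 100,000
adults 18–44, a reference sample of 5,000 drawn (optionally with unequal
known inclusion probabilities) without replacement carrying inverse-
probability weights, and a panel of 2,000 drawn without replacement with
probability proportional to a logistic joining propensity
(Efraimidis–Spirakis sampling).  Optional MCAR missingness exercises the
fallback-weight path.

* **Strong selection** (default): joining depends on identity, attitudes,
  lifestyle, demographics and the two behaviour auxiliaries — all visible
  to the stage-5 pool — with coefficients fixed once by exact enumeration
  so the age-sex-weighted average absolute OR is ≈1.46 (male) / 1.43
  (female) at population level; gay/lesbian and bisexual identities end up
  ≈7x / 4.5x over-represented.  The joining intercept is low (−6) to keep
  propensities off the saturation regime, making selection effectively
  log-linear.
* **Null**: intercept-only joining; the panel is a simple random sample.

What the generator does **not** emulate: panel recruitment dynamics, quota
setting and relaxation, within-panel nonresponse, mode/reporting effects,
continuous covariates, and informative missingness.  Passing recovery tests
therefore show the *machinery* is correct and that PSA removes bias when
its ignorability assumption holds by construction — they say nothing about
whether that assumption holds for any real panel.

## Validation studies and problem sizes

* Published-table reproduction: ORs recomputed from the printed prevalence
  columns (3 dp) agree with the printed ORs (2 dp) within 0.02 on all 44
  rows, and the small/moderate/large rule applied to the printed ORs
  reproduces every printed category and the headline counts (15 moderate
  male stage-5; 6 large male age-sex; 9 moderate-or-large female stage-5;
  3 large female age-sex).  Classification for table reproduction uses the
  OR rounded to 2 dp as printed; pipeline use is full precision.  Boundary
  values (exactly 1.25 or 1.67) classify as moderate; no printed row sits
  on a boundary.
* Null recovery: five independent scenario draws at default sizes, both
  genders; the mean average absolute OR stays below 1.1 at every weighting
  (the residual ≈1.08 is the Monte-Carlo noise floor of 22 ORs at these
  sample sizes, not bias).
* Correct-specification recovery: one male-stratum run at n_web=10,000;
  age-sex weighting >1.3, stage-5 <1.1, stage profile non-increasing up to
  noise.
* Stepwise type-I: 500 replicates of a pure-noise binary candidate at
  n=4,000 retain it at a rate inside the binomial 95% interval around 0.05.
* Bootstrap calibration: in the null scenario with an intercept-only
  propensity model the bootstrap log-OR SE matches sqrt(1/(n p (1-p))) on
  the panel side within 15% at B=500 (observed ≈1–7% across seeds).

These sizes keep the whole validation suite under a minute of CPU apart
from the bootstrap analyses (~2 minutes), while leaving comfortable margins
on every bound.

## Known limitations

* The subclassification estimator is coarse by design; with five subclasses
  a residual few percent of the log-odds bias survives even under correct
  specification — visible as stage-5 averages of ~1.05 rather than 1.0 at
  n_web=10,000.
* The absolute-OR transform is non-smooth at OR=1, so its bootstrap SE is a
  slightly biased estimator for outcomes with true OR near 1; the log-OR SE
  is the cleaner diagnostic.
* Stepwise selection inherits the usual caveats (post-selection inference
  is not attempted; p-values of selected variables are reported as fitted,
  not selection-adjusted).
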
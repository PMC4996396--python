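# Methods

`lungsig` re-creates, as tested code, a complete evaluation framework for
batch-effect handling in autoantibody protein-microarray screens: a
generator for six-run screening datasets, the preprocessing rules used for
GenePix exports, three adjustment strategies, PVCA variance attribution,
class-comparison concordance, and cross-validated classifier panels.  This
note records the models, the defaults and why, the numerical choices, and
what the synthetic data can and cannot show.

## The generative model

Log2 intensity of antigen (feature) $g$ on array $j$ processed in run $i$:

$$
y_{gj} \;=\; \mu_g \;+\; x_j^{\top}\beta \;+\; \Delta\,\mathbf 1[\text{case}_j \wedge g \in R]
\;+\; s_i \;+\; \gamma_{ig} \;+\; \delta_{ig}\,\varepsilon_{gj},
\qquad \varepsilon_{gj}\sim\mathcal N(0,\sigma^2).
$$

- $\mu_g \sim \mathcal N(8,\,1.2^2)$: baseline log2 reactivity.  The left
  tail deliberately dips below the preprocessing floor $\log_2 100 \approx
  6.64$, so a realistic fraction of antigens is partly or fully censored.
- $R$: the planted reactive set, $|R| = \text{round}(f\cdot n)$ with
  $f = 0.02$ by default; $\Delta = 0.585 = \log_2 1.5$, the class
  difference the study's power calculation assumed.
- $\gamma_{ig} \sim \mathcal N(0, 0.5^2)$: additive per-run, per-feature
  batch effects; $\delta_{ig}^2 \sim \text{InvGamma}(a, a-1)$ with shape
  $a = 30$ (mean 1): multiplicative batch dispersion.  This is exactly the
  location/scale model ComBat assumes, with its parametric prior family, so
  the adjuster's assumptions hold by construction in the null case.
- $s_i$: a session offset, $+0.25$ for runs 1–3 and $-0.25$ for runs 4–6
  (`session_shift = 0.5`).  The source screening showed the six runs
  clustering into two session super-groups on the first principal
  components; the separation magnitude is not quantified anywhere, so 0.5
  log2 units — matching the additive batch SD — is this package's
  calibration choice.
- $\sigma = 0.414$: the 50th percentile of the within-class SD
  distribution used in the study's sample-size calculation.
- Duplicate printing: each feature is emitted as two spots
  $y \pm \mathcal N(0, 0.15^2)$.  With the baseline spread above, 0.15
  reproduces the reported within-array duplicate-spot Pearson correlation
  of ~0.98.
- Spots are flagged (bad) independently with probability 0.01; each slide
  carries 281 positive-control spots (E. coli lysate at 0.3/0.4/0.5 mg/mL,
  intensity linear in concentration with noise set so $R^2 \approx 0.97$)
  and 82 negative buffer spots kept below the floor of 100.
- Covariates (sex, age group in the four bins 0–56/56–64/64–70/70–100,
  smoking) are sampled from the cohort's marginal frequencies and have
  zero effect by default, matching the finding that they contributed
  0.02–0.06% of variance.

The design is the six-run layout: four pure runs (18 cases of one
histology + 18 controls) and two mixed runs (7+7 cases of two histologies +
14 controls); 25 cases per histology, 200 arrays total.

Spot tables carry raw-scale ($2^y$) intensities so the GPR writer/reader
and the floor→log2 preprocessing round-trip the model exactly.

## Preprocessing

Fixed order: floor raw intensities at 100 → log2 → average duplicate spots
(flagged spots removed first; a feature is missing on an array only when
both duplicates are unusable) → exclude features missing on ≥ 50% of
arrays (inclusive comparison on exact rationals) → exclude features with
zero variance (antigens fully censored at the floor carry no information
and their point mass breaks scale models downstream) → feature-wise 10-NN
imputation.  Imputation distances are mean squared differences over
co-observed arrays; candidate neighbours must be observed on the target
array; ties break by feature order; k clamps to the available candidates.
Observed cells are never altered.

## Batch adjustment

**Quantile normalization** maps every array onto the across-array mean of
sorted columns; ties receive the mean of the reference values over the
tied rank span, making the result invariant to row permutations.

**ComBat** (parametric empirical Bayes).  Per-feature OLS on batch dummies
(optionally plus protected covariates) gives the grand mean
$\hat\alpha_g$ and pooled residual variance $\hat\sigma_g^2$ (denominator
$n$); standardized data $Z$ give raw per-batch effects $\hat\gamma_{ig}$
(batch means) and $\hat\delta^2_{ig}$ (batch variances, $n_i - 1$).
Method-of-moments priors: $\gamma \sim \mathcal N(\bar\gamma_i,
\bar\tau_i^2)$ across features, $\delta^2 \sim
\text{InvGamma}(\lambda_i, \theta_i)$ with $\lambda = (2s^2 + m^2)/s^2$,
$\theta = (ms^2 + m^3)/s^2$.  The coupled posterior equations

$$
\gamma^* = \frac{n_i\bar\tau^2\hat\gamma + \delta^{*2}\bar\gamma}
                {n_i\bar\tau^2 + \delta^{*2}},\qquad
\delta^{*2} = \frac{\theta + \tfrac12\sum_j (Z_{gj}-\gamma^*)^2}
                   {n_i/2 + \lambda - 1}
$$

iterate to a relative tolerance of 1e-8.  Adjusted data:
$y^* = \hat\sigma(Z-\gamma^*)/\delta^* + \hat\alpha + x^{\top}\hat\beta$.
The default excludes biological covariates from the design (the era's
default); protecting the class label is available via the `covariates`
argument.  Only the parametric variant is implemented.  The test suite
checks the estimates against a step-by-step transcription oracle (1e-8)
and against the reference R implementation (`sva::ComBat`) run through
Rscript.

**DWD merging.**  The distance-weighted discrimination direction between
two batches solves $\min \sum_i 1/r_i + C\sum_i \xi_i$ subject to
$r_i = y_i(x_i^{\top}w + \beta) + \xi_i > 0$, $\xi_i \ge 0$,
$\lVert w\rVert \le 1$.  Optimizing the slacks out analytically leaves the
smooth convex loss $V(u) = 1/u$ for $u \ge 1/\sqrt C$ and
$2\sqrt C - Cu$ otherwise, minimized over the span of the arrays (a
component of $w$ orthogonal to every array changes no margin and wastes
norm budget), so the problem has at most $n_\text{arrays}+1$ variables and
is solved with a trust-region constrained optimizer.  The penalty defaults
to $C = 100/\text{median}^2$ of pairwise distances, a scale-invariant
heuristic.  Merging translates each batch along $w$ so both mean
projections land on the pooled mean; within-batch geometry is untouched.
Because only two batches merge at a time, six runs are merged along a
binary tree, by default ((1,2),3) and ((4,5),6) before joining the two
session groups — group-first merging with chronological pairing inside
each group, chosen for determinism since the exact within-group pair order
of the original analysis is not recorded; the tree is configurable.

## PCA and PVCA

PCA is computed on arrays after feature-wise centering (SVD); scores are
reproducible up to sign.  PVCA retains the leading PCs up to 60%
cumulative variance, fits each retained PC score vector with a
random-effects model holding one variance component per factor (run, type,
sex, age, smoking) and per pairwise interaction, converts each PC's
components to proportions, averages them weighted by eigenvalue share, and
renormalizes.

The per-PC fit maximizes the restricted likelihood directly: the score
covariance is $V = \sum_k s_k^2 K_k + s_e^2 I$ with block kernels
$K_k = Z_kZ_k^{\top}$ (elementwise products for interactions), and
L-BFGS-B runs on log-variances with analytic gradients, started from a
non-negative-least-squares (method-of-moments) fit of the empirical outer
product on the kernels; that NNLS fit is also the fallback if the
optimizer fails.  This direct fit was chosen because generic mixed-model
routines proved unreliable on this fully crossed 16-component design; it
is validated against lme4's REML on crossed toys in the test suite.
Identical factor groupings (confounded pairs) are rejected with an error
naming the pair.

A finite-sample caveat: with few arrays, the 16 components can soak up
chance variance on individual PCs, deflating the residual share.  At the
study's 200 arrays pure noise attributes > 90% to the residual, as it
should.

## Class comparison and concordance

Per-feature two-sample t-test, pooled variance by default (the referenced
analysis software's convention; Welch available).  Features whose pooled
within-group SE is ≤ 1e-10 get p = NA and never enter the significant
list: antigens floored across an analysis subset leave only float dust in
the variance, and their t would otherwise be numerical noise.  The
significant list uses strict p < 0.001 with no multiplicity correction
(the study's rule; an FDR column can be derived from the emitted table).

Relative overlap of two significant lists is
$100\,\lvert A\cap B\rvert / \lvert A\cup B\rvert$, rounded to one
decimal; the union denominator is validated by reproducing the printed
worked example (340 and 392 antigens sharing 318 → 76.8%).  The
concordance table runs, per adjustment method and histology, the
single-run analysis (e.g. SCLC: run 1) and the cross-run analysis (run 1
+ the SCLC cases and controls of run 5) and reports the overlap between
the two lists — the study's yardstick for ranking adjustment strategies.
In the mixed runs the case:control ratio differs from the pure runs
(7:14 vs 18:18), so uncorrected batch effects partially confound class in
cross-run analyses; this is what makes the criterion discriminating.

Sample size per class uses the two-sided normal approximation
$n = \lceil 2(z_{1-\alpha/2}+z_{1-\beta})^2\sigma^2/\Delta^2\rceil$; with
$\alpha=0.001$, power 0.9, $\Delta = 0.585$, $\sigma = 0.414$ it returns
21, matching the printed calculation.

## Classifier panels

Feature selection (inside every LOOCV fold):

- *Greedy pairs*: rank by pooled |t|; take the best remaining gene, pair
  it with the gene maximizing the two-sample |t| of the projection onto
  the pair's diagonal-LD direction (weights = mean difference / pooled
  variance per gene), remove both, repeat.
- *SVM-RFE*: train a linear soft-margin SVM (C = 1), drop the half of
  features with smallest |weight| (floor), repeat; the final round trims
  exactly to the target size.  Ties break by feature order.

Models: compound covariate predictor (threshold at the midpoint of class
mean scores), DLDA, k-NN (Euclidean, odd k), nearest centroid, linear SVM
(C = 1), and the Bayesian CCP (two-Gaussian model on the compound score
with pooled variance and class-frequency priors, 0.5 posterior cut).
All prediction ties resolve to "control" — deterministic and conservative
for a diagnostic.  LOOCV is complete: the held-out array influences
neither ranking, pairing, nor elimination in its fold (asserted by a
spike-the-held-out-array test).  Reported metrics are the correct
classification rate, sensitivity (cases) and specificity (controls);
they satisfy $CC\cdot(P+N) = \text{sens}\cdot P + \text{spec}\cdot N$
exactly.  Panel overlaps across histologies are reported as all 15
exclusive regions of the four-set Venn diagram.

## What the synthetic data does and does not show

The generator reproduces the statistical skeleton the methods assume:
location/scale batch structure, the session super-grouping, duplicate
printing, censoring at the floor, flags, control spots, and a
case-reactive antigen subset at the study's assumed effect size.  Passing
tests therefore demonstrate that the pipeline's machinery is correct and
that its qualitative findings (ComBat removes the run variance component;
adjusted data keep single-run findings alive across runs; complete CV does
not leak) are reproduced under the assumed model.

It does **not** emulate: histology-specific reactivity (planted antigens
are shared by all cancer cases, so per-histology classifier panels overlap
far more than real panels would and classification saturates easily),
heterogeneous per-antigen effect sizes or per-patient antibody repertoires,
spatial/print-tip artifacts, IgG concentration differences between classes,
or non-Gaussian reactivity distributions.  Quantities that depend on real
biology — the original screening's significant-antigen counts, overlap percentages
and accuracy table — are not reproducible from synthetic data and are not
claimed; only desk-derivable printed values (the 76.8% worked example, the
0.585 log2 difference, n = 21) and model-level behaviors are asserted.

## Numerical choices and degenerate inputs

- Exact rational comparison for the ≥ 50% flag-exclusion rule.
- Variances below 1e-20 (float dust from averaging) are treated as zero;
  such features are excluded (preprocessing) or reported as p = NA
  (class comparison) or rejected with an error naming the feature
  (ComBat).
- EB fixed point: relative change < 1e-8 (configurable); denominators
  guarded at 1e-30.
- DWD: solver failure raises with the solver status; the returned
  direction is normalized to unit length.
- PVCA: log-variance bounds [-30, 10] after scaling the scores to unit
  variance; a PC with zero variance contributes pure residual.
- One master seed drives generation; pipeline stages derive child seeds
  via `numpy.random.SeedSequence`.

## Default problem sizes

The analysis drivers and the reproduction script simulate 2000 features ×
200 arrays — full study scale in arrays and design, reduced in features.
Feature count affects only the resolution of feature-level summaries (the
EB priors and PVCA are stable from a few hundred features up); the choice
keeps a full pipeline run in the minutes range on one core.
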
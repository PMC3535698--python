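# Methods

## The model

`bcmicro` fuses the prediction scores of six miRNA target-prediction
tools — TargetScan, miRanda, PicTar, mirTarget, PITA and Diana-microT —
into a single posterior probability that an mRNA is a true target of a
miRNA. Let x₁…x₆ be the six scores for one (miRNA, gene) pair and y the
latent target status (y = 1: true target). Each tool only reports scores
above its internal cutoff, so missingness is informative: a per-tool
indicator sᵢ records whether tool i reported anything, with
class-conditional reporting rates p(sᵢ=1|y=1) = TPR and
p(sᵢ=1|y=0) = FPR (complements FNR, TNR).

Given y the tools are modeled as independent, so

    p(y=1 | x₁…x₆) ∝ p(y=1) ∏ᵢ p(xᵢ | y),

and marginalizing the indicator leaves exactly one term per tool:

    p(xᵢ | y) = p(xᵢ | sᵢ=1, y) · p(sᵢ=1 | y)   if xᵢ is present,
    p(xᵢ | y) = p(sᵢ=0 | y)                      if xᵢ is missing,

because a numeric score is impossible when the tool was silent and a
missing score impossible when it was not. Conditional independence given
y is an approximation — the six tools share features such as seed
complementarity and binding energy, so their scores are correlated even
within a class; the fusion is therefore naive-Bayes-like and its
posterior magnitudes should be read as rankings more than calibrated
probabilities on real data.

All likelihood products are computed as sums of logs with a final
log-sum-exp; six density factors can underflow double precision
otherwise.

## Conditional score densities

Each tool × class gets a parametric family fitted by maximum likelihood
on the non-missing scores of that class (`cond_dists`):

| family | parameters | support transform | default use |
|---|---|---|---|
| `gamma_reflected` | shape, scale | density of r − x, r = max + 1e-9·range | TargetScan (both classes) |
| `negative_binomial` | size, prob | counts = round(scale·(x − min)) | miRanda (both classes) |
| `gamma` | shape, scale | x − shift; shift 0 when all scores > 0, else min − 1e-9·range | PicTar (both classes) |
| `gaussian_mixture_2` | weights, means, sds | none | mirTarget positives |
| `gaussian` | mean, sd (1/n MLE) | none | PITA (both classes) |
| `exponential_shifted` | rate | x − min | mirTarget negatives, Diana-microT (both classes) |

Notes on the choices:

* The reflection point for left-skewed scores is the sample maximum plus
  a 1e-9·range offset so the largest training score keeps positive
  density; it is stored in the model and reused at prediction time.
* The NB fit discretizes real-valued scores by shifting to min 0,
  multiplying by a configurable `scale` (default 1) and rounding; the
  size parameter is found by maximizing the profile likelihood (the NB
  mean MLE is the sample mean for any size), a bounded 1-D search over
  log-size.
* The unreflected Gamma keeps a zero shift for strictly positive scores:
  fitting a two-parameter Gamma to min-shifted data biases the shape
  estimate noticeably (≈10 % low for Gamma(3, 2) at n = 10⁴), so the
  min-anchored shift is only a fallback for data with non-positive
  values.
* The two-component mixture is fitted by EM with fixed, reproducible
  initialization (means at the 25th/75th percentiles, sds at half the
  sample sd, weights ½/½), stopping when the log-likelihood improves by
  < 1e-8 or at 500 iterations, with up to 5 seed-controlled jittered
  restarts if a component collapses (sd < 1e-6·range). Components are
  reported in ascending-mean order.
* Every density is floored at 1e-12 (configurable per fit) so one score
  outside the fitted support cannot force a 0/0 posterior; reporting
  rates are clamped to [1e-9, 1 − 1e-9] before logs for the same reason.
* Fit preconditions: ≥ 10 scores (≥ 20 for the mixture) with non-zero
  variance; violations raise typed errors naming the tool and class when
  they occur inside `train_model`.

## Training

`train_model` estimates, from one labeled score table: the twelve
conditionals (class-stratified, non-missing scores only), the per-tool
reporting rates as presence fractions within each class, and the prior
as the positive label fraction unless overridden. The bundled
`mir124_reference_rates.tsv` carries the six tools' reporting rates
estimated on a miR-124 Ago2-IP reference (22 luciferase-validated plus
256 IP-enriched positives vs 19 780 negatives), and
`reference.REFERENCE_PRIOR = 0.0133` is the genome-wide prior published
with that benchmark. The prior is stored as a constant because its
source arithmetic is not recoverable: the stated counts give
278/20058 ≈ 0.01386, not 0.0133. Using one miRNA's reference for all
miRNAs assumes every tool performs consistently across miRNAs; the
package makes that assumption optional by default (rates come from
whatever labeled table is supplied; the fixture is an override).

Negative training pairs from over-expression microarrays are selected by
`negative_pair_filter`: up-regulated, differential-expression
p < 0.001 and linear fold change > 1.5, both strict so boundary values
are excluded.

## Evaluation

* `roc_curve` sweeps thresholds over the unique present scores (ties
  enter the called set together); records with missing scores count only
  in denominators, so the realized curve stops at the tool's coverage
  limit (max reachable FPR = fraction of negatives with any score).
  With `extrapolate=True` a straight segment continues to (1, 1) — the
  dashed-line convention for partially covering tools — and the
  trapezoidal AUC includes it. The extrapolated AUC equals the
  Mann–Whitney concordance obtained by ranking all uncalled records in
  one tie below every called one (a property test asserts this).
  Per-tool orientation flags (`DEFAULT_DIRECTIONS`) encode that more
  negative TargetScan context scores and PITA energies mean stronger
  targets.
* `five_fold_cv` uses a seeded stratified 5-fold partition (both classes
  in every training split), trains on four folds, scores the held-out
  fold, and pools the out-of-fold posteriors into one ROC.
* `cumulative_downfold` computes the running cumulative sum c(t) of
  protein log fold changes over a ranked prediction list and the area
  A(n) = Σ_{t≤n} c(t); more negative is better. Genes absent from the
  proteomics table are skipped without consuming rank positions. Both
  sums are plain left-fold accumulations so they match a literal double
  loop bit-for-bit. `average_downfold` gives F(n), the mean of A_i(n)
  over miRNAs; a `table6_convention` switch divides by 2M instead of M
  to reproduce a published summary table whose entries equal half the
  plain mean.

## Synthetic data

`synthetic.generate` draws tables with exactly the generative structure
the fusion assumes: y ~ Bernoulli(prior), sᵢ ~ Bernoulli(TPR or FPR),
present scores from the class conditional. One seeded stream is consumed
in fixed record/tool order, making runs byte-reproducible. Two built-in
specifications share the bundled miR-124 reporting rates and
artifact-default density shapes (chosen to resemble each tool's score
histograms — e.g. reflected-Gamma context scores in roughly [−1.5, 0],
NB alignment scores around 140–170, a bimodal positive class for the
SVM-probability-like mirTarget scores; they are illustrative defaults,
not published parameter values):

* `reference_spec` — prior 0.0133, the genome-wide condition;
* `balanced_demo_spec` — prior 0.25, the condition used for training and
  cross-validation exercises. At the genome-wide prior a 5 000-record
  table carries ~66 positives, of which a low-coverage tool like PicTar
  scores only ~12 — below the fitters' minimum sample sizes — so
  training-based checks (model recovery at n = 20 000, CV fusion
  dominance at n = 5 000) run at the balanced prior where every
  tool × class stratum is populated.

Because the generator satisfies conditional independence by
construction, passing tests demonstrate correctness of the estimation
and fusion machinery, not that real tool scores meet the independence
assumption; correlated tools would shrink (not invert) the fused
advantage. Problem sizes used by the test suite and acceptance script —
1 000 random fusion oracles, 10 000 draws per density fit, 20 000
records for model recovery, 5 000 for cross-validation — were chosen so
every estimate sits well inside its sampling tolerance.

## Known limitations

* No modeling of inter-tool score dependence; the BN structure is fixed.
* One score per (miRNA, gene) per tool is assumed; per-site aggregation
  (e.g. best miRanda site, total context score) happens upstream.
* Identifiers are opaque strings; no gene-symbol normalization.
* The density families are fixed configuration, not selected by
  goodness-of-fit.
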
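# Methods

This note documents the statistical procedures implemented in
`irlncpair`, the synthetic-data generator used to exercise them, the
numerical choices, and the limits of what the package's tests establish.

## 1. The pair-indicator model

For genes A, B (canonically ordered A < B lexicographically) and sample
s, the indicator is C(A,B,s) = 0 if expr(A,s) < expr(B,s), else 1 — ties
deliberately take the 1 branch, and tie counts are logged so tie-heavy
(e.g. heavily zero-inflated) data can be spotted.  Because C depends
only on the within-sample ordering, the matrix is invariant under any
strictly increasing per-sample transform of expression; this is the
property that lets the downstream risk score travel across platforms
without renormalisation, and it is tested literally (monotone-warp
invariance) rather than assumed.

A pair is *informative* when its one-fraction f across the modeling
cohort satisfies 0.2 < f < 0.8 strictly.  Pairs outside the band are
nearly constant and cannot split the cohort; the bounds are exposed
(`pair_lo`, `pair_hi`).  Only tumor samples enter the pair matrix:
survival modeling concerns tumors, and mixing in normals would let the
validity filter be driven by samples that never contribute follow-up.
Under a train/test split the filter uses the training half only and the
surviving pair list is frozen for the test half.

## 2. Screening chain

* **Biotype split.** Annotation from a GTF (`gene` features; `gene_type`
  preferred over `gene_biotype` when both appear) or a two-column TSV.
  Unannotated genes are dropped with a logged count; biotypes other than
  `lncRNA`/`protein_coding` map to `other`.
* **Immune coexpression.** An lncRNA is immune-related when, for some
  immune gene, |r| > 0.4 and p < 0.001 (both strict), with r the Pearson
  correlation of log2(FPKM+1) and p from the two-sided t transform
  t = r·√((n−2)/(1−r²)).  No multiplicity correction is applied inside
  this screen (it is a raw-p gate).  Default uses all samples
  (tumor + normal); `coexpr_samples="tumor"` and Spearman correlation
  are available because the field is split on both conventions — the
  package takes no position on which matches any particular study.
* **Differential expression.** A two-group moderated t on log2(FPKM+1):
  per gene, pooled residual variance s²_g on d_g = n_t + n_n − 2 df; an
  inverse-chi-square variance prior (d₀, s₀²) fitted by method of
  moments on log s²_g using digamma/trigamma identities (trigamma
  inverted by Newton); posterior variance
  s̃² = (d₀s₀² + d_g s²_g)/(d₀ + d_g); two-sided p on d₀ + d_g df; BH
  across the post-coexpression gene set only, since that is the tested
  family.  When every residual variance is zero the prior is degenerate
  and the test falls back to Welch's t with a warning.  The d₀ → ∞
  closed-form limit (ordinary z with the pooled prior variance) is kept
  as a test hook.  Genes pass at |log2FC| > 2 and FDR < 0.05, both
  strict; the fold-change gate is two-sided so both up- and
  down-regulated genes survive.

## 3. Signature selection

All survival likelihoods in the package are the **Breslow** partial
likelihood, fitted by damped Newton–Raphson to |Δβ|∞ < 1e−8.  One
likelihood definition everywhere makes AIC values comparable across the
univariate screen, the stepwise search and the forest tables, and makes
every fit checkable against a brute-force grid search.  Monotone
likelihoods (coefficients leaving |β| ≤ 20) are flagged non-converged
and the offending pair excluded with a warning.  Efron weighting is not
offered: simulated event times are continuous (day-rounded), so ties are
rare, and the exactly-testable estimator was preferred.

* **Univariate screen.** One fit per pair; survivors at Wald p < 0.05
  (configurable).  The threshold is a conventional default — the
  screen's purpose is to keep the lasso problem well-posed, not to
  control error rates.
* **Repeated lasso.** R cycles (default 1000; reduced in tests).  Each
  cycle draws a patient bootstrap resample (63.2% subsampling available),
  fits the L1 Cox path (scikit-survival's coxnet), and picks the penalty
  by 10-fold cross-validated partial likelihood in the
  Verweij–van Houwelingen difference form, evaluated with the package's
  own Breslow log-likelihood.  The pairs with nonzero coefficients at
  the chosen penalty are recorded; a pair's selection frequency over the
  R cycles measures its stability, and pairs reaching `min_freq`
  (default 2) are selected.  Resamples with fewer than two events are
  redrawn with a log entry; a cycle that keeps failing is skipped, and
  the stage aborts only if every cycle fails.  One integer seed spawns
  independent per-cycle generator streams, so the frequency table is
  reproducible and insensitive to skipped cycles.
* **Stepwise Cox.** Bidirectional AIC search from the full model over
  the selected pairs: at each step all single-term drops (lexicographic
  order) then all re-adds are evaluated and the lowest-AIC move applied;
  the search stops when no move improves AIC.  The empty model is a
  legal outcome — on null data the pipeline reports no signature rather
  than inventing one.  A non-converging full model restarts with a tiny
  ridge (1e−6) and a warning.
* **Zenith rule.** Candidate models are nested prefixes of the selected
  pairs ordered by descending lasso frequency (univariate p, then pair
  id, as tie-breaks).  Each candidate is refitted and its 3-year AUC
  computed; the first candidate attaining the maximum AUC — the point
  where the AUC-vs-size curve peaks — is the final model, and the whole
  trace is written for inspection.  The stepwise model is reported
  alongside (`stepwise_signature.tsv`) because the two reductions answer
  slightly different questions (in-sample parsimony vs horizon
  discrimination) and which one a given study "used" is often
  ambiguous; the pipeline scores patients with the zenith choice.

## 4. Risk model

The score is Σᵢ Coefᵢ·xᵢ with xᵢ the 0/1 indicators — no
standardisation, so with n pairs the score takes at most 2ⁿ values.

The time-dependent ROC at horizon t uses the cumulative/dynamic
definition with inverse-probability-of-censoring weights: cases are
subjects with an observed event by t, weighted 1/Ĝ(T⁻); controls are
subjects still under observation after t; Ĝ is the Kaplan–Meier
estimator of the censoring distribution (events and censorings
swapped), and the left limit Ĝ(T⁻) is used so a case is weighted by its
probability of having remained uncensored *up to* its event.  The AUC is
the weighted Mann–Whitney statistic with score ties at half weight.
With no censoring Ĝ ≡ 1 and the estimator reduces exactly to the plain
Mann–Whitney AUC of "event by t" against the score — an identity the
tests verify to 1e−12.  Case weights are capped (default 20) when Ĝ
reaches zero, with a warning.  Times are stored in days and horizons
given in years (conversion 365.25, configurable).

The cutoff maximises Youden's J = sensitivity + specificity − 1 on the
3-year curve (default) or minimises the distance to the (0,1) corner
(`criterion="closest"`); ties go to the smaller threshold, which calls
more patients high-risk.  The per-threshold criterion table is part of
the result, so any other cutpoint rule can be audited against it.
High-risk assignment is strict (`score > threshold`).

## 5. Validation batteries

KM curves and the two-sample log-rank test (lifelines); Pearson
chi-square (no continuity correction) of risk group against stage/T/N/M
with expected counts < 5 flagged; unpaired Mann–Whitney rank-sum
comparisons (exact enumeration when both groups ≤ 8 and untied, else
the tie-corrected normal approximation with continuity correction) for
risk scores across binary clinical regroupings (stage I–II vs III–IV,
T1–2 vs T3–4, N0 vs N1+, M0 vs M1), abundance columns, drug IC50s and
configured checkpoint genes; Spearman correlation of abundances with
the score, BH-corrected within each deconvolution-method label; and
uni/multivariate Cox fits of age, stage, T, N, M (numeric-coded
ordinals) and the continuous score, with collinear covariates dropped
from the joint fit and noted.  Every battery applies BH within itself;
missing clinical codes are dropped per-analysis, not cohort-wide.

## 6. The synthetic generator

The generator's job is to give every stage a recoverable ground truth,
one knob per screen:

* **Expression.** log2 signal x = baseline + loading·F + ΔDE + ε, with
  baseline ~ U(2, 8), a standard-normal latent immune factor F shared by
  the immune genes and the chosen coexpressed lncRNAs, loading 2σ (so
  the population log-scale correlation is 0.8, comfortably past the 0.4
  gate; loading 1 when σ = 0), a tumor-column shift ΔDE = `de_log2fc`
  (default 3) on the DE lncRNAs, and ε ~ N(0, σ = 0.5).  FPKM is
  max(2^x − 1, 0).  Planted-pair members get identical baselines and
  loadings, so their ordering is noise-driven and the pair indicator
  splits the cohort near 50/50 — inside the validity band.
* **Survival.** Event times are exponential with rate
  h₀·exp(Σ βₖCₖ), h₀ = 0.10/yr; administrative censoring is uniform on
  (1, 10) years; observed time is the minimum (rounded to days) and the
  event flag its comparison.  The default planted signature is three
  pairs with β = +0.9, −0.85, +1.0.
* **Clinical covariates.** Age ~ round N(65, 10) clipped to [30, 90];
  stage/T/N/M drawn with category probabilities interpolating between a
  low-risk and a high-risk profile according to the linear-predictor
  quartile, scaled by `clinical_effect` (0 switches the association
  off).
* **Auxiliary tables.** Six abundance method labels × six cell types,
  and five drugs, each column a·z + N(0,1) with z the standardized
  linear predictor and signed coefficients in {±2, ±1, ±0.5}, so both
  positive and negative associations exist.

Default cohort sizes mirror a TCGA-scale colon cohort (373 tumor / 41
normal); tests run smaller for speed.  One integer seed drives three
spawned generator streams (expression, survival, auxiliary), and all
exports use a fixed float format, so identical configs reproduce
byte-identical files.  Run-log timestamps are therefore **off by
default** (`record_timestamps=True` restores them): wall-clock fields
would break the reproducibility contract that two identical runs yield
identical output directories.

What the generator does *not* emulate: read counts and library-size
artifacts, batch effects, zero-inflation/dropout, gene–gene correlation
beyond the single immune factor, non-proportional hazards, informative
censoring, and normal-sample survival.  Passing tests therefore show
that the implementation recovers the structures it models under clean
log-normal/PH conditions — not that the screening thresholds are
well-calibrated for any particular real cohort.

## 7. Numerical choices and degenerate inputs

* Strict inequalities at every published threshold (0.4, 0.001, 2,
  0.05, 0.2/0.8); boundary cases are excluded and tested as such.
* Cox: Newton with step halving; convergence |Δβ|∞ < 1e−8; |β| > 20
  treated as divergence; SEs from the inverse negative Hessian.
* Prior-df fitting: Newton inversion of the trigamma function from the
  starting point 0.5 + 1/target; a non-positive moment target yields
  d₀ = ∞ (pure pooling).
* Empty screens raise a clean typed halt (`EmptyResult`) that the
  pipeline converts into a `halted:<stage>` run-log status with an
  empty signature; invalid inputs raise `PipelineHalt`, which the CLI
  maps to a nonzero exit naming the stage.
* Cohort split: seeded permutation, train gets the extra sample on odd
  n; every data-dependent decision is made on the training half.
* Tie-breaks are total orders (AIC then drop-before-add then pair id;
  cutoff ties to the smaller threshold; candidate order by frequency,
  univariate p, pair id), so outputs are independent of dict/hash
  order.

## 8. Problem sizes used by the test suite

Unit and property tests run on cohorts of 20–1000 patients and 2–137
genes, chosen so each check exercises its statistical content in
seconds.  The heaviest experiments are the selection-recovery study (20
seeded runs, 50 pairs × 400 patients, 100 lasso cycles each) and the
null-calibration batteries (1000 seeded replicates per test, sized so
the Monte-Carlo error of a rejection-rate estimate is ≈0.7 percentage
points).  Where a recovery claim concerns an estimate rather than a
single draw (e.g. hazard-ratio recovery at n = 1000), the assertion is
on the across-seed Monte-Carlo average, whose error is an order of
magnitude smaller than per-seed sampling noise.

## 9. Known limitations

* The moderated-t implementation covers the two-group design only — no
  general design matrices, contrasts, or precision weights.
* The IPCW ROC has no confidence bands; the nearest-neighbor-smoothed
  ROC estimator some survival packages use is not implemented, so AUC
  values may differ in the second decimal from smoothed estimators on
  the same data.
* The lasso penalty grid is the coxnet default path (30 points here);
  extremely correlated pair sets can make the chosen penalty, and hence
  the frequency table, sensitive to the grid.
* `PipelineParams.cutoff_criterion` offers Youden and closest-to-corner;
  a cutpoint defined through AIC over dichotomized Cox fits is not
  implemented because no reproducible standard definition exists.
* Immune-cell abundances and drug IC50s are consumed as given tables;
  the deconvolution and sensitivity-prediction models that produce them
  are out of scope.
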
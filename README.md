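# irlncpair

Rank-based immune lncRNA **pair** prognostic signatures for tumor cohorts.

## The problem

Prognostic gene signatures built from expression *levels* are fragile:
they inherit every normalisation and batch artifact of the platform that
measured them.  An alternative is to model *within-sample orderings*: for
an ordered pair of immune-related lncRNAs (A, B) and a sample s, define

    C(A, B, s) = 0  if  expr(A, s) < expr(B, s),   else 1.

The indicator depends only on which gene is higher inside one sample, so
it is invariant to any strictly increasing per-sample transform of
expression — no fixed expression scale is needed.  A Cox model over such
pair indicators gives each patient the risk score

    risk(s) = Σᵢ Coefᵢ · xᵢ(s),      xᵢ ∈ {0, 1},

and a cutoff on that score splits the cohort into high- and low-risk
groups whose survival, staging, immune infiltration and chemosensitivity
can then be compared.

`irlncpair` implements the full chain for bulk tumor/normal FPKM cohorts:

1. **Screening** — biotype split (GTF or TSV annotation); immune
   coexpression (|Pearson r| > 0.4 at p < 0.001 on log2(FPKM+1));
   moderated-t differential expression (empirical-Bayes variance
   shrinkage) at |log2FC| > 2, FDR < 0.05.
2. **Pairing** — all m(m−1)/2 pair indicators over the tumor cohort;
   pairs kept when their one-fraction lies strictly in (0.2, 0.8).
3. **Selection** — univariate Cox screen (Breslow partial likelihood);
   R-cycle bootstrap lasso-Cox with 10-fold cross-validated penalty
   choice, recording each pair's selection frequency; bidirectional
   stepwise AIC Cox; and the *zenith* rule — over candidate models nested
   by lasso frequency, the smallest one attaining the maximal 3-year AUC.
4. **Risk model** — IPCW cumulative/dynamic time-dependent ROC at 1/2/3
   years; Youden (or closest-to-corner) cutoff on the 3-year curve;
   strict `score > threshold` high-risk assignment.
5. **Validation** — Kaplan–Meier/log-rank, chi-square against
   clinicopathological categories, rank-sum strip comparisons, Spearman
   correlation with immune-cell abundance panels, drug-IC50 group
   comparisons, and uni/multivariate Cox forest tables, each battery
   BH-corrected within itself.

A seeded synthetic-cohort generator (`irlncpair.simulate`) plants
recoverable signal at every stage — a latent immune factor for the
coexpression screen, a tumor log2 shift for the DE screen, and a
proportional-hazards model over planted pair indicators for the selection
chain — so the whole pipeline is testable without any download.

## Worked example

```python
from irlncpair import default_config, simulate_study
from irlncpair.pipeline import PipelineParams, StudyInputs, run_study

cfg = default_config(n_tumor=150, n_normal=40, n_lnc=40, n_mrna=120,
                     n_immune=60, n_coexpressed_lnc=15, n_de_lnc=12, seed=7)
study = simulate_study(cfg)
runlog = run_study(StudyInputs.from_study(study),
                   PipelineParams(lasso_cycles=100, seed=7), "out/")
```

prints (via `runlog.counts`) the screening funnel and model summary:

```
"n_lnc": 40, "n_irlnc": 15, "n_deirlnc": 12,
"n_candidate_pairs": 66, "n_valid_pairs": 25,
"n_screened_pairs": 4, "n_selected_pairs": 4,
"stepwise_size": 3, "signature_size": 4,
"auc_1y": 0.741529, "auc_2y": 0.775812, "auc_3y": 0.755923,
"cutoff_threshold": 0.3662462121, "n_high": 61, "n_low": 89
```

Of the 40 simulated lncRNAs, 15 pass the immune-coexpression screen and
12 the DE screen (exactly the planted ones); 66 candidate pairs reduce to
25 informative ones, 4 survive the univariate screen, and the zenith
model keeps 4 pairs — including all 3 planted pairs, with fitted
coefficients near their true log hazard ratios (e.g. +0.96 for a planted
+0.90).  The 3-year AUC of 0.756 and the log-rank comparison of the
resulting 61/89 high/low split (χ² = 34.96, p = 3.4e-09) quantify how
well the recovered score stratifies survival.  The `examples/` scripts
walk through each stage with the same numbers.

A thin CLI covers the shell workflow:

```sh
irlncpair simulate --outdir study/ --seed 7
irlncpair run --indir study/ --outdir out/ --seed 7
```

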
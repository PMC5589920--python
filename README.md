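# explobatch

Diagnose, quantify and correct batch effects in gene-expression matrices —
with a formal per-component statistical test instead of visual inspection.

When expression datasets profiled at different times, labs or platforms are
merged, systematic non-biological differences (batch effects) can dominate
the signal or, worse, masquerade as biology. The common diagnostics (PCA
plots, dendrograms) are visual and subjective, and the common PCA fix —
deleting whole principal components associated with batch — also deletes
any biology entangled with them.

`explobatch` is built on **probabilistic principal component and
covariates analysis (PPCCA)**, a latent Gaussian model in which the
covariates enter the prior mean of the scores:

```
y_i = W u_i + μ + ξ_i        ξ_i ~ MVN_p(0, σ²I)
u_i = β x_i + ε_i            ε_i ~ MVN_q(0, I)
```

Here `y_i` is a sample's p-gene expression vector, `u_i` its q-dimensional
probabilistic principal component (pPC) score, `x_i` its design vector
(intercept + batch dummies + optional biological covariates), and `β`
measures — in score units — how each covariate shifts each pPC. The model
is fitted by EM; q is chosen by maximising BIC = 2·loglik − k·log n.

* **find_batch** tests every pPC k and batch contrast b with the Wald
  statistic Δ_bk = β_bk / SE(β_bk) (leave-one-out jackknife SEs with
  analytic rotation/scale variance terms); a pPC is batch-affected when the
  95% CI excludes zero. Biological covariates are tested identically, so
  batch and biology can be told apart.
* **correct_batch** subtracts the estimated batch shift in score space,
  `u_ck = u_ak − x_b β_bk`, and reconstructs
  `y_corrected = y − W(u_a − u_c)`, preserving each sample's residual —
  biology sharing a component with batch survives.
* **gpca_test** (guided PCA, a global permutation test) and
  **pca_removal_correct** (whole-component deletion) are included as the
  standard comparators, plus **proportion_of_variation** for variance
  audits.
* A **synthetic** module generates data from the model with controllable
  batch/biology effects and runs the replicated calibration studies.

## Worked example

Simulate two batches of 50 samples × 30 genes with a 3-latent-unit batch
shift on component 1 and a biological (binary) effect of 2 units on
component 2, then detect and correct:

```python
import explobatch as eb

ds = eb.simulate(eb.SimulationConfig(
    n_per_batch=(50, 50), p=30, q_true=2,
    batch_beta=[[3.0], [0.0]], bio_beta=[0.0, 2.0],
    loading_scale=(1.2, 0.8), seed=42))

res = eb.correct_batch(ds.Y, ds.batch,
                       covariates={"bio": list(ds.bio)}, q=2)
print(res.assessment_before.table)
```

```
 component covariate  contrast  coefficient       se     delta    ci_low   ci_high  significant
         1     batch batch[B2]    -3.036564 0.379874 -7.993615 -3.781103 -2.292025         True
         2     batch batch[B2]     0.452027 0.624633  0.723668 -0.772231  1.676285        False
         1       bio   bio[c1]    -0.258912 0.327659 -0.790188 -0.901112  0.383288        False
         2       bio   bio[c1]     2.008493 0.288342  6.965651  1.443352  2.573634         True
```

The forest table reads: batch shifts pPC1 by −3.04 score units (CI
excludes 0 → significant; the sign is relative to the reference batch B1),
while the biological covariate sits on pPC2 (+2.01, significant) — batch
and biology are separated. After correction
(`res.assessment_after.table`):

```
 component covariate  contrast  coefficient       se     delta    ci_low  ci_high  significant
         1     batch batch[B2]     0.007447 0.207024  0.035972 -0.398313 0.413207        False
         2     batch batch[B2]    -0.000159 0.215121 -0.000738 -0.421788 0.421470        False
         1       bio   bio[c1]    -0.260399 0.324683 -0.802012 -0.896766 0.375967        False
         2       bio   bio[c1]     2.003873 0.285289  7.024004  1.444716 2.563030         True
```

The batch coefficients collapse to ~0 (no pPC significant) while the
biological effect is untouched (+2.00, still significant). The global
comparator agrees: `eb.gpca_test` gives statistic 0.999, p = 0.001 before
correction and 0.028, p = 1.0 after.

The same workflow is available from the shell on TSV/CSV files:

```
explobatch find    --expression expr.tsv --annotation ann.tsv
explobatch correct --expression expr.tsv --annotation ann.tsv --covariate bio
explobatch gpca    --expression expr.tsv --annotation ann.tsv --n-perm 999
explobatch simulate --batch-shift 3 --out-dir sim/
explobatch study   --scenario retention
```

`find` writes the forest table (`forest.tsv`), the BIC-vs-q table and a
one-line verdict; `correct` writes the corrected matrix, before/after
assessments and a JSON provenance sidecar recording q, the adjusted
components and the batch coefficients.

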
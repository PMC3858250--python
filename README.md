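# mrsig — molecular risk scores for survival after liver resection

Patients who undergo resection of colorectal-cancer liver metastases have
highly variable outcomes, and purely clinical staging (the five-factor
clinical risk score, CRS) separates them only modestly. `mrsig` implements
and stress-tests the alternative: a **molecular risk score (MRS)** built
from tumor gene-expression profiles by *supervised principal components* for
censored survival, validated train/test with the signature fully frozen
before it touches held-out data.

The pipeline, end to end:

1. **Preprocess** — log2 transform and quantile normalization; the
   reference distribution can be frozen on training samples and applied to
   test samples by rank.
2. **Screen** — for every gene *g*, a univariate Cox proportional-hazards
   fit of the standardized expression *z<sub>g</sub>* against the endpoint
   (disease-specific survival, DSS, or liver-recurrence-free survival,
   LRFS), Efron tie correction, Wald test. Genes with *p* < 0.001 survive.
   For LRFS the screen can instead use the Fine–Gray subdistribution model,
   treating cancer death without liver recurrence as a competing risk, and
   the two screens' p-values are compared per gene.
3. **Construct the MRS** — genes are ranked by |z| = |β̂/se|; the |z|
   cutpoint is tuned by K-fold cross-validation (pre-validated Cox score
   statistic); the signature is the first principal component of the
   selected-gene training submatrix:

   MRS(s) = Σ<sub>g∈S</sub> w<sub>g</sub> · (x<sub>gs</sub> − μ<sub>g</sub>)/σ<sub>g</sub>,

   with w the PC1 loadings (or, optionally, the standardized Cox
   coefficients), oriented so higher MRS ⇒ higher hazard, and dichotomized
   at the **training median**.
4. **Validate frozen** — Kaplan–Meier curves and log-rank tests by MRS
   group, Harrell's concordance index for MRS and CRS, multivariate Cox
   hazard ratios for both scores, and the combined three-group
   stratification (CRS and MRS both low / discordant / both high).

Because the method's value is statistical, the package ships a first-class
**synthetic cohort generator** with known ground truth: planted prognostic
genes reading a shared latent hazard axis, clinical factors with real
effect, tunable censoring, and a controllable competing-event fraction.
Every claim the pipeline makes is tested against that truth or against
independent oracles (brute-force partial-likelihood maximization,
exhaustive concordance enumeration, `lifelines`, R's `cmprsk` and `limma`).

## Worked example

```bash
python analysis/01_simulate.py        # synthetic cohort with known truth
python analysis/02_train_validate.py  # train MRS, validate frozen on test set
python analysis/03_competing_risks.py # Cox vs Fine-Gray screening agreement
python analysis/04_stratification.py  # combined CRS+MRS three-group ladder
```

Output of the run at seed 1 (the default):

```
[dss] signature: 13 genes (13 of 20 planted), cutpoint p=3.16e-04
  test c-index  MRS 0.66 | CRS 0.57
  test log-rank p (MRS high vs low) = 0.001334
  test 3-year survival: high 21% vs low 55%
  multivariate HR: MRS 2.86 (1.50-5.44, p=0.00142); CRS 1.75 (0.83-3.71, p=0.142)
[lrfs] signature: 26 genes (18 of 20 planted), cutpoint p=1.00e-02
  test c-index  MRS 0.75 | CRS 0.59
  test log-rank p (MRS high vs low) = 2.21e-06
  test 3-year survival: high 13% vs low 68%
...
[dss] entire-cohort 3-year survival by combined risk: low 53% >= intermediate 27% >= high 0% (log-rank p = 9.2e-10)
```

Reading it: the screen found 13 of the 20 genes truly linked to cancer
death; the frozen molecular score separates held-out patients (test
concordance 0.66 for DSS, 0.75 for LRFS, versus 0.57/0.59 for the clinical
score), remains an independent predictor when the clinical score is in the
model (multivariate hazard ratio 2.9 for DSS), and combining both scores
produces a cleanly ordered three-group survival ladder.

The same stages are scriptable via the `mrsig` CLI
(`simulate`, `normalize`, `screen`, `train`, `score`, `validate`,
`run-all`) for use on real expression matrices in the documented TSV/CSV
formats.

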
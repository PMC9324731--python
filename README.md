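# cse-recall

Entropy-based metrology for word-list memory tests: Rasch restitution of
person ability and item difficulty from binary recall responses, Brillouin
(combinatorial) entropy explanatory variables for serial-position effects,
construct specification equations (CSE) fitted by principal component
regression, residual-PCA multidimensionality diagnostics, and a theoretical
prediction of residual-contrast loadings under serial-position scale
distortion.

## What's inside

| Module | Purpose |
| --- | --- |
| `cse_recall.entropy_constructs` | Scale constant `M = 1/ln(L)`, primacy / mid-range / recency / frequency difficulty terms, per-item explanatory matrix |
| `cse_recall.rasch_core` | Dichotomous Rasch model: JMLE estimation with uncertainties, standardized residuals, sensitivity, back-conversion to the success-probability scale |
| `cse_recall.spe_ctt` | Classic-test-theory proportions and serial-position curves per clinical group and region |
| `cse_recall.cse_pcr` | Explanatory-variable PCA (PCA1), correlations, CSE fitting by PCR with k=2 uncertainty propagation, per-item term decomposition, subgroup CSEs |
| `cse_recall.residual_pca` | Residual contrasts (PCA2), variance decomposition, disattenuated correlation, per-cluster refits, multidimensionality checklist |
| `cse_recall.loading_theory` | Cohort-integrated sensitivity and theoretical contrast-loading predictions under a difficulty shift |
| `cse_recall.synthetic_cohort` | Rasch-generative cohort simulator with group-wise ability distributions and region-wise difficulty shifts; 225-person four-group preset |
| `cse_recall.io_cli` | CSV I/O, bundled 15-item reference table, run configuration, `cse-recall` CLI |

The bundled reference table (`cse_recall/data/table1_ravlt_ir.csv`) carries
the published 15-item explanatory variables, empirical difficulties and
fitted values used as desk-scale inputs throughout.

## CLI

```sh
cse-recall simulate --seed 7 --out responses.csv
cse-recall rasch-fit --responses responses.csv --out-items items.csv --out-persons persons.csv
cse-recall ctt --responses responses.csv --out ctt.csv
cse-recall entropy-vars --length 15 --out vars.csv
cse-recall cse-fit --out cse.csv                 # bundled reference table
cse-recall pca-residuals --responses responses.csv --out contrasts.csv
cse-recall predict-loadings --ddelta 2 --out predictions.csv
cse-recall spe-curves --responses responses.csv --out spe.csv
cse-recall reproduce-table1                      # pass/fail reproduction report
```

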
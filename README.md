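# piicm

Probabilistic dose–response prediction for in-vitro drug-combination
screens, built on a permutation-invariant multi-output Gaussian process.

Each two-drug experiment is first fit independently with a Bayesian
dose–response model: log-logistic monotherapy curves, a Bliss-product
non-interaction surface, and a latent GP interaction field pushed through a
bounding transform so the surface stays in (0, 1), under heteroskedastic
measurement noise. The per-experiment latent posteriors (mean and variance
on a common unit-box concentration grid) then become noisy observations of a
joint multi-output GP over all (cell line, drug pair) experiments, whose
kernel factorizes into low-rank free-form cell-line and drug-pair
covariances times a squared-exponential input kernel — symmetrized so that
predictions are exactly invariant to jointly swapping a drug pair and its
concentrations. Held-out experiments are predicted in latent space and
reconstructed into dose–response surfaces.

Inference never materializes the full covariance: missing experiments (and
all reversed-order duplicates) are dummy observations with huge noise, the
linear solves run through preconditioned conjugate gradients on structured
Kronecker matvecs, and the log-determinant uses the exact eigenvalue
multiset of the structured prior (obtained from its Kronecker factors)
combined with the observed noise entries through a Weyl-type pairing.
Gradients of the marginal likelihood are computed analytically, including
through the factor eigendecompositions.

## Layout

| module | contents |
| --- | --- |
| `piicm.screen_data` | screen CSV I/O, canonical experiment keys, unit-box scaling, common grid, stage-2 `Z`/`S` matrix assembly with masking |
| `piicm.stage1` | per-experiment Bayesian fit (elliptical-slice + slice sampling), grid summaries, monotherapy-only Bliss surfaces |
| `piicm.kernels` | squared-exponential / low-rank / permutation-invariant covariance operator, structured matvecs, exact eigenvalue routine |
| `piicm.inference` | masked preconditioned CG, approximate log-determinant with analytic gradients, Adam training, predictive posterior |
| `piicm.prediction` | surface reconstruction, weighted RMSE / Pearson metrics, train/test split, rank cross-validation, Bliss baseline |
| `piicm.simulate` | synthetic viability screens and direct latent-matrix simulation, with ground truth |
| `piicm.workflows` | end-to-end pipelines used by the CLI and the simulation studies |

## CLI

```sh
piicm simulate --preset small --seed 1 --out sim/        # screen + ground truth
piicm screen validate sim/screen.csv
piicm stage1 fit --screen sim/screen.csv --k 4 --fast --out summaries.csv
piicm train --summaries summaries.csv --rc 2 --rd 2 --variant invariant \
    --seed 1 --out model.json
piicm predict --model model.json --summaries summaries.csv \
    --targets targets.csv --out predictions.csv
piicm evaluate --model model.json --summaries summaries.csv \
    --test targets.csv --out report.json
piicm cv --summaries summaries.csv --rc 1,2 --rd 1,2 --folds 5 --out cv.json
```

`targets.csv` / `test.csv` need columns `cell_line,drug_a,drug_b`. Screen
tables are long-format CSV with columns
`cell_line,drug_a,drug_b,conc_a,conc_b,replicate,viability` (blank `drug_b`
for monotherapy rows; concentrations on the log10 scale).

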
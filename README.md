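# sorptionlab

Water sorption isotherm modeling and model selection for dried food
products: twelve conventional isotherm equations (GAB plus eleven empirical
forms) with temperature and categorical-covariate parameterizations, four
machine-learning regressors, nonlinear least-squares fitting with
genetic-algorithm or closed-form initialization, a repeated train/validation
evaluation protocol, residual-validity screening (Ljung-Box, Levene) and
ANOVA + Fisher-LSD model ranking. A synthetic dynamic-dewpoint-style data
generator provides datasets with known ground truth so the whole pipeline is
testable offline.

## Layout

| module | contents |
| --- | --- |
| `sorptionlab.models` | the 12 closed-form isotherm equations, Arrhenius/linear temperature laws, dummy covariates |
| `sorptionlab.synthetic` | DDI-style grid and dataset generation, noise models, crossing/hysteresis scenarios |
| `sorptionlab.fitting` | quadratic GAB initialization, genetic algorithm, nonlinear OLS (RMS), Arrhenius linearization, confidence intervals, global fits |
| `sorptionlab.ml` | regression tree (SE-rule pruning), random forest, kNN, Laplacian-kernel nu-SVR |
| `sorptionlab.evaluation` | MRE / adjusted-R2 metrics, repeated 75/25 splits, diagnostics, two-factor ANOVA + LSD compact letters, `run_pipeline` |
| `sorptionlab.io` / `sorptionlab.cli` | CSV/JSON artifacts, truth sidecars, the `sorptionlab` command |

Moisture is decimal dry basis internally (kg water / kg dry solid); a
`percent` flag converts `% d.b.` files at the I/O boundary. Temperature
enters all temperature laws in Kelvin.

## CLI

```sh
sorptionlab simulate --scenario crossing --seed 7 --out ds.csv --noise-sd 0.002
sorptionlab fit      --data ds.csv --model GAB,Oswin --out fits.json
sorptionlab evaluate --data ds.csv --models GAB,Oswin,SVM \
                     --iterations 100 --seed 3 --out metrics.csv \
                     --ranking-out ranking.json
sorptionlab rank     --metrics metrics.csv --out ranking.json
sorptionlab report   --data ds.csv --model GAB --out report/
```

`simulate` writes the dataset CSV plus a `*.truth.json` sidecar holding the
generating model, parameters, noise and seed; reruns with the same seed are
byte-identical. `evaluate` emits the long-format metric table
(`model,iteration,subset,mre_pct,r2_pct,r2adj_pct,n,m`) and a resolved
config JSON next to it. A YAML file of per-command defaults can be passed as
`sorptionlab --config run.yaml <command>`; explicit flags win.

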
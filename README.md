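# mokkensep

Nonparametric item response theory (Mokken) scaling for measuring
household **socioeconomic position (SEP)** from dichotomous asset
ownership data, with the standard polychoric-PCA wealth index and an
expenditure comparison built in.

Asset-based wealth indices are a staple of health research in
settings where expenditure data are hard to collect: households
answer yes/no questions about assets, utilities and infrastructure
(a bucket, electricity, a television, a car, …) and the answers are
combined into a wealth score, usually split into quintiles. The
dominant construction is a principal component analysis of the asset
correlations. Mokken scale analysis is a nonparametric alternative
that makes no distributional assumptions: it selects the subset of
items that form a probabilistic Guttman scale — so that the plain
**sum of owned items** validly orders households on the latent wealth
trait — and simultaneously orders the items themselves from "easy"
to "hard".

## What it computes

For a complete-case households × items binary matrix:

- **Loevinger scalability coefficients.** For a pair with the harder
  (less popular) item h and easier item e, `H_ij = 1 − F_ij/E_ij`,
  where `F_ij` counts Guttman errors (harder owned, easier not) and
  `E_ij = n·p_h(1−p_e)` is the count expected under independence;
  item (`H_i`) and scale (`H`) coefficients aggregate the summed
  errors, with bootstrap standard errors, and `H^T` (the same
  coefficient on the transposed matrix) summarises item-ordering
  accuracy across households. Scales with H > .5 are conventionally
  "strong", .4–.5 "medium", .3–.4 "weak".
- **Automated item selection (AISP).** Greedy bottom-up partitioning
  of the pool into Mokken scales: grow each scale by the item that
  maximises scale H subject to significantly positive `H_ij` with all
  members and within-scale `H_i ≥ c` (default c = .3); leftovers are
  unscalable.
- **Model checks.** Restscore tests of monotonicity and of
  non-intersection / invariant item ordering (IIO), with iterative
  removal of the worst IIO offender.
- **Wealth indices.** The Mokken sum score, and the first principal
  component of the tetrachoric correlation matrix scored with
  Filmer–Pritchett standardisation; both with tie-respecting
  quintiles.
- **Evaluation.** Weighted Cronbach's alpha with a Feldt 95% CI, and
  Pearson/Spearman comparisons of all indices with log household
  expenditure, including per-quintile expenditure summaries.

A seeded synthetic-survey generator (2PL response model, log-normal
expenditure with a latent trait loading) provides ground-truth data
for all of it; see `docs/methods.md` for the model and every tuning
constant.

## Worked example

Run the full pipeline on the default 17-item synthetic survey (3,810
households):

```python
from mokkensep import PipelineConfig, run_full_pipeline

report = run_full_pipeline(PipelineConfig(synthetic={"n": 3810, "seed": 1}, seed=1))
print(report.partition.item_table(report.scalability.popularity,
                                  report.scalability.item_H_se).to_string(index=False))
```

```
                 item  proportion scale   H_i  H_i_se
                clock       0.903     1 0.604   0.013
          electricity       0.900     1 0.604   0.013
           television       0.781     1 0.662   0.014
            motorbike       0.499     1 0.672   0.013
         video_player       0.297     1 0.628   0.013
       landline_phone       0.173     1 0.545   0.014
         refrigerator       0.151     1 0.509   0.015
magazine_subscription       0.070     1 0.463   0.017
      washing_machine       0.050     1 0.445   0.018
             computer       0.054     1 0.479   0.018
         mobile_phone       0.046     1 0.457   0.019
           dishwasher       0.003     1 0.548   0.082
               bucket       0.854     2 0.890   0.018
 agricultural_machine       0.081     2 0.890   0.019
              bicycle       0.831     -   NaN   0.020
         second_house       0.040     -   NaN   0.020
                  car       0.039     -   NaN   0.020
```

The AISP has recovered the generator's structure: the 12 items driven
by the dominant wealth trait form scale 1 (each with within-scale
`H_i` ≥ .3; `H_i_se` are full-pool bootstrap SEs — note how the SE
balloons for the 0.3%-popularity dishwasher item), the two
agrarian-cluster items form scale 2, and the three items nearly
unrelated to wealth are unscalable (`-`). Continuing:

```python
print(round(report.partition.reports[0].scale_H, 3))          # 0.565
print(len(report.mokken_items))                               # 12
print(round(report.reliability["unit_mokken_scale"].alpha, 3))  # 0.738
print(round(report.comparison.pearson["mokken_vs_pca_full"], 3))        # 0.978
print(round(report.comparison.pearson["mokken_vs_log_expenditure"], 3)) # 0.515
```

Scale 1 is a strong scale (H = .565 > .5). The IIO check finds no
critical violations on this realisation, so all 12 items are kept and
the Mokken SEP score is their unweighted sum. The unit-weighted alpha
of .738 is the scale's internal consistency; the sum score correlates
r = .98 with the 17-item polychoric PCA index and r = .52 with log
expenditure — the PCA and Mokken measures are near-interchangeable as
orderings, and both track expenditure as well as the generating
model's trait-expenditure coupling allows.

The same analysis runs from the shell (`mokkensep run --seed 1 --out
runs/demo`), and `mokkensep simulate`, `msa`, `pca` and `compare`
expose the individual stages; `--config pipeline.yaml` supplies real
data (`input_path`, item columns, dichotomisation thresholds such as
car counts → ownership) and all tuning constants.

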
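# icpg — positional imputation of CpG methylation states in single cells

Single-cell bisulphite sequencing (scRRBS/scBS-seq) reads out DNA
methylation one cell at a time, but each cell covers only a small fraction
of its CpG sites (roughly 1–10% for scRRBS). `icpg` predicts the missing
binary methylation states from **positional features alone** — no genome
sequence required — exploiting two strong regularities of methylomes:
neighboring CpG sites within a cell tend to share a state, and homologous
positions across cells of a population tend to agree.

It is aimed at anyone working with sparse multi-cell CpG coverage tables
(Bismark-style `.cov` files or simple TSVs) who needs per-site, per-cell
state calls with probabilities.

## Model

For a target site at position $p$ in cell $t$ of a $w$-cell dataset, the
feature vector concatenates:

* **intra-cell skip-K block** (4J values, default J=2): for neighbor ranks
  $j = 1..J$ on each side, the signed distance $p_j - p$ to the $j$-th
  nearest CpG site in the same cell and that site's state $s_j$;
* **cross-cell block** (14 values per donor cell $r \ne t$):
  a match flag and the donor state $s_r^l$ when the donor has an
  observation at exactly $p$ ($p_t^c = p_r^l$); the **F4** features
  $(p_r^{l-1}-p,\; s_r^{l-1},\; p_r^{l+1}-p,\; s_r^{l+1})$ — flanking
  distances and states around the match, or around the bracketing interval
  when there is no match; and the **D8** features — the four inter-site
  gaps and outer states over the donor window $l-2..l+2$, defined only
  around an exact match.

Missing neighbors are sentinel-encoded (distance $10^6$ bp, state −1) so
tree ensembles can split on them directly. One classifier is trained per
target cell. Four base learners (random forest, AdaBoost, XGBoost,
LightGBM) are tuned by random search maximizing the cross-validated
fitness

$$\mathrm{Fit} = \frac{1}{N_{FCV}} \sum_{j=1}^{N_{FCV}} \mathrm{MCC}_j,$$

the mean Matthews correlation coefficient over $N_{FCV}=5$ stratified
folds, and can be combined by **stacking** (extra-trees meta-predictor on
strictly out-of-fold base probabilities) or **soft voting**. Evaluation
uses chromosome holdout (train 1,3,5,7,9,11 / test 2,4,6,8,10,12 /
validation 13–19) so no genomic position leaks between sets, and reports
Sen, Spe, ACC, F1 and MCC per cell.

A synthetic-methylome generator (`icpg.synthetic_data`) emulates the
scRRBS regime — CpG islands, regional state coherence, cross-cell
concordance ρ, coverage dropout q — so the whole pipeline is testable
without any download. Sequence-window encoders (one-hot; 84-dimensional
1/2/3-gram frequencies) are included as comparison baselines.

## Worked example

```python
from icpg import CpGImputer, SimulationParams, simulate_dataset
from icpg.methdata import ChromosomeSplit

ds, truth = simulate_dataset(SimulationParams(seed=1))   # 6 cells, 3 chromosomes
split = ChromosomeSplit(train=frozenset({"chr1", "chr3"}),
                        test=frozenset({"chr2"}), validation=frozenset())
res = CpGImputer(ds, target_cells=["cell00"], algo="lgbm", split=split) \
    .fit(n_trials=8, seed=1, fast=True)
print(res.summary())
```

prints

```
CpG methylation imputation results
==================================
cells: 6 (targets: 1)  features: positional  algo: lgbm
trials: 8  folds: 5  seed: 1
train chroms: chr1,chr3
test chroms:  chr2

Cross-validated fitness (mean fold MCC):
cell_id algo  fit_score
 cell00 lgbm     0.7855

Held-out test-chromosome metrics:
  cell_id  n_sites    sen    spe    acc     f1    mcc
   cell00      587 0.8661 0.9195 0.8978 0.8734 0.7878
macro_avg      587 0.8661 0.9195 0.8978 0.8734 0.7878
```

Fitness 0.7855 is the tuned model's mean fold MCC on the training
chromosomes; the table shows its performance on the 587 covered sites of
the never-seen chromosome 2 — e.g. 92% of unmethylated sites correctly
recovered (Spe) with MCC 0.79. `res.predict(...)` returns per-site
probabilities for imputation; `icpg.write_predictions` exports them as a
BED-like TSV.

The same pipeline runs from a shell:

```sh
icpg simulate --out sim --seed 1
icpg train --manifest sim/manifest.tsv --algo lgbm --fast --out bundle
icpg predict --bundle bundle --out calls.bed
icpg benchmark --trials 2 --out bench.tsv     # classifiers x feature schemes
```

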
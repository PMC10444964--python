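# Methods

## Problem setting

Single-cell reduced-representation bisulphite sequencing yields, per cell,
a sparse table of CpG sites with methylated/total read counts. After a
depth filter and binarization, each covered site carries a binary state
(1 methylated, 0 unmethylated); the task is to predict states at sites
the assay missed, and to validate the predictor on covered sites held out
by chromosome. Two empirical regularities carry the signal: methylation
is spatially coherent along the genome (CpG islands are predominantly
unmethylated, inter-island "open sea" predominantly methylated, with
state runs spanning many consecutive sites), and cells of one population
agree at homologous positions far above chance.

## Data model and preprocessing

Coordinates are 1-based positions of the CpG cytosine on the forward
strand; CpG-dyad strand merging is assumed done upstream. Sites with
fewer than `min_depth = 4` total reads are discarded — below four reads a
binary call is unreliable — and remaining sites are called methylated
when the methylated-read fraction is ≥ `meth_threshold = 0.5`. The 0.5
threshold is this package's choice: it is the symmetric rule, and both
parameters are exposed (`binarize_and_filter`, CLI `--min-depth`).
Within a cell and chromosome, duplicate positions are rejected rather
than merged; merging policy belongs to the upstream caller.

Evaluation uses chromosome holdout: train on chromosomes 1,3,5,7,9,11,
test on 2,4,6,8,10,12, validation 13–19. Chromosomes outside these sets
(20–22, X, Y, M) are excluded by default (overridable), keeping the three
views genuinely disjoint in genomic position.

## Positional features

For target site `(chrom, pos)` in cell `t`:

* **Intra-cell skip-K block.** For each side and neighbor rank
  `j = 1..J`, the signed distance to the `j`-th nearest same-cell CpG and
  its state. Rank 1 is the immediate neighbor, rank 2 skips one site.
  `J = 2` (8 values) is the default: informativeness decays quickly with
  rank because spatial correlation decays with distance. The target's own
  state is never included.
* **Cross-cell block (14 values per donor).** `match_flag` and
  `match_state` report whether the donor observes exactly `pos` and with
  what state. `F4` holds the signed distances and states of the two donor
  sites flanking `pos` (around the match when matched, around the
  bracketing interval otherwise). `D8` holds the four consecutive
  inter-site gaps over the donor window `l−2..l+2` around an exact match,
  each paired with its outer site's state (`s_{l−2}, s_{l−1}, s_{l+1},
  s_{l+2}`); it is defined only around a match and is all-sentinel
  otherwise. The gap/state pairing is this package's standardization of
  the D-feature layout: the matched site's own state is already carried
  by `match_state`, so the window states enter once each and the layout
  stays non-redundant.

Unknown states are encoded −1 and missing distances as a sentinel of
10⁶ bp (configurable). Tree ensembles split on such sentinel values
directly, which avoids imputation entirely; a sentinel larger than any
real chromosomal distance in the data is the only requirement. Upstream
distances are negative, downstream positive, D gaps positive — the signs
fall directly out of the `p_neighbor − p_target` differences. All
features are invariant under translating every position by a constant.

Feature vectors have fixed length `4J + 14(w−1)` for a `w`-cell dataset;
donor blocks follow the manifest's cell order with the target cell
skipped, so a fitted model is tied to the dataset's cell count and
ordering, and `predict` rejects a dataset with a different `w`.

## Sequence-encoder baselines

Two encoders over a window of `2·flank+1` bases centered on the CpG
(default flank 50 bp, a compact context window; configurable):

* one-hot, row order A, T, G, C (the encoder's documented convention;
  rows for N are all-zero);
* n-gram frequencies `t_i = N(o_i)/(M−(n−1))` for n = 1, 2, 3, fixed
  lexicographic vocabulary over A<C<G<T, total length 84. Grams
  containing N are dropped from the numerator with the denominator
  unchanged, preserving the 84-length contract and keeping entries in
  [0, 1].

These exist to quantify what positional features add; on the synthetic
data, whose reference is uniform random, they bound the no-sequence-signal
baseline.

## Classifiers, tuning, ensembles

One model per target cell (coverage and class balance differ per cell;
donor features always come from the other cells). Base learners: random
forest, AdaBoost, XGBoost, LightGBM — four tree ensembles of different
bias/variance character, all pinned to one thread for bit-for-bit
reproducibility. Hyperparameters are tuned by seeded random search over
standard gradient-boosting ranges (trees 100–1000, depth 3–10, learning
rate 10⁻³–0.3 log-uniform, L2 leaf regularization 1–10; a reduced `fast`
space with 50–300 trees serves small runs), maximizing

    Fit = mean over 5 stratified CV folds of the held-out-fold MCC.

MCC is the tuning criterion because the class balance is skewed
(unmethylated majority) and both classes matter equally. All trials of
one search share one fold split, so trials differ only in parameters;
ties go to the earliest trial. A fold whose test half degenerates to one
class contributes MCC 0 with a warning, keeping the fitness finite.
Random search rather than an adaptive sampler is a deliberate choice: the
spaces are low-dimensional, the budget small, and seeded random search is
exactly reproducible and embarrassingly simple to audit.

**Stacking** builds the meta design matrix from out-of-fold base
probabilities — the same stratified folds for every base, so no base ever
predicts a row it trained on — fits an extra-trees meta-predictor on it,
then refits the bases on the full training set for deployment.
**Voting** is soft: the arithmetic mean of base probabilities (hard vs
soft is unspecified in common practice; soft preserves calibration
information). Labels are `probability ≥ 0.5`; the threshold, including
the boundary convention, is explicit and configurable.

## Evaluation

Five metrics from the confusion counts with methylated as positive:
Sen = TP/(TP+FN), Spe = TN/(TN+FP), ACC = (TP+TN)/n,
F1 = TP/(TP+½(FP+FN)), and MCC as
(TP·TN − FP·FN)/√((TP+FN)(TN+FN)(TP+FP)(TN+FP)) — algebraically the
standard covariance form, asserted equal to it in the tests. Zero
denominators yield a flagged 0.0 instead of NaN so per-cell tables over
sparse cells stay rectangular. Cell-level reports carry an unweighted
(macro) average row: every cell counts equally regardless of its
coverage.

## Synthetic data generator

The generator is the package's study-condition definition, not a test
convenience dial. Per chromosome it alternates dense island runs (mean
`island_size = 15` CpGs at mean spacing `gap_within = 80` bp) with sparse
open-sea runs whose site count is set so the mean island rate is
`island_rate = 60` per Mb (sea spacing `gap_between = 3000` bp). Each run
draws a regional latent state — methylated with probability
`p_meth_island = 0.25` for islands and `p_meth_sea = 0.75` for sea,
giving the unmethylated-majority imbalance characteristic of real
CpG-site tables — and each site deviates from its regional state with
probability `flip_with_distance = 0.02` per kb of distance from the run
start (capped at 0.49), so spatial correlation decays with distance.
Cells then agree with the per-site consensus with probability
`concordance ρ = 0.95`, observe each site with probability
`coverage q = 0.30`, and draw `4 + Poisson(depth_mean − 4)` reads
(`depth_mean = 10`), with a minority-read rate of 0.05 clamped so the
read majority always matches the state — the depth floor keeps every
simulated site above the 4-read filter, so small simulations are not
silently emptied. Defaults use `w = 6` cells and three 1.6-Mb
chromosomes (~2000 CpGs each), desk-scale sizes chosen so the full
tune-fit-evaluate cycle runs in seconds while leaving ~600 held-out
evaluation sites per cell. The implied cross-cell agreement at shared
sites is ρ² + (1−ρ)² ≈ 0.905, verified empirically in the tests.

`simulate_null` reuses the identical positional scaffold but draws every
cell/site state as an independent fair coin: any classifier scoring
meaningfully above MCC 0 on its output is leaking information.

What the generator does **not** model: bisulphite conversion error as a
separate process (only a symbolic minority-read rate), realistic genome
sequence (the reference used for sequence encoders is uniform random),
copy-number or allele-specific methylation, batch effects, or
non-stationary island density. Passing tests therefore demonstrate that
the machinery recovers positional/cross-cell signal when present and
invents none when absent — not that any particular accuracy will be
attained on real tissue data.

## Numerical and design choices

* Determinism: a single integer seed fixes simulation, fold splits,
  search sampling and every estimator; all estimators run single-threaded;
  reruns are byte-identical.
* The spec-level slot for a CatBoost-style ordered-boosting base is
  filled by LightGBM, the gradient-boosting implementation this package
  builds against; the algo id is `lgbm`.
* Per-cell seeds are derived arithmetically from the run seed and the
  cell index, so adding a target cell never perturbs another cell's fit.
* Output files are written temp-then-rename; a failed command leaves no
  partial output.
* The model surface is a Model/Results pair (`CpGImputer` /
  `CpGImputerResults`): construction binds data and configuration,
  `fit()` returns an immutable results object carrying tuned parameters,
  cross-validated fitness, held-out metrics and `summary()`.

## Known limitations

* A fitted model transfers only to datasets with the same cell count and
  manifest order; cross-dataset transfer would need donor-block
  re-anchoring.
* Intermediate (allelic) methylation is collapsed to a binary state by
  the 0.5 rule; sites near 50% methylated reads are genuinely ambiguous.
* With a single cell (`w = 1`) only the 8 intra-cell features remain;
  accuracy degrades accordingly.
* The held-out evaluation covers sites the assay observed; accuracy on
  truly unobserved sites inherits any covered/uncovered site bias of the
  assay, which the simulation's uniform dropout does not model.
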
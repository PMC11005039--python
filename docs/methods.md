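# Methods

## The screening problem and the surrogate loop

A structure-based screening campaign ranks a library of N ligands by a
docking score and carries the best β fraction (the virtual screening
hits, k_hits = round(βN)) forward. `aldock` treats docking as an
expensive oracle revealed batch by batch: a campaign docks a random batch
of n ligands, fits a regressor from binary Morgan fingerprints to the
revealed scores, and greedily docks the n undocked ligands the surrogate
scores best, repeating until the budget is spent. All campaigns in this
package are retrospective — the full score vector exists up front (a
stored score table or the synthetic oracle) and the loop merely controls
the order in which it is revealed. That is why `run_active_learning`
takes a score *vector* rather than an arbitrary callback: every in-scope
use case materializes the scores, and retrospective evaluation needs the
full vector anyway to label hits.

Scores follow the lower-is-better convention internally; tables declaring
the opposite are negated on load and the transform recorded.

## Ensembling and train regimes

Models from successive iterations see different slices of chemical space.
Three combination rules are implemented, all operating on each model's
cached predictions over the full library (computed once at model
creation, never recomputed):

* **LastModel** — newest model only.
* **MeanRank** — each model ranks the undocked pool (midranks on ties);
  ligands are acquired by mean rank. Ranking is over the *pool* by
  default; `rank_over="library"` switches to whole-library ranks (the
  two differ only by a monotone shift when the pool shrinks; the pool
  convention is used because acquisition only ever compares undocked
  ligands).
* **TopFromEveryModel** — each of the k windowed models contributes its
  best ⌈n/k⌉ pool ligands; contributions concatenate oldest→newest,
  duplicates keep the first occurrence, shortfalls are refilled from the
  most recent model (freshest information), and the result is truncated
  to n.

Train regimes: *add* fits on all docked ligands (|X_j| = nj), *noadd* on
the latest batch only (|X_j| = n). The model window W (default unbounded;
20 in ultra-large mode) bounds both memory and MeanRank cost.

Every tie anywhere — hit labeling, batch acquisition, per-model ranking —
breaks by ascending ligand id, so runs are bit-reproducible from the
config seed alone. The seed batch is uniform without replacement.

## Base models

Model families map to scikit-learn estimators at their documented
defaults (LinearRegression, Ridge/RidgeCV, Lasso/LassoCV, LinearSVR,
KNeighborsRegressor, DecisionTreeRegressor, RandomForestRegressor);
features are raw binary fingerprints for every family, with no centering
or scaling. Because "defaults" drift across library versions, the exact
resolved hyperparameters and the scikit-learn version are serialized into
every fitted model and run manifest. The active loop defaults to plain
linear regression: its train+predict cost is seconds per iteration at
desk scale, and the soft performance test pins this at fit 20,000×512 /
predict 200,000×512 under a generous bound on one CPU — the package's
desk-scale working sizes.

## Synthetic docking oracle

The generator emulates the statistical skeleton of a docking campaign,
not its physics:

* fingerprint bits i.i.d. Bernoulli(`bit_density`, default 0.05 — sparse,
  like folded Morgan fingerprints of drug-like molecules);
* true score −w·x with non-negative weights on a random
  `weight_sparsity` = 0.25 fraction of `n_bits` = 256 bits
  (half-normal scale 1.0), so a minority of substructures carries signal
  and bit-rich ligands tend to score better;
* two independent Gaussian noise draws per ligand (`noise_sd`, or
  `noise_to_signal` as a variance ratio) standing in for two docking runs
  with different sampling seeds. Gaussian noise is the simplest
  exchangeable choice that reproduces the second-docking ceiling:
  corr(run1, run2) = 1/(1+noise_to_signal), e.g. 0.5 at equal noise and
  signal variance.

What it does **not** emulate: correlated substructures, activity cliffs,
heavy-tailed score distributions, nonlinear epistasis between bits
(a pairwise-interaction stress option exists but is off by default), or
library redundancy. Passing tests therefore demonstrate the machinery and
its statistical calibration, not performance on any real receptor. The
linear ground truth also means the default surrogate is well-specified;
noiseless runs retrieve ≥99% of hits within 10% docked, which is a
correctness check, not a realistic recall claim.

## Evaluation protocol

* **Hit labeling**: k_hits = round(βN) lowest scores, id tie-break.
* **Single-iteration benchmark**: for train size m, a seeded uniform pool
  of 1.25m ligands is drawn, its top-1% labeled hits, and a stratified
  5-fold split yields m-train / m/4-test partitions with the 1:99
  imbalance on both sides. Fold plans depend only on (scores, m, seed)
  and are reused across model families. Recall selects as many
  top-predicted test ligands as the partition holds hits; with integral
  β·|test| this is exactly the predicted top-β, and when rounding makes
  the counts differ by one it keeps a perfect predictor at recall 1.0
  instead of capping it below 1 by bookkeeping.
* **Cumulative recall**: hits among all docked ligands (acquisition =
  docking), reported against the fraction of the library docked.
* **Constant-recall extrapolation**: h₀ = nβr, h_j = (Nβ − H_{j−1})·r,
  implemented as the recurrence and cross-checked against the closed form
  H_j = Nβ − (Nβ − nβr)(1−r)ʲ to 1e-9. Note the model charges the random
  seed batch the modeled yield nβr, although a random batch's literal
  expectation is nβ; the formula is implemented as published and the
  comparison utility plots the analytic random line H = docked·β
  alongside. Empirically the extrapolation overestimates small-batch
  campaigns late in a run; `compare_trace_to_extrapolation` reports the
  deviation rather than asserting it.
* **Stopping diagnostic**: per-iteration hit yield over the hypergeometric
  random expectation n·(remaining hits)/(remaining pool); advisory only.

## Acceptance problem sizes

The acceptance checks run the framework at sizes chosen for a single CPU:
noiseless recovery at N = 50,000 / B = 256, baseline calibration and the
second-docking ceiling at N = 20,000, the noisy trend campaign at
N = 100,000 / B = 256 with noise/signal = 1, budget 10% docked,
n ∈ {500, 1000, 2500}, 5 seeds per configuration, and the fold-protocol
arithmetic on a 10⁶-score library. Statistical assertions use 3
hypergeometric standard errors of the seed-mean.

## Known limitations and open choices

* The batch-size advantage of small n is evaluated under MeanRank/noadd
  (the package's default and strongest regime). Under LastModel/noadd the
  smallest batch (n = 500 at B = 256) *inverts* the trend: ordinary least
  squares on n ≈ 2B rows is data-starved, an artifact of desk-scale
  feature/sample ratios (real campaigns train on 4–20× the feature
  count). MeanRank's pooling across iterations compensates, and the
  ordering is monotone there.
* Packed fingerprint storage (8 bits/byte with a JSON header and SHA-256
  payload checksum) is this package's container; a text export exists for
  debugging.
* No hyperparameter search, uncertainty-based acquisition, or
  asynchronous docking orchestration — the loop is deliberately pure
  greedy with library-default models.
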
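"""The iterative acquisition engine.

A campaign starts by docking a uniformly random seed batch of n ligands.
At every later iteration a base regressor is (re)trained on docked
ligands — all of them ("add" regime, |X_j| = n*j) or only the latest batch
("noadd", |X_j| = n) — its predictions over the full library are cached,
and the n undocked ligands it scores best are acquired (docked) next.

Predictions of models from different iterations are combined under three
regimes:

* **LastModel** — no ensembling; use only the newest model.
* **MeanRank**  — each model in the window ranks the undocked pool
  (rank 1 = best, ties get midranks); a ligand's acquisition score is its
  mean rank across models, lower = better.
* **TopFromEveryModel** — each of the k windowed models contributes its
  best ceil(n/k) pool ligands; contributions are concatenated oldest to
  newest, de-duplicated keeping the first occurrence, refilled from the
  most recent model's next-best ligands if short, and truncated to n.

The model window keeps only the last W models (W=20 in ultra-large mode,
unbounded otherwise).  All tie-breaking is by ascending ligand id, so runs
are bit-reproducible from the seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from math import ceil
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from . import models as _models
from .datasets import LigandLibrary
from .evaluation import label_hits

logger = logging.getLogger(__name__)

__all__ = [
    "ActiveConfig",
    "IterationRecord",
    "RunTrace",
    "acquire_batch",
    "ensemble_meanrank",
    "ensemble_topfromevery",
    "build_train_set",
    "run_active_learning",
    "stopping_diagnostic",
]

ENSEMBLING_REGIMES = ("LastModel", "MeanRank", "TopFromEveryModel")
TRAIN_REGIMES = ("add", "noadd")


@dataclass(frozen=True)
class ActiveConfig:
    """Campaign parameters.

    ``window=None`` means unbounded (every model so far participates in the
    ensemble); ultra-large mode uses ``window=20``.  ``baseline="random"``
    replaces the surrogate with fresh Gaussian scores each iteration — the
    random-acquisition control.
    """

    batch_size: int
    n_iterations: int
    ensembling: str = "MeanRank"
    train_regime: str = "noadd"
    window: int | None = None
    beta: float = 0.01
    seed: int = 0
    base_model: _models.ModelSpec = field(default_factory=_models.ModelSpec)
    baseline: str | None = None
    rank_over: str = "pool"

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.ensembling not in ENSEMBLING_REGIMES:
            raise ValueError(f"ensembling must be one of {ENSEMBLING_REGIMES}")
        if self.train_regime not in TRAIN_REGIMES:
            raise ValueError(f"train_regime must be one of {TRAIN_REGIMES}")
        if self.window is not None and self.window < 1:
            raise ValueError("window must be >= 1 (or None for unbounded)")
        if not 0.0 < self.beta <= 1.0:
            raise ValueError("beta must be in (0, 1]")
        if self.baseline not in (None, "random"):
            raise ValueError("baseline must be None or 'random'")
        if self.rank_over not in ("pool", "library"):
            raise ValueError("rank_over must be 'pool' or 'library'")

    def to_dict(self) -> dict:
        d = {
            "batch_size": self.batch_size,
            "n_iterations": self.n_iterations,
            "ensembling": self.ensembling,
            "train_regime": self.train_regime,
            "window": self.window,
            "beta": self.beta,
            "seed": self.seed,
            "base_model": self.base_model.to_dict(),
            "baseline": self.baseline,
            "rank_over": self.rank_over,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ActiveConfig":
        d = dict(d)
        bm = d.get("base_model")
        if isinstance(bm, dict):
            d["base_model"] = _models.ModelSpec(
                family=bm.get("family", "linear"),
                hyperparameters=bm.get("hyperparameters", {}),
                seed=bm.get("seed"),
            )
        return cls(**d)


@dataclass
class IterationRecord:
    """One acquisition step: what was docked and what it yielded."""

    iteration: int
    acquired: np.ndarray
    new_hits: int
    cum_hits: int
    score_min: float
    score_mean: float
    score_median: float
    train_size: int
    fit_seconds: float

    def to_dict(self) -> dict:
        return {
            "iteration": self.iteration,
            "acquired": np.asarray(self.acquired).tolist(),
            "new_hits": self.new_hits,
            "cum_hits": self.cum_hits,
            "score_min": self.score_min,
            "score_mean": self.score_mean,
            "score_median": self.score_median,
            "train_size": self.train_size,
            "fit_seconds": self.fit_seconds,
        }


@dataclass
class RunTrace:
    """Full campaign record: per-iteration batches plus global metadata."""

    config: ActiveConfig
    n_library: int
    k_hits: int
    records: list[IterationRecord] = field(default_factory=list)
    model_params: dict = field(default_factory=dict)
    oracle_description: str = ""

    @property
    def docked_ids(self) -> np.ndarray:
        if not self.records:
            return np.empty(0, dtype=np.int64)
        return np.concatenate([np.asarray(r.acquired, dtype=np.int64) for r in self.records])

    def cumulative_hits(self) -> np.ndarray:
        return np.array([r.cum_hits for r in self.records])

    def validate(self) -> None:
        docked = self.docked_ids
        if len(np.unique(docked)) != len(docked):
            raise AssertionError("a ligand was acquired twice")
        H = self.cumulative_hits()
        if len(H) and (np.any(np.diff(H) < 0) or H[-1] > self.k_hits):
            raise AssertionError("cumulative hits must be non-decreasing and <= k_hits")
        for rec in self.records[:-1]:
            if len(rec.acquired) != self.config.batch_size:
                raise AssertionError("only the final batch may be short")

    def to_jsonl(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            header = {
                "type": "run",
                "config": self.config.to_dict(),
                "n_library": self.n_library,
                "k_hits": self.k_hits,
                "model_params": self.model_params,
                "oracle_description": self.oracle_description,
            }
            fh.write(json.dumps(header) + "\n")
            for rec in self.records:
                fh.write(json.dumps(rec.to_dict()) + "\n")

    @classmethod
    def from_jsonl(cls, path: str | Path) -> "RunTrace":
        with open(path) as fh:
            header = json.loads(fh.readline())
            trace = cls(
                config=ActiveConfig.from_dict(header["config"]),
                n_library=header["n_library"],
                k_hits=header["k_hits"],
                model_params=header.get("model_params", {}),
                oracle_description=header.get("oracle_description", ""),
            )
            for line in fh:
                d = json.loads(line)
                trace.records.append(
                    IterationRecord(
                        iteration=d["iteration"],
                        acquired=np.asarray(d["acquired"], dtype=np.int64),
                        new_hits=d["new_hits"],
                        cum_hits=d["cum_hits"],
                        score_min=d["score_min"],
                        score_mean=d["score_mean"],
                        score_median=d["score_median"],
                        train_size=d["train_size"],
                        fit_seconds=d["fit_seconds"],
                    )
                )
        return trace


def acquire_batch(
    predicted: np.ndarray, pool_ids: np.ndarray, n: int
) -> tuple[np.ndarray, bool]:
    """Pick the n pool ligands with the smallest predicted score.

    Ties are broken by ascending ligand id.  Returns ``(ids, terminal)``
    where ``terminal`` flags an empty pool; a pool shorter than n is
    returned whole.
    """
    pool_ids = np.asarray(pool_ids, dtype=np.int64)
    predicted = np.asarray(predicted, dtype=np.float64)
    if len(predicted) != len(pool_ids):
        raise ValueError("predictions and pool ids must align")
    if len(pool_ids) == 0:
        return np.empty(0, dtype=np.int64), True
    order = np.lexsort((pool_ids, predicted))
    return pool_ids[order[: min(n, len(pool_ids))]], False


def ensemble_meanrank(
    predictions: Sequence[np.ndarray], pool_ids: np.ndarray
) -> np.ndarray:
    """Mean per-model rank of each pool ligand (rank 1 = best; midranks).

    ``predictions`` are cached full-library prediction vectors; the output
    aligns with ``pool_ids`` and is lower-is-better.
    """
    if len(predictions) == 0:
        raise ValueError("MeanRank needs at least one model")
    pool_ids = np.asarray(pool_ids, dtype=np.int64)
    acc = np.zeros(len(pool_ids))
    for pred in predictions:
        acc += rankdata(np.asarray(pred)[pool_ids], method="average")
    return acc / len(predictions)


def ensemble_topfromevery(
    predictions: Sequence[np.ndarray], pool_ids: np.ndarray, n: int
) -> np.ndarray:
    """Union-of-tops acquisition over k models.

    Each model contributes its best ceil(n/k) pool ligands (score order,
    ties by id), oldest model first.  Duplicates keep their first
    occurrence; if the de-duplicated union falls short of n it is refilled
    from the most recent model's next-best ligands; the result is truncated
    to min(n, |pool|).
    """
    k = len(predictions)
    if k == 0:
        raise ValueError("TopFromEveryModel needs at least one model")
    pool_ids = np.asarray(pool_ids, dtype=np.int64)
    target = min(n, len(pool_ids))
    share = ceil(n / k)
    orders = [
        pool_ids[np.lexsort((pool_ids, np.asarray(pred)[pool_ids]))]
        for pred in predictions
    ]
    seen: set[int] = set()
    chosen: list[int] = []
    for ranked in orders:  # oldest -> newest
        for lig in ranked[:share].tolist():
            if lig not in seen:
                seen.add(lig)
                chosen.append(lig)
    if len(chosen) < target:  # refill from the freshest model
        for lig in orders[-1].tolist():
            if lig not in seen:
                seen.add(lig)
                chosen.append(lig)
                if len(chosen) == target:
                    break
    return np.asarray(chosen[:target], dtype=np.int64)


def build_train_set(
    batches: Sequence[np.ndarray], regime: str
) -> np.ndarray:
    """Training ids for the next model: every docked ligand ("add") or the
    most recent batch only ("noadd")."""
    if len(batches) == 0:
        raise ValueError("no completed iterations")
    if regime == "add":
        return np.concatenate([np.asarray(b, dtype=np.int64) for b in batches])
    if regime == "noadd":
        return np.asarray(batches[-1], dtype=np.int64)
    raise ValueError(f"unknown train regime {regime!r}")


def run_active_learning(
    library: LigandLibrary,
    config: ActiveConfig,
    *,
    scores: np.ndarray | None = None,
    fixed_predictions: np.ndarray | None = None,
) -> RunTrace:
    """Execute a full greedy acquisition campaign and return its trace.

    ``scores`` (default: ``library.scores``) is the ground-truth score
    vector the oracle reveals batch by batch; hits are its best beta
    fraction.  ``fixed_predictions`` short-circuits the surrogate with a
    frozen predictor vector (the second-docking upper-bound baseline);
    ``config.baseline="random"`` draws fresh Gaussian predictions each
    iteration (the lower bound).  Bit-reproducible from ``config.seed``.
    """
    if library.fingerprints is None and config.baseline is None and fixed_predictions is None:
        raise ValueError("library has no fingerprints; cannot train surrogate models")
    y = library.scores if scores is None else np.asarray(scores, dtype=np.float64)
    if y is None:
        raise ValueError("no scores available to act as the docking oracle")
    if len(y) != library.n:
        raise ValueError("score vector length does not match the library")
    n_lib = library.n
    n = config.batch_size
    labels = label_hits(y, config.beta)

    if n * config.n_iterations > n_lib:
        logger.warning(
            "budget %d exceeds library size %d; final batch will be truncated",
            n * config.n_iterations, n_lib,
        )

    root = np.random.SeedSequence(config.seed)
    model_seed_src = root.spawn(config.n_iterations)
    rng = np.random.default_rng(root)

    trace = RunTrace(config=config, n_library=n_lib, k_hits=labels.k_hits)
    docked = np.zeros(n_lib, dtype=bool)
    batches: list[np.ndarray] = []
    window_models: list[_models.FittedModel] = []
    cum_hits = 0

    for j in range(config.n_iterations):
        pool_ids = np.flatnonzero(~docked)
        if len(pool_ids) == 0:
            logger.info("pool exhausted after %d iterations", j)
            break
        fit_seconds = 0.0
        train_size = 0
        if j == 0:
            batch = np.sort(rng.choice(n_lib, size=min(n, n_lib), replace=False))
        elif config.baseline == "random":
            y_seen = y[docked]
            pred_pool = rng.normal(float(y_seen.mean()), float(y_seen.std()) or 1.0,
                                   len(pool_ids))
            batch, _ = acquire_batch(pred_pool, pool_ids, n)
        elif fixed_predictions is not None:
            batch, _ = acquire_batch(
                np.asarray(fixed_predictions, dtype=np.float64)[pool_ids], pool_ids, n
            )
        else:
            train_ids = build_train_set(batches, config.train_regime)
            train_size = len(train_ids)
            spec = config.base_model
            if spec.family in ("lasso_cv", "linear_svr", "decision_tree", "random_forest"):
                it_seed = int(model_seed_src[j].generate_state(1)[0] % (2**31))
                spec = _models.ModelSpec(spec.family, dict(spec.hyperparameters), it_seed)
            fm = _models.fit(spec, library.fingerprints[train_ids], y[train_ids])
            fm.cached_predictions = _models.predict(fm, library.fingerprints)
            fit_seconds = fm.fit_seconds
            if not trace.model_params:
                trace.model_params = dict(fm.resolved_params)
            window_models.append(fm)
            if config.window is not None and len(window_models) > config.window:
                window_models = window_models[-config.window :]
            preds = [m.cached_predictions for m in window_models]
            if config.ensembling == "LastModel":
                batch, _ = acquire_batch(preds[-1][pool_ids], pool_ids, n)
            elif config.ensembling == "MeanRank":
                rank_ids = np.arange(n_lib) if config.rank_over == "library" else pool_ids
                combined = ensemble_meanrank(preds, rank_ids)
                if config.rank_over == "library":
                    combined = combined[pool_ids]
                batch, _ = acquire_batch(combined, pool_ids, n)
            else:
                batch = ensemble_topfromevery(preds, pool_ids, n)

        batch_scores = y[batch]
        new_hits = int(labels.mask[batch].sum())
        cum_hits += new_hits
        docked[batch] = True
        batches.append(batch)
        trace.records.append(
            IterationRecord(
                iteration=j,
                acquired=batch,
                new_hits=new_hits,
                cum_hits=cum_hits,
                score_min=float(batch_scores.min()),
                score_mean=float(batch_scores.mean()),
                score_median=float(np.median(batch_scores)),
                train_size=train_size,
                fit_seconds=fit_seconds,
            )
        )
    trace.validate()
    return trace


def stopping_diagnostic(trace: RunTrace) -> "pd.DataFrame":
    """Per-iteration hit yield relative to the random expectation.

    For each iteration the expected random yield is
    ``|batch| * remaining_hits / remaining_pool`` (both counted before the
    batch was acquired); the reported ratio h_j / expected drifting toward
    1 signals that the surrogate has stopped beating chance — an advisory
    stopping criterion, never enforced.
    """
    import pandas as pd

    if not trace.records:
        raise ValueError("empty trace")
    rows = []
    docked_before = 0
    hits_before = 0
    for rec in trace.records:
        remaining_hits = trace.k_hits - hits_before
        remaining_pool = trace.n_library - docked_before
        expected = len(rec.acquired) * remaining_hits / remaining_pool if remaining_pool else 0.0
        exhausted = expected == 0.0
        ratio = 0.0 if exhausted else rec.new_hits / expected
        rows.append(
            dict(iteration=rec.iteration, new_hits=rec.new_hits,
                 expected_random=expected, ratio=ratio, hits_exhausted=exhausted)
        )
        docked_before += len(rec.acquired)
        hits_before = rec.cum_hits
    return pd.DataFrame(rows)
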
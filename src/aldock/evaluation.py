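"""Hit labeling, recall metrics, the single-iteration benchmark, and the
constant-recall extrapolation model.

Virtual-screening hits (VSHs) are the ligands whose docking scores fall in
the best (lowest) beta fraction of the library — top-1% by default, top-0.05%
for ultra-large comparisons.  Two recall notions are used:

* **single-iteration recall** — train a regressor on m ligands, predict a
  held-out partition, and count how many of the partition's true hits land
  in the model's predicted top-beta of that partition;
* **cumulative recall** — in an active-learning campaign, the fraction of
  all library hits among everything docked so far (acquisition = docking).

The single-iteration protocol draws a pool of 1.25·m ligands, labels the
pool's top-1% as hits, and splits it with stratified 5-fold CV into train
partitions of m and test partitions of m/4 — a 1:99 hit:nonhit imbalance on
both sides.  Fold assignments depend only on (m, seed), never on the model
family, so every family is scored on identical folds.

The constant-recall extrapolation assumes the model keeps retrieving a
fixed fraction r of the hits still hidden in the pool at every step:
``h_0 = n*beta*r`` and ``h_j = (N*beta - H_{j-1})*r``, whose cumulative sum
has the closed form ``H_j = N*beta - (N*beta - n*beta*r)*(1-r)**j``.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import models as _models
from .datasets import LigandLibrary
from .oracle import random_score_baseline

if TYPE_CHECKING:  # pragma: no cover
    from .active_loop import RunTrace

__all__ = [
    "HitLabels",
    "FoldPlan",
    "ExtrapolationCurve",
    "label_hits",
    "recall_at",
    "top_fraction_ids",
    "single_iteration_recall",
    "make_fold_plan",
    "single_iteration_benchmark",
    "extrapolate_recall",
    "compare_trace_to_extrapolation",
]

#: benchmark pseudo-families handled without fitting an estimator
BASELINE_FAMILIES = ("random", "second_docking", "perfect")


@dataclass
class HitLabels:
    """Boolean hit mask over the library: the round(beta*N) lowest scores."""

    mask: np.ndarray
    beta: float
    k_hits: int

    @property
    def ids(self) -> np.ndarray:
        return np.flatnonzero(self.mask)


def label_hits(scores: np.ndarray, beta: float) -> HitLabels:
    """Flag the round(beta*N) best-scoring ligands as virtual screening hits.

    Ties at the score cutoff are broken by ascending ligand id, so the
    flagged set is deterministic.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    n = len(scores)
    k = int(np.rint(beta * n))
    if k < 1:
        raise ValueError(
            f"round(beta*N) = 0 for beta={beta}, N={n}: increase beta or the library size"
        )
    order = np.lexsort((np.arange(n), scores))
    mask = np.zeros(n, dtype=bool)
    mask[order[:k]] = True
    return HitLabels(mask=mask, beta=float(beta), k_hits=k)


def top_fraction_ids(predicted: np.ndarray, beta: float, ids: np.ndarray | None = None) -> np.ndarray:
    """Ids of the round(beta*len) lowest predicted scores (ties by ascending id)."""
    predicted = np.asarray(predicted, dtype=np.float64)
    n = len(predicted)
    ids = np.arange(n) if ids is None else np.asarray(ids)
    k = int(np.rint(beta * n))
    order = np.lexsort((ids, predicted))
    return ids[order[:k]]


def recall_at(selected_ids: np.ndarray, labels: HitLabels) -> float:
    """|selected ∩ hits| / k_hits."""
    selected_ids = np.asarray(selected_ids, dtype=np.int64)
    if selected_ids.size and (
        selected_ids.min() < 0 or selected_ids.max() >= len(labels.mask)
    ):
        raise ValueError("selected ids outside the library range")
    return float(labels.mask[selected_ids].sum() / labels.k_hits)


def single_iteration_recall(predicted: np.ndarray, hit_mask: np.ndarray) -> float:
    """Recall within one held-out partition.

    Select as many top-predicted ligands (lowest predicted scores, ties by
    position) as the partition has true hits and count the fraction of
    those hits caught.  With the stratified 1:99 protocol the partition's
    hit count equals its top-beta size whenever beta*|partition| is
    integral, so this coincides with "hits in the predicted top-beta";
    when rounding makes the two differ by one ligand, selecting the hit
    count keeps a perfect predictor at recall 1.0.
    """
    predicted = np.asarray(predicted, dtype=np.float64)
    hit_mask = np.asarray(hit_mask, dtype=bool)
    n_hits = int(hit_mask.sum())
    if n_hits == 0:
        raise ValueError("partition contains no hits")
    order = np.lexsort((np.arange(len(predicted)), predicted))
    sel = order[:n_hits]
    return float(hit_mask[sel].sum() / n_hits)


@dataclass
class FoldPlan:
    """Stratified single-iteration fold layout, reproducible from (m, seed).

    ``pool_ids`` are the 1.25·m library ids in the plan; ``hit_mask`` is
    pool-aligned (top-1% of the pool's own scores); ``folds`` holds
    (train_ids, test_ids) pairs in library-id space.
    """

    m: int
    n_folds: int
    beta: float
    seed: int
    pool_ids: np.ndarray
    hit_mask: np.ndarray
    folds: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "m": self.m,
                "n_folds": self.n_folds,
                "beta": self.beta,
                "seed": self.seed,
                "pool_ids": self.pool_ids.tolist(),
                "hit_mask": self.hit_mask.astype(int).tolist(),
                "folds": [[tr.tolist(), te.tolist()] for tr, te in self.folds],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "FoldPlan":
        d = json.loads(text)
        return cls(
            m=d["m"],
            n_folds=d["n_folds"],
            beta=d["beta"],
            seed=d["seed"],
            pool_ids=np.asarray(d["pool_ids"], dtype=np.int64),
            hit_mask=np.asarray(d["hit_mask"], dtype=bool),
            folds=[
                (np.asarray(tr, dtype=np.int64), np.asarray(te, dtype=np.int64))
                for tr, te in d["folds"]
            ],
        )


def make_fold_plan(
    scores: np.ndarray,
    m: int,
    n_folds: int = 5,
    seed: int = 0,
    beta: float = 0.01,
) -> FoldPlan:
    """Draw a 1.25·m pool and build stratified train/test folds (m : m/4).

    The pool is a seeded uniform sample of the library; its top-beta are the
    plan's hits; stratification keeps the ~1:99 imbalance identical in
    train and test partitions.  The plan depends only on (scores, m,
    n_folds, seed, beta) — never on the model evaluated with it.
    """
    scores = np.asarray(scores, dtype=np.float64)
    n = len(scores)
    pool_size = int(round(1.25 * m))
    if n < pool_size:
        raise ValueError(f"library of {n} ligands cannot supply a pool of {pool_size}")
    n_pool_hits = int(np.rint(beta * pool_size))
    if n_pool_hits < n_folds:
        raise ValueError(
            f"only {n_pool_hits} pool hits for {n_folds} folds: too few to stratify"
        )
    rng = np.random.default_rng(seed)
    pool_ids = np.sort(rng.choice(n, size=pool_size, replace=False))
    hit_mask = label_hits(scores[pool_ids], beta).mask
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed % (2**32))
    folds = [
        (pool_ids[train_idx], pool_ids[test_idx])
        for train_idx, test_idx in skf.split(np.zeros(pool_size), hit_mask)
    ]
    return FoldPlan(
        m=m, n_folds=n_folds, beta=float(beta), seed=seed,
        pool_ids=pool_ids, hit_mask=hit_mask, folds=folds,
    )


def _pool_mask_lookup(plan: FoldPlan) -> dict[int, bool]:
    return dict(zip(plan.pool_ids.tolist(), plan.hit_mask.tolist()))


def single_iteration_benchmark(
    library: LigandLibrary,
    specs: Sequence[_models.ModelSpec | str],
    train_sizes: Sequence[int],
    *,
    seed: int = 0,
    n_folds: int = 5,
    beta: float = 0.01,
    second_scores: np.ndarray | None = None,
) -> pd.DataFrame:
    """Recall + wall time for each (model family, train size m, fold).

    ``specs`` may mix :class:`~aldock.models.ModelSpec` instances, family
    name strings, and the pseudo-families ``"random"`` (Gaussian baseline),
    ``"second_docking"`` (needs ``second_scores``), and ``"perfect"``
    (predicts the true scores; sanity ceiling).  A model failure is
    recorded as a NaN cell and the benchmark continues.
    """
    if library.scores is None:
        raise ValueError("library has no scores")
    resolved: list[_models.ModelSpec | str] = [
        s if isinstance(s, _models.ModelSpec) or s in BASELINE_FAMILIES
        else _models.ModelSpec(family=s)
        for s in specs
    ]
    rows = []
    for m in train_sizes:
        plan_seed = int(np.random.SeedSequence([seed, m]).generate_state(1)[0] % (2**31))
        plan = make_fold_plan(library.scores, m, n_folds=n_folds, seed=plan_seed, beta=beta)
        lookup = _pool_mask_lookup(plan)
        for spec in resolved:
            family = spec if isinstance(spec, str) else spec.family
            for fold_idx, (train_ids, test_ids) in enumerate(plan.folds):
                test_mask = np.array([lookup[i] for i in test_ids.tolist()], dtype=bool)
                y_train = library.scores[train_ids]
                fit_s = pred_s = 0.0
                try:
                    if family == "random":
                        bl_seed = int(
                            np.random.SeedSequence([seed, m, fold_idx]).generate_state(1)[0]
                            % (2**31)
                        )
                        pred = random_score_baseline(y_train, bl_seed, size=len(test_ids))
                    elif family == "second_docking":
                        if second_scores is None:
                            raise ValueError("second_docking baseline needs second_scores")
                        pred = np.asarray(second_scores)[test_ids]
                    elif family == "perfect":
                        pred = library.scores[test_ids]
                    else:
                        if library.fingerprints is None:
                            raise ValueError("library has no fingerprints")
                        fm = _models.fit(spec, library.fingerprints[train_ids], y_train)
                        fit_s = fm.fit_seconds
                        t0 = time.perf_counter()
                        pred = _models.predict(fm, library.fingerprints[test_ids])
                        pred_s = time.perf_counter() - t0
                    recall = single_iteration_recall(pred, test_mask)
                except Exception as exc:  # record the failed cell, keep going
                    rows.append(
                        dict(family=family, m=m, fold=fold_idx, recall=np.nan,
                             fit_seconds=np.nan, predict_seconds=np.nan, error=str(exc))
                    )
                    continue
                rows.append(
                    dict(family=family, m=m, fold=fold_idx, recall=recall,
                         fit_seconds=fit_s, predict_seconds=pred_s, error="")
                )
    return pd.DataFrame(rows)


@dataclass
class ExtrapolationCurve:
    """Per-step and cumulative hit counts under the constant-recall model."""

    n: int
    n_library: int
    r: float
    beta: float
    h: np.ndarray  # h_j, j = 0..J
    H: np.ndarray  # cumulative

    def closed_form(self) -> np.ndarray:
        """H_j = N*beta - (N*beta - n*beta*r) * (1-r)**j."""
        j = np.arange(len(self.H))
        nb = self.n_library * self.beta
        return nb - (nb - self.n * self.beta * self.r) * (1.0 - self.r) ** j


def extrapolate_recall(
    n: int, n_library: int, r: float, beta: float, n_steps: int
) -> ExtrapolationCurve:
    """Iterate the constant-recall recurrence for j = 0..n_steps.

    Step 0 retrieves ``h_0 = n*beta*r``; every later step retrieves fraction
    r of the hits still outstanding: ``h_j = (N*beta - H_{j-1})*r``.
    """
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"recall r must lie in [0, 1], got {r}")
    if n > n_library:
        raise ValueError("batch size exceeds library size")
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    total_hits = n_library * beta
    h = np.empty(n_steps + 1)
    H = np.empty(n_steps + 1)
    h[0] = n * beta * r
    H[0] = h[0]
    for j in range(1, n_steps + 1):
        h[j] = (total_hits - H[j - 1]) * r
        H[j] = H[j - 1] + h[j]
    return ExtrapolationCurve(n=n, n_library=n_library, r=r, beta=beta, h=h, H=H)


def compare_trace_to_extrapolation(
    trace: "RunTrace", r: float, curve: ExtrapolationCurve | None = None
) -> tuple[pd.DataFrame, dict]:
    """Align a campaign trace with its constant-recall extrapolation.

    Returns per-iteration cumulative-hit curves for the trace, the
    extrapolation at recall r, and the analytic random line H = docked*beta,
    plus a deviation summary (extrapolation minus trace, in hit-fraction
    units).  The random seed batch of a real campaign retrieves ~n*beta hits
    while the extrapolation charges it n*beta*r — an intentional fidelity
    to the published recurrence, reported as-is.
    """
    n_iter = len(trace.records)
    if curve is not None and curve.n != trace.config.batch_size:
        raise ValueError(
            f"extrapolation batch size {curve.n} != trace batch size "
            f"{trace.config.batch_size}"
        )
    if n_iter == 0:
        return pd.DataFrame(
            columns=["iteration", "fraction_docked", "hits_trace",
                     "hits_extrapolation", "hits_random"]
        ), {"max_abs_deviation": np.nan, "mean_deviation": np.nan}
    if curve is None:
        curve = extrapolate_recall(
            trace.config.batch_size, trace.n_library, r, trace.config.beta, n_iter - 1
        )
    docked = np.cumsum([len(rec.acquired) for rec in trace.records])
    rows = pd.DataFrame(
        {
            "iteration": np.arange(n_iter),
            "fraction_docked": docked / trace.n_library,
            "hits_trace": [rec.cum_hits for rec in trace.records],
            "hits_extrapolation": curve.H[:n_iter],
            "hits_random": docked * trace.config.beta,
        }
    )
    dev = (rows["hits_extrapolation"] - rows["hits_trace"]) / trace.k_hits
    summary = {
        "max_abs_deviation": float(dev.abs().max()),
        "mean_deviation": float(dev.mean()),
    }
    return rows, summary
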
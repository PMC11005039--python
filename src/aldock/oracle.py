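"""Score oracles: synthetic docking surrogate and the two campaign baselines.

Docking scores from a sampling-based scoring function are noisy: re-docking
the same ligand with a different random seed yields a different score.  The
synthetic oracle emulates this with a sparse linear ground truth over
binary fingerprint bits plus two independent Gaussian noise draws per
ligand — the pair plays the role of two independent docking runs of the
same library against the same receptor, which bound what any surrogate
model can achieve ("second docking" ceiling).

Two baselines bracket surrogate performance in a campaign:

* **random** — i.i.d. Gaussian scores matching the library's score mean
  and standard deviation; selection by this predictor is uniformly random,
  so its hit recall sits at the hit fraction beta (lower bound).
* **second docking** — the other noisy realization used as the predictor
  of the first; no model trained on run-1 scores can beat run 2 of the
  docking program itself (upper bound).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datasets import LigandLibrary

__all__ = [
    "SyntheticOracleSpec",
    "PairedScores",
    "make_synthetic_library",
    "random_score_baseline",
    "second_docking_predictor",
]


@dataclass(frozen=True)
class SyntheticOracleSpec:
    """Parameters of the synthetic docking oracle.

    ``true_score = -(w . x)`` with non-negative weights ``w`` supported on a
    random ``weight_sparsity`` fraction of bits, so bit-rich ligands score
    lower (= better), matching the sign convention of empirical scoring
    functions.  ``noise_sd`` is the per-realization Gaussian noise standard
    deviation; ``noise_to_signal``, when given, overrides it as
    ``noise_sd = sqrt(noise_to_signal * var(true_score))``.
    """

    n_ligands: int
    n_bits: int = 256
    bit_density: float = 0.05
    weight_sparsity: float = 0.25
    weight_scale: float = 1.0
    noise_sd: float = 0.0
    noise_to_signal: float | None = None
    interaction_strength: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ligands < 1:
            raise ValueError("n_ligands must be >= 1")
        if self.interaction_strength < 0:
            raise ValueError("interaction_strength must be >= 0")
        if not 0.0 < self.bit_density < 1.0:
            raise ValueError(f"bit_density must be in (0, 1), got {self.bit_density}")
        if not 0.0 < self.weight_sparsity <= 1.0:
            raise ValueError("weight_sparsity must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.noise_to_signal is not None and self.noise_to_signal < 0:
            raise ValueError("noise_to_signal must be >= 0")


@dataclass
class PairedScores:
    """Noiseless ground truth plus two independent noisy realizations.

    ``realization_a`` conventionally plays the first docking run (defines
    ground-truth hits in a campaign); ``realization_b`` the second.  As the
    noise vanishes the two realizations coincide with ``true_score``.
    """

    true_score: np.ndarray
    realization_a: np.ndarray
    realization_b: np.ndarray
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        for name in ("true_score", "realization_a", "realization_b"):
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
            setattr(self, name, arr)
        n = len(self.true_score)
        if len(self.realization_a) != n or len(self.realization_b) != n:
            raise ValueError("paired score vectors must share length")


def make_synthetic_library(
    spec: SyntheticOracleSpec,
) -> tuple[LigandLibrary, PairedScores]:
    """Generate a fingerprint library with paired noisy docking scores.

    Fingerprint bits are i.i.d. Bernoulli(``bit_density``); the library's
    ``scores`` field holds ``realization_a`` (the "first docking run").
    Fully reproducible from ``spec.seed``.
    """
    root = np.random.SeedSequence(spec.seed)
    ss_bits, ss_weights, ss_noise = root.spawn(3)
    n, b = spec.n_ligands, spec.n_bits

    rng_bits = np.random.default_rng(ss_bits)
    fingerprints = (rng_bits.random((n, b)) < spec.bit_density).astype(np.uint8)

    rng_w = np.random.default_rng(ss_weights)
    support_size = max(1, int(round(spec.weight_sparsity * b)))
    support = rng_w.choice(b, size=support_size, replace=False)
    weights = np.zeros(b)
    weights[support] = np.abs(rng_w.standard_normal(support_size)) * spec.weight_scale

    true_score = -(fingerprints @ weights).astype(np.float64)
    if spec.interaction_strength > 0:
        # nonlinear stress option: sparse pairwise bit interactions, so the
        # linear surrogate is deliberately misspecified
        n_pairs = max(1, b // 4)
        pairs = rng_w.choice(b, size=(n_pairs, 2))
        pair_w = np.abs(rng_w.standard_normal(n_pairs)) * spec.interaction_strength
        for (i, k), w in zip(pairs, pair_w):
            true_score -= w * (fingerprints[:, i] & fingerprints[:, k])

    if spec.noise_to_signal is not None:
        noise_sd = float(np.sqrt(spec.noise_to_signal * true_score.var()))
    else:
        noise_sd = float(spec.noise_sd)
    rng_noise = np.random.default_rng(ss_noise)
    realization_a = true_score + rng_noise.normal(0.0, noise_sd, n) if noise_sd else true_score.copy()
    realization_b = true_score + rng_noise.normal(0.0, noise_sd, n) if noise_sd else true_score.copy()

    library = LigandLibrary(
        ids=np.arange(n),
        fingerprints=fingerprints,
        scores=realization_a,
    )
    paired = PairedScores(
        true_score=true_score,
        realization_a=realization_a,
        realization_b=realization_b,
        noise_sd=noise_sd,
    )
    return library, paired


def random_score_baseline(
    scores: np.ndarray, seed: int, size: int | None = None
) -> np.ndarray:
    """Gaussian random-score predictor matching the input mean and SD.

    Draws i.i.d. ``Normal(mean(scores), sd(scores))``, one per ligand (or
    ``size`` draws when given), ignoring fingerprints entirely — the
    lower-bound baseline of a screening campaign.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if len(scores) < 2:
        raise ValueError("need at least 2 scores to match mean and SD")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    size = len(scores) if size is None else size
    sd = float(scores.std())
    if sd == 0.0:
        warnings.warn("zero-variance scores: random baseline returns a constant vector")
        return np.full(size, float(scores.mean()))
    rng = np.random.default_rng(seed)
    return rng.normal(float(scores.mean()), sd, size)


def second_docking_predictor(paired: PairedScores, predict_with: str = "b") -> np.ndarray:
    """Use one noisy docking realization as the predictor of the other.

    With ``predict_with="b"`` (default) realization_b predicts the hits
    defined by realization_a, and vice versa.  The pair is exchangeable,
    so expected recall is invariant to the choice.
    """
    if predict_with not in ("a", "b"):
        raise ValueError(f"predict_with must be 'a' or 'b', got {predict_with!r}")
    vec = paired.realization_b if predict_with == "b" else paired.realization_a
    if vec is None:
        raise ValueError(f"realization_{predict_with} is missing")
    return np.asarray(vec, dtype=np.float64)
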
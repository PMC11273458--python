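"""Batch selection for exploration and exploitation, plus campaign metrics.

Exploration picks the candidates about which the model is most uncertain:
the posterior standard deviation is recomputed after every single pick by
conditioning the GP on the already-selected points (posterior variance does
not depend on the unobserved labels, so no fantasy labels are needed).

Exploitation ranks candidates by posterior mean, keeps a top-M pool, and
diversifies within it by greedy MAP inference for a determinantal point
process (DPP) whose kernel is the fitted GP kernel on the standardized
descriptors — at each step the variant adding the largest log-determinant
gain joins the batch, which pushes the batch toward mutually dissimilar
(near-orthogonal) feature vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gp_model import GPFit, predict

__all__ = [
    "BatchDesign",
    "select_exploration_batch",
    "select_exploitation_batch",
    "hit_rate",
    "precision_at_hits",
    "learning_curve",
    "diversity_metrics",
]


@dataclass
class BatchDesign:
    """An ordered batch of selected variants with per-pick scores."""

    variants: list[str]
    indices: list[int]
    scores: list[float]
    criterion: str
    round_label: str = ""
    pool_description: str = ""

    def __post_init__(self) -> None:
        if len(set(self.variants)) != len(self.variants):
            raise ValueError("batch contains duplicate variants")

    def __len__(self) -> int:
        return len(self.variants)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.variants) + 1),
                "variant_code": self.variants,
                "score": self.scores,
                "criterion": self.criterion,
            }
        )


def _lexicographic_argmax(values: np.ndarray, codes: list[str], active: np.ndarray) -> int:
    """Index of the maximum, ties broken by lexicographically smallest code."""
    vals = np.where(active, values, -np.inf)
    top = vals.max()
    tied = np.flatnonzero(vals >= top - 1e-12)
    if tied.size == 1:
        return int(tied[0])
    return int(min(tied, key=lambda i: codes[i]))


def select_exploration_batch(
    fit: GPFit,
    candidate_X: np.ndarray,
    candidate_codes: list[str],
    batch_size: int,
    round_label: str = "",
) -> BatchDesign:
    """Iterative maximum-uncertainty selection with label-free conditioning.

    Greedy loop: pick the candidate with the largest posterior standard
    deviation, condition the posterior covariance on a (future, noisy)
    observation at that point, recompute all candidate variances, repeat.
    The recorded score of each pick is its posterior std at selection time.
    """
    candidate_X = np.atleast_2d(np.asarray(candidate_X, dtype=float))
    n_cand = candidate_X.shape[0]
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    if batch_size > n_cand:
        raise ValueError(f"batch_size={batch_size} exceeds the {n_cand} candidates")
    if len(candidate_codes) != n_cand:
        raise ValueError("candidate codes do not align with candidate features")

    noise_var = fit.config.sigma_log**2 + fit.config.jitter
    # Posterior variance given the training set.
    pred = predict(fit, candidate_X)
    var = pred.std**2
    # B[:, t] are normalized conditional cross-covariances to the t-th pick;
    # posterior covariance between i and j given training and picks is
    # k_post(i, j) - sum_t B[i, t] B[j, t].
    B = np.zeros((n_cand, batch_size))
    K_cross = fit.kernel(candidate_X, fit.X)
    from scipy.linalg import solve_triangular

    V = solve_triangular(fit.L, K_cross.T, lower=True)  # (n_train, n_cand)

    active = np.ones(n_cand, dtype=bool)
    picks: list[int] = []
    scores: list[float] = []
    for t in range(batch_size):
        j = _lexicographic_argmax(var, candidate_codes, active)
        scores.append(float(np.sqrt(max(var[j], 0.0))))
        picks.append(j)
        active[j] = False
        # Posterior covariance of every candidate with the pick.
        cov_j = fit.kernel(candidate_X, candidate_X[j : j + 1]).ravel() - V.T @ V[:, j]
        if t:
            cov_j -= B[:, :t] @ B[j, :t]
        denom = var[j] + noise_var
        b = cov_j / np.sqrt(denom)
        B[:, t] = b
        var = np.maximum(var - b**2, 0.0)
    return BatchDesign(
        variants=[candidate_codes[i] for i in picks],
        indices=picks,
        scores=scores,
        criterion="max_posterior_std",
        round_label=round_label,
        pool_description=f"{n_cand} candidates",
    )


def greedy_dpp(K: np.ndarray, k: int, codes: list[str] | None = None) -> list[int]:
    """Greedy MAP inference for a DPP with kernel Gram matrix ``K``.

    Iteratively adds the item with the largest conditional variance
    (equivalently the largest log-determinant gain), with ties broken by
    lexicographic code.  Exact for k=1 and a standard 1/4-approximation in
    general; matches exhaustive search on small pools in practice.
    """
    n = K.shape[0]
    if codes is None:
        codes = [f"{i:06d}" for i in range(n)]
    d = np.diag(K).astype(float).copy()
    B = np.zeros((n, k))
    active = np.ones(n, dtype=bool)
    picks: list[int] = []
    for t in range(k):
        j = _lexicographic_argmax(d, codes, active)
        picks.append(j)
        active[j] = False
        c = K[:, j] - B[:, :t] @ B[j, :t]
        b = c / np.sqrt(max(d[j], 1e-300))
        B[:, t] = b
        d = np.maximum(d - b**2, 0.0)
    return picks


__all__.append("greedy_dpp")


def select_exploitation_batch(
    fit: GPFit,
    candidate_X: np.ndarray,
    candidate_codes: list[str],
    batch_size: int,
    pool_size: int | None = None,
    round_label: str = "",
) -> BatchDesign:
    """Top predictions diversified by a greedy DPP.

    Candidates are ranked by posterior mean; the top ``pool_size`` (default
    5x the batch size) form the high-prediction pool; a greedy MAP DPP on
    the fitted kernel's Gram submatrix picks ``batch_size`` mutually
    dissimilar variants from that pool.  With ``pool_size == batch_size``
    the batch is exactly the greedy top-k by mean.
    """
    candidate_X = np.atleast_2d(np.asarray(candidate_X, dtype=float))
    n_cand = candidate_X.shape[0]
    if pool_size is None:
        pool_size = 5 * batch_size
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    if pool_size < batch_size:
        raise ValueError(f"pool_size={pool_size} smaller than batch_size={batch_size}")
    pool_size = min(pool_size, n_cand)
    if pool_size < batch_size:
        raise ValueError(f"batch_size={batch_size} exceeds the {n_cand} candidates")

    pred = predict(fit, candidate_X)
    order = np.lexsort((candidate_codes, -pred.mean))
    pool = order[:pool_size]
    K = fit.kernel(candidate_X[pool], candidate_X[pool])
    K = K + 1e-10 * np.eye(pool_size)
    local = greedy_dpp(K, batch_size, codes=[candidate_codes[i] for i in pool])
    picks = [int(pool[i]) for i in local]
    return BatchDesign(
        variants=[candidate_codes[i] for i in picks],
        indices=picks,
        scores=[float(pred.mean[i]) for i in picks],
        criterion="dpp_diversified_top_mean",
        round_label=round_label,
        pool_description=f"top-{pool_size} of {n_cand} candidates by posterior mean",
    )


def hit_rate(activities: np.ndarray, threshold: float = 1.0) -> float:
    """Fraction of variants with relative activity above the reference."""
    arr = np.asarray(activities, dtype=float)
    if arr.size == 0:
        raise ValueError("empty activity vector")
    return float((arr > threshold).mean())


def precision_at_hits(
    predicted_means: np.ndarray,
    actual_activities: np.ndarray,
    threshold: float = 1.0,
) -> float:
    """TP / (TP + FP) for predicted hits; NaN if nothing is predicted a hit.

    Both vectors must be on the same (relative-activity) scale.
    """
    pred = np.asarray(predicted_means, dtype=float)
    actual = np.asarray(actual_activities, dtype=float)
    if pred.shape != actual.shape:
        raise ValueError("prediction and activity vectors are not aligned")
    predicted_hit = pred > threshold
    if not predicted_hit.any():
        warnings.warn("no variant predicted to be a hit; precision undefined")
        return float("nan")
    return float((actual[predicted_hit] > threshold).mean())


def learning_curve(
    X: np.ndarray,
    y_log: np.ndarray,
    groups: np.ndarray,
    X_test: np.ndarray,
    y_test_log: np.ndarray,
    fractions: list[float],
    config,
    seeds: list[int],
    threshold: float = 1.0,
) -> pd.DataFrame:
    """Precision and MSE versus training-set fraction.

    For each fraction and seed, a random subsample of distinct variants is
    drawn, the GP is refitted, and precision-at-hits plus MSE are evaluated
    on the fixed held-out set; metrics are averaged over seeds.
    """
    from .gp_model import fit_gp

    groups = np.asarray(groups)
    uniq = np.unique(groups)
    rows = []
    for frac in fractions:
        if not 0 < frac <= 1:
            raise ValueError(f"fractions must lie in (0, 1], got {frac}")
        precisions, mses, ns = [], [], []
        for seed in seeds:
            rng = np.random.default_rng(seed)
            n_take = max(int(round(frac * uniq.size)), 2)
            take = set(rng.choice(uniq, size=min(n_take, uniq.size), replace=False))
            mask = np.array([g in take for g in groups])
            if mask.sum() < 3:
                warnings.warn(f"fraction {frac} leaves too few rows; skipped")
                continue
            fit = fit_gp(X[mask], y_log[mask], config)
            pred = predict(fit, X_test)
            precisions.append(
                precision_at_hits(np.exp(pred.mean), np.exp(y_test_log), threshold)
            )
            mses.append(float(((pred.mean - y_test_log) ** 2).mean()))
            ns.append(int(mask.sum()))
        rows.append(
            {
                "fraction": frac,
                "n": float(np.mean(ns)) if ns else np.nan,
                "precision": float(np.nanmean(precisions)) if precisions else np.nan,
                "mse": float(np.mean(mses)) if mses else np.nan,
            }
        )
    return pd.DataFrame(rows)


def diversity_metrics(batch_X: np.ndarray, gram: np.ndarray | None = None) -> dict[str, float]:
    """Mean/min pairwise Euclidean distance and Gram log-determinant of a batch.

    ``gram`` defaults to the linear Gram matrix of the feature rows.  A batch
    with duplicate rows has zero minimum distance and log-det -inf.
    """
    X = np.atleast_2d(np.asarray(batch_X, dtype=float))
    m = X.shape[0]
    if m < 2:
        raise ValueError("diversity metrics need a batch of >= 2 variants")
    diffs = X[:, None, :] - X[None, :, :]
    D = np.sqrt((diffs**2).sum(axis=-1))
    iu = np.triu_indices(m, k=1)
    pair = D[iu]
    if gram is None:
        gram = X @ X.T
    sign, logdet = np.linalg.slogdet(gram)
    return {
        "mean_pairwise_distance": float(pair.mean()),
        "min_pairwise_distance": float(pair.min()),
        "log_det_gram": float(logdet) if sign > 0 else float("-inf"),
    }
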
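"""Two-stage feature reduction: L1 pre-selection, then ARD ranking.

Evidence maximization with one lengthscale per feature (automatic relevance
determination, ARD) is expensive and non-convex over a hundred-plus
features, so a LASSO path first shrinks the pool to a manageable 20-100
features; the GP marginal likelihood is then maximized over per-feature
lengthscales, and features are ranked by relevance (inverse lengthscale).
The final encoding is the top-k of that ranking (k = 20 by default).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import lasso_path

from .encoding import FeatureMatrix, subset_features
from .gp_model import GPConfig, fit_gp

__all__ = [
    "SelectionResult",
    "lasso_preselect",
    "ard_rank",
    "select_top_k",
    "select_features",
]


@dataclass
class SelectionResult:
    """Outcome of the two-stage reduction."""

    stage1_features: list[str]
    lasso_alpha: float
    ard_ranking: list[str]
    ard_lengthscales: dict[str, float]
    final_features: list[str]
    evidence: float
    n_restarts: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "stage1_features": self.stage1_features,
                    "lasso_alpha": self.lasso_alpha,
                    "ard_ranking": self.ard_ranking,
                    "ard_lengthscales": self.ard_lengthscales,
                    "final_features": self.final_features,
                    "evidence": self.evidence,
                    "n_restarts": self.n_restarts,
                },
                indent=2,
            )
        )


def lasso_preselect(
    fm: FeatureMatrix,
    y: np.ndarray,
    target_range: tuple[int, int] = (20, 100),
    n_alphas: int = 100,
) -> tuple[list[str], float]:
    """Choose features with nonzero LASSO coefficients.

    Fits an L1 path over ``n_alphas`` log-spaced penalties and picks the
    penalty whose nonzero count falls inside ``target_range``, closest to
    the range midpoint.  If no penalty lands in range, the closest count is
    used with a warning.  Returns (feature names, chosen alpha).
    """
    X = fm.X
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] <= 2:
        raise ValueError("need more than 2 rows for the L1 path")
    lo, hi = target_range
    if not 1 <= lo <= hi:
        raise ValueError(f"invalid target range {target_range}")
    yc = y - y.mean()
    if np.allclose(yc, 0.0):
        warnings.warn("response is constant; no features selected")
        return [], float("inf")
    if hi >= X.shape[1]:
        hi = X.shape[1]
    with warnings.catch_warnings():
        # Small penalties on correlated descriptors converge slowly; the
        # selected penalty is never in that regime.
        warnings.simplefilter("ignore", ConvergenceWarning)
        alphas, coefs, _ = lasso_path(X, yc, n_alphas=n_alphas, eps=1e-4, max_iter=3000)
    nnz = (np.abs(coefs) > 1e-10).sum(axis=0)
    midpoint = 0.5 * (lo + hi)
    in_range = np.flatnonzero((nnz >= lo) & (nnz <= hi))
    if in_range.size:
        best = in_range[np.argmin(np.abs(nnz[in_range] - midpoint))]
    else:
        best = int(np.argmin(np.abs(nnz - midpoint)))
        warnings.warn(
            f"no L1 penalty yields {lo}-{hi} features; "
            f"using closest count {nnz[best]}"
        )
    mask = np.abs(coefs[:, best]) > 1e-10
    names = [fm.columns[i] for i in np.flatnonzero(mask)]
    return names, float(alphas[best])


def ard_rank(
    fm: FeatureMatrix,
    y: np.ndarray,
    sigma_log: float,
    n_restarts: int = 5,
    seed: int = 0,
    config: GPConfig | None = None,
) -> tuple[list[str], dict[str, float], float]:
    """Rank features by ARD relevance under evidence maximization.

    Fits a GP with one lengthscale per feature (noise fixed at
    ``sigma_log``) and ranks features by 1/lengthscale descending: a short
    lengthscale means the activity varies quickly along that feature, i.e.
    the feature is relevant.  Returns (ranked names, lengthscales, evidence).
    """
    if config is None:
        config = GPConfig()
    cfg = replace(
        config,
        ard=True,
        sigma_log=sigma_log,
        n_restarts=n_restarts,
        seed=seed,
        blocks=None,
    )
    fit = fit_gp(fm.X, y, cfg)
    ls = np.atleast_1d(fit.lengthscales)
    order = np.lexsort((fm.columns, ls))  # short lengthscale first; names break ties
    ranking = [fm.columns[i] for i in order]
    lengthscales = {fm.columns[i]: float(ls[i]) for i in range(len(fm.columns))}
    return ranking, lengthscales, fit.log_marginal_likelihood


def select_top_k(ranking: Sequence[str], k: int) -> list[str]:
    """First k features of a relevance ranking."""
    if k < 1:
        raise ValueError("k must be >= 1: a model needs at least one feature")
    if k > len(ranking):
        raise ValueError(f"k={k} exceeds the {len(ranking)} ranked features")
    return list(ranking[:k])


def select_features(
    fm: FeatureMatrix,
    y: np.ndarray,
    sigma_log: float,
    k: int = 20,
    target_range: tuple[int, int] = (20, 100),
    n_restarts: int = 5,
    seed: int = 0,
    config: GPConfig | None = None,
) -> SelectionResult:
    """Run the full two-stage pipeline and return a SelectionResult."""
    stage1, alpha = lasso_preselect(fm, y, target_range=target_range)
    if not stage1:
        raise ValueError("L1 pre-selection returned no features")
    fm1 = subset_features(fm, stage1)
    ranking, lengthscales, evidence = ard_rank(
        fm1, y, sigma_log, n_restarts=n_restarts, seed=seed, config=config
    )
    k_eff = min(k, len(ranking))
    final = select_top_k(ranking, k_eff)
    return SelectionResult(
        stage1_features=stage1,
        lasso_alpha=alpha,
        ard_ranking=ranking,
        ard_lengthscales=lengthscales,
        final_features=final,
        evidence=evidence,
        n_restarts=n_restarts,
    )
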
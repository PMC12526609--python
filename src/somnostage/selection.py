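"""Feature selection: mRMR (MIQ criterion) and PCA variance thresholding.

The minimum-redundancy maximum-relevance ranking greedily selects
features: the first pick maximises relevance, the mutual information
I(x, y) with the stage label; each later pick maximises the mutual
information quotient MIQ = V_x / W_x, where V_x = I(x, y) and W_x is the
mean mutual information between the candidate and the features already
selected.  Mutual information is the plug-in estimate (log base 2) on a
joint frequency table after equal-frequency (quantile) discretisation of
continuous inputs — the relevance threshold of 0.01 bits is therefore
relative to this estimator.  Retained features are then decorrelated by
PCA on z-scored columns, the number of components chosen as the smallest
k whose cumulative explained variance reaches a threshold (94% or 98%),
and the principal-component scores can be re-ranked with the same mRMR
machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.metrics import mutual_info_score

__all__ = [
    "MiConfig",
    "MrmrRanking",
    "PcaModel",
    "mutual_information",
    "mrmr_rank",
    "redundancy_batch",
    "select_by_relevance_threshold",
    "pca_fit",
    "pca_transform",
    "select_pcs_by_cumulative_variance",
    "rank_pcs_mrmr",
]

_LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class MiConfig:
    """Mutual-information estimator settings."""

    bins: int = 10
    strategy: str = "quantile"

    def __post_init__(self) -> None:
        if self.bins < 2:
            raise ValueError("bins must be >= 2")
        if self.strategy not in ("quantile", "uniform"):
            raise ValueError(f"unknown strategy {self.strategy!r}")


@dataclass
class MrmrRanking:
    """Full greedy mRMR trace.

    ``order`` lists feature names from first to last pick; ``scores[i]``
    is the criterion value at the i-th pick (relevance for the first,
    MIQ thereafter); ``relevance`` maps every feature to V_x = I(x, y);
    ``redundancy[i]`` is W_x of the i-th pick at selection time.
    """

    order: list
    scores: list
    relevance: dict
    redundancy: list

    def __len__(self) -> int:
        return len(self.order)


@dataclass
class PcaModel:
    """Fitted PCA with the preprocessing needed to reuse it."""

    mean: np.ndarray
    scale: np.ndarray
    components: np.ndarray          # (k, n_features) orthonormal rows
    explained_pct: np.ndarray       # percent, sums to ~100
    feature_names: list = field(default_factory=list)

    @property
    def cumulative_pct(self) -> np.ndarray:
        return np.cumsum(self.explained_pct)


def _discretize(a: np.ndarray, cfg: MiConfig) -> np.ndarray:
    a = np.asarray(a)
    if a.dtype.kind in "OUS" or a.dtype.kind == "b":
        _, codes = np.unique(a, return_inverse=True)
        return codes
    a = a.astype(float)
    uniq = np.unique(a)
    if uniq.size <= cfg.bins:
        return np.searchsorted(uniq, a)
    if cfg.strategy == "quantile":
        edges = np.quantile(a, np.linspace(0, 1, cfg.bins + 1)[1:-1])
    else:
        edges = np.linspace(a.min(), a.max(), cfg.bins + 1)[1:-1]
    return np.digitize(a, np.unique(edges))


def mutual_information(a, b, cfg: MiConfig | None = None) -> float:
    """Plug-in mutual information in bits after discretisation.

    Continuous inputs are quantile-discretised into ``cfg.bins`` bins;
    categorical inputs (labels) are used as-is.  Non-negative; I(a, a)
    equals the entropy of the discretised variable.
    """
    cfg = cfg or MiConfig()
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D of equal length")
    if a.size < 2:
        raise ValueError("need at least 2 observations")
    return float(mutual_info_score(_discretize(a, cfg), _discretize(b, cfg)) / _LN2)


def mrmr_rank(X, y, cfg: MiConfig | None = None, feature_names=None) -> MrmrRanking:
    """Greedy mRMR ranking of all columns of X against labels y.

    First pick maximises relevance I(x, y); each later pick maximises
    MIQ = V_x / W_x with W_x the mean MI against the already-selected
    set.  Ties break by column order, so the trace is deterministic.
    """
    cfg = cfg or MiConfig()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("X must be 2-D with at least one column")
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("labels must not be constant")
    n_feat = X.shape[1]
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(n_feat)]
    feature_names = list(feature_names)

    disc = [_discretize(X[:, j], cfg) for j in range(n_feat)]
    ydisc = _discretize(y, cfg)
    rel = np.array([
        mutual_info_score(disc[j], ydisc) / _LN2 for j in range(n_feat)
    ])

    selected: list[int] = []
    scores: list[float] = []
    redundancies: list[float] = []
    # cached MI between each candidate and each selected feature
    mi_cache = np.zeros((n_feat, 0))
    remaining = list(range(n_feat))

    first = int(np.argmax(rel))
    selected.append(first)
    scores.append(float(rel[first]))
    redundancies.append(0.0)
    remaining.remove(first)

    while remaining:
        new_col = np.array([
            mutual_info_score(disc[j], disc[selected[-1]]) / _LN2
            for j in range(n_feat)
        ])[:, None]
        mi_cache = np.hstack([mi_cache, new_col])
        w = mi_cache[remaining, :].mean(axis=1)
        v = rel[remaining]
        # zero redundancy with positive relevance is an infinitely good pick
        miq = np.where(w > 0, v / np.maximum(w, 1e-300), np.where(v > 0, np.inf, 0.0))
        best = int(np.argmax(miq))
        pick = remaining[best]
        selected.append(pick)
        scores.append(float(miq[best]))
        redundancies.append(float(w[best]))
        remaining.remove(pick)

    return MrmrRanking(
        order=[feature_names[j] for j in selected],
        scores=scores,
        relevance={feature_names[j]: float(rel[j]) for j in range(n_feat)},
        redundancy=redundancies,
    )


def redundancy_batch(X, cfg: MiConfig | None = None) -> float:
    """Batch redundancy of a feature set: mean pairwise MI including self-terms,
    W_S = (1/|S|²) Σ_{i,j} I(x_i, x_j).  Diagnostic companion to the greedy W_x."""
    cfg = cfg or MiConfig()
    X = np.asarray(X, dtype=float)
    k = X.shape[1]
    disc = [_discretize(X[:, j], cfg) for j in range(k)]
    total = 0.0
    for i in range(k):
        for j in range(k):
            total += mutual_info_score(disc[i], disc[j]) / _LN2
    return total / k ** 2


def select_by_relevance_threshold(
    ranking: MrmrRanking, threshold: float = 0.01
) -> list:
    """Features whose reported mRMR score ≥ threshold, in rank order."""
    if len(ranking) == 0:
        raise ValueError("empty ranking")
    kept = [n for n, s in zip(ranking.order, ranking.scores) if s >= threshold]
    if not kept:
        warnings.warn(
            f"no feature reaches the relevance threshold {threshold}", stacklevel=2
        )
    return kept


def pca_fit(X, standardize: bool = True, feature_names=None) -> PcaModel:
    """PCA on (optionally z-scored) columns, components by decreasing variance."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be 2-D with more than one row")
    if not np.all(np.isfinite(X)):
        bad = np.where(~np.isfinite(X).all(axis=0))[0]
        names = feature_names or [f"f{i}" for i in range(X.shape[1])]
        raise ValueError(f"non-finite entries in columns: {[names[j] for j in bad]}")
    mean = X.mean(axis=0)
    if standardize:
        scale = X.std(axis=0, ddof=1)
        scale[scale == 0] = 1.0
    else:
        scale = np.ones(X.shape[1])
    Z = (X - mean) / scale
    p = PCA(svd_solver="full")
    p.fit(Z)
    return PcaModel(
        mean=mean,
        scale=scale,
        components=p.components_,
        explained_pct=p.explained_variance_ratio_ * 100.0,
        feature_names=list(feature_names) if feature_names is not None else [],
    )


def pca_transform(model: PcaModel, X, k: int | None = None) -> np.ndarray:
    """Project rows of X onto the first k components."""
    X = np.asarray(X, dtype=float)
    Z = (X - model.mean) / model.scale
    comps = model.components if k is None else model.components[:k]
    return Z @ comps.T


def select_pcs_by_cumulative_variance(
    model_or_pcts, threshold_pct: float
) -> int:
    """Smallest k whose cumulative explained variance reaches the threshold."""
    if not (0 < threshold_pct <= 100):
        raise ValueError("threshold must be in (0, 100]")
    if isinstance(model_or_pcts, PcaModel):
        pct = model_or_pcts.explained_pct
    else:
        pct = np.asarray(model_or_pcts, dtype=float)
    cum = np.cumsum(pct)
    hit = np.nonzero(cum >= threshold_pct - 1e-9)[0]
    if hit.size == 0:
        return int(pct.size)
    return int(hit[0]) + 1


def rank_pcs_mrmr(scores, y, cfg: MiConfig | None = None) -> MrmrRanking:
    """mRMR ranking of principal-component score columns (delegates)."""
    names = [f"PC{i + 1}" for i in range(np.asarray(scores).shape[1])]
    return mrmr_rank(scores, y, cfg, feature_names=names)
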
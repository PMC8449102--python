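"""Zero-shot decoding of word identity from evoked responses.

A linear ridge regression maps brain features (channels x time-bin values)
onto distributional word-embedding vectors. Evaluation is all-pairs
leave-two-out: for every unordered pair of words the mapping is refit on the
remaining n-2 items, the two held-out responses are projected into embedding
space, and the pair is scored correct when matching each prediction to its
own word gives a smaller summed cosine distance than the swapped assignment.
Mean accuracy over all n(n-1)/2 pairs runs from 50% (chance) to 100%.

Implementation note: with the ridge solved in closed form, each held-out
prediction is a fixed linear functional of the training targets
(``pred_i = h_i @ Y_train``). The per-pair "hat" vectors ``h_i`` depend only
on the features and alpha, so label permutations (chance calibration) reuse
them and cost one matrix product per permutation instead of refitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .preprocess import BinnedEpochs, FeatureMatrix, window_features, zscore_columns
from .semantic import EmbeddingTable

__all__ = [
    "RidgeMapping",
    "DecodingResult",
    "AccuracyTimecourse",
    "PermutationCalibration",
    "fit_ridge",
    "cosine_distance",
    "match_pair",
    "leave2out_accuracy",
    "timeresolved_accuracy",
    "permutation_calibration",
    "within_category_accuracy",
]


def _as_features(X) -> np.ndarray:
    if isinstance(X, FeatureMatrix):
        return X.values
    return np.asarray(X, dtype=float)


def _as_targets(Y) -> np.ndarray:
    if isinstance(Y, EmbeddingTable):
        return Y.vectors
    return np.asarray(Y, dtype=float)


@dataclass
class RidgeMapping:
    """A fitted linear map from brain features to embedding dimensions."""

    weights: np.ndarray  # (n_features, dim)
    intercepts: np.ndarray  # (dim,)
    alpha: float

    def predict(self, X) -> np.ndarray:
        return _as_features(X) @ self.weights + self.intercepts


@dataclass
class DecodingResult:
    """Leave-two-out decoding outcome.

    ``pair_scores`` is symmetric with NaN diagonal; entries are 1 (pair
    correctly matched), 0 (swapped) or 0.5 (exact tie). ``mean_accuracy``
    is the mean over the upper triangle. ``per_item_cosine`` is the mean
    cosine distance between an item's predicted and true vector across all
    pairs that held it out.
    """

    pair_scores: np.ndarray
    mean_accuracy: float
    per_item_cosine: np.ndarray
    items: list[str] | None = None


@dataclass
class AccuracyTimecourse:
    """Decoding accuracy per sliding-window position (times at window centers, ms)."""

    accuracies: np.ndarray
    times_ms: np.ndarray


@dataclass
class PermutationCalibration:
    """Null accuracies from label permutation, with the chance threshold."""

    null_accuracies: np.ndarray
    threshold: float  # empirical 95th percentile of the null
    p_value: float
    observed: float


def _spectral_filter(s: np.ndarray, alpha: float) -> np.ndarray:
    """Ridge filter factors s/(s^2 + alpha); pseudoinverse when alpha == 0."""
    if alpha == 0:
        tol = s.max(initial=0.0) * max(s.shape[0], 1) * np.finfo(float).eps
        out = np.zeros_like(s)
        np.divide(1.0, s, out=out, where=s > tol)
        return out
    return s / (s**2 + alpha)


def fit_ridge(X, Y, alpha: float = 1.0) -> RidgeMapping:
    """Fit a ridge regression from features to target dimensions.

    Coefficients minimize ``||y - Xw||^2 + alpha ||w||^2`` per target
    dimension, computed in closed form via SVD of the centered feature
    matrix; ``alpha=0`` gives the minimum-norm least-squares solution.
    The intercept is fit on centered data and retained.
    """
    if alpha < 0:
        raise ValueError(f"alpha must be >= 0, got {alpha}")
    X, Y = _as_features(X), _as_targets(Y)
    if X.shape[0] != Y.shape[0]:
        raise ValueError(f"{X.shape[0]} feature rows vs {Y.shape[0]} target rows")
    xm, ym = X.mean(axis=0), Y.mean(axis=0)
    U, s, Vt = np.linalg.svd(X - xm, full_matrices=False)
    f = _spectral_filter(s, alpha)
    W = Vt.T @ (f[:, None] * (U.T @ (Y - ym)))
    return RidgeMapping(weights=W, intercepts=ym - xm @ W, alpha=alpha)


def cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    """``1 - cos(u, v)``, in [0, 2]; raises on zero-norm input."""
    u, v = np.asarray(u, dtype=float), np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine distance undefined for zero-norm vector")
    return float(1.0 - np.dot(u, v) / (nu * nv))


def match_pair(pred_i, pred_j, true_i, true_j) -> float:
    """Score a held-out pair: 1 if the correct assignment of the two
    predictions to the two words has the smaller summed cosine distance,
    0 if the swapped assignment does, 0.5 on an exact tie."""
    correct = cosine_distance(pred_i, true_i) + cosine_distance(pred_j, true_j)
    swapped = cosine_distance(pred_i, true_j) + cosine_distance(pred_j, true_i)
    if correct < swapped:
        return 1.0
    if correct > swapped:
        return 0.0
    return 0.5


_GCV_GRID = np.logspace(-3, 3, 13)


def _gcv_alpha(U: np.ndarray, s: np.ndarray, Yc: np.ndarray,
               grid: np.ndarray = _GCV_GRID) -> float:
    """Pick the ridge penalty minimizing generalized cross-validation error.

    Uses the SVD of the centered training features: with hat-matrix
    eigenvalues s^2/(s^2 + alpha), GCV(alpha) = m ||r||^2 / (m - edf)^2
    summed over target dimensions.
    """
    m = Yc.shape[0]
    UtY = U.T @ Yc
    best_alpha, best_score = float(grid[0]), np.inf
    for alpha in grid:
        shrink = s**2 / (s**2 + alpha)
        edf = shrink.sum() + 1.0  # +1 for the intercept
        fitted = U @ (shrink[:, None] * UtY)
        rss = float(((Yc - fitted) ** 2).sum())
        score = m * rss / max(m - edf, 1e-12) ** 2
        if score < best_score:
            best_alpha, best_score = float(alpha), score
    return best_alpha


class _PairHats:
    """Per-pair linear functionals mapping training targets to held-out predictions.

    ``alpha`` may be the string ``"gcv"``, in which case the penalty is
    selected per pair by generalized cross-validation on that pair's
    training fold (``Y`` is then required).
    """

    def __init__(self, X: np.ndarray, alpha, fold_safe_scaling: bool = False,
                 Y: np.ndarray | None = None):
        n = X.shape[0]
        if n < 4:
            raise ValueError(f"leave-two-out needs >= 4 items, got {n}")
        use_gcv = isinstance(alpha, str)
        if use_gcv:
            if alpha != "gcv":
                raise ValueError(f"alpha must be a number or 'gcv', got {alpha!r}")
            if Y is None:
                raise ValueError("alpha='gcv' requires the target matrix")
        elif alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {alpha}")
        self.n = n
        self.pairs = np.array(list(combinations(range(n), 2)))
        n_pairs = len(self.pairs)
        self.H_i = np.zeros((n_pairs, n))
        self.H_j = np.zeros((n_pairs, n))
        self.alphas = np.empty(n_pairs)
        m = n - 2
        for k, (i, j) in enumerate(self.pairs):
            idx = np.delete(np.arange(n), [i, j])
            Xt = X[idx]
            xi, xj = X[i], X[j]
            if fold_safe_scaling:
                mu, sd = Xt.mean(axis=0), Xt.std(axis=0)
                sd = np.where(sd > 0, sd, 1.0)
                Xt = (Xt - mu) / sd
                xi, xj = (xi - mu) / sd, (xj - mu) / sd
            xm = Xt.mean(axis=0)
            U, s, Vt = np.linalg.svd(Xt - xm, full_matrices=False)
            if use_gcv:
                Yt = Y[idx]
                pair_alpha = _gcv_alpha(U, s, Yt - Yt.mean(axis=0))
            else:
                pair_alpha = alpha
            self.alphas[k] = pair_alpha
            f = _spectral_filter(s, pair_alpha)
            gi = U @ (f * (Vt @ (xi - xm)))
            gj = U @ (f * (Vt @ (xj - xm)))
            self.H_i[k, idx] = gi - gi.sum() / m + 1.0 / m
            self.H_j[k, idx] = gj - gj.sum() / m + 1.0 / m

    def predictions(self, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return self.H_i @ Y, self.H_j @ Y


def _row_cosine_distance(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    na = np.linalg.norm(A, axis=1)
    nb = np.linalg.norm(B, axis=1)
    if np.any(na == 0) or np.any(nb == 0):
        raise ValueError("cosine distance undefined for zero-norm vector")
    return 1.0 - np.einsum("ij,ij->i", A, B) / (na * nb)


def _score_pairs(
    hats: _PairHats, Y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pair scores plus the per-pair correct-assignment cosine distances."""
    Pi, Pj = hats.predictions(Y)
    ii, jj = hats.pairs[:, 0], hats.pairs[:, 1]
    d_ii = _row_cosine_distance(Pi, Y[ii])
    d_jj = _row_cosine_distance(Pj, Y[jj])
    d_ij = _row_cosine_distance(Pi, Y[jj])
    d_ji = _row_cosine_distance(Pj, Y[ii])
    correct = d_ii + d_jj
    swapped = d_ij + d_ji
    scores = np.where(correct < swapped, 1.0, np.where(correct > swapped, 0.0, 0.5))
    return scores, d_ii, d_jj


def _null_accuracies(
    hats: _PairHats, Y: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    null = np.empty(n_perm)
    for p in range(n_perm):
        perm = rng.permutation(hats.n)
        scores, _, _ = _score_pairs(hats, Y[perm])
        null[p] = scores.mean()
    return null


def _build_result(
    hats: _PairHats, Y: np.ndarray, items: list[str] | None
) -> DecodingResult:
    scores, d_ii, d_jj = _score_pairs(hats, Y)
    n = hats.n
    mat = np.full((n, n), np.nan)
    ii, jj = hats.pairs[:, 0], hats.pairs[:, 1]
    mat[ii, jj] = scores
    mat[jj, ii] = scores
    cos_sum = np.zeros(n)
    np.add.at(cos_sum, ii, d_ii)
    np.add.at(cos_sum, jj, d_jj)
    return DecodingResult(
        pair_scores=mat,
        mean_accuracy=float(scores.mean()),
        per_item_cosine=cos_sum / (n - 1),
        items=items,
    )


def leave2out_accuracy(
    X, Y, alpha: float | str = 1.0, fold_safe_scaling: bool = False
) -> DecodingResult:
    """All-pairs leave-two-out zero-shot evaluation.

    For each unordered item pair the ridge mapping is refit on the other
    n-2 items and the held-out predictions are matched to the two candidate
    embedding vectors by cosine distance. ``alpha`` is the fixed ridge
    penalty, or ``"gcv"`` to select it per pair by generalized
    cross-validation inside the training fold. ``fold_safe_scaling``
    re-derives column standardization inside each training fold instead of
    relying on whole-set scaling.
    """
    Xv, Yv = _as_features(X), _as_targets(Y)
    if Xv.shape[0] != Yv.shape[0]:
        raise ValueError(f"{Xv.shape[0]} feature rows vs {Yv.shape[0]} target rows")
    items = Y.words if isinstance(Y, EmbeddingTable) else None
    hats = _PairHats(Xv, alpha, fold_safe_scaling, Y=Yv)
    return _build_result(hats, Yv, items)


def timeresolved_accuracy(
    binned: BinnedEpochs,
    Y,
    window_size: int = 5,
    alpha: float = 1.0,
    standardize: bool = True,
) -> AccuracyTimecourse:
    """Leave-two-out accuracy in a sliding window over time bins (stride 1).

    Each window's channels x bins values are concatenated, column z-scored,
    and decoded; the reported time of a window is the mean of its bin
    centers. With 40 bins and a 5-bin window there are 36 positions.
    """
    n_bins = binned.n_bins
    if window_size > n_bins:
        raise ValueError(f"window_size {window_size} exceeds {n_bins} bins")
    Yv = _as_targets(Y)
    n_pos = n_bins - window_size + 1
    acc = np.empty(n_pos)
    times = np.empty(n_pos)
    for start in range(n_pos):
        feats = window_features(binned, window_size=window_size, start_bin=start)
        if standardize:
            feats = zscore_columns(feats)
        acc[start] = leave2out_accuracy(feats.values, Yv, alpha=alpha).mean_accuracy
        times[start] = binned.bin_centers[start : start + window_size].mean()
    return AccuracyTimecourse(accuracies=acc, times_ms=times)


def permutation_calibration(
    X,
    Y,
    n_perm: int = 1000,
    alpha: float = 1.0,
    seed: int | None = None,
    observed: float | None = None,
) -> PermutationCalibration:
    """Chance-level calibration by permuting the word-label assignment.

    Each permutation shuffles the row order of the targets relative to the
    features and recomputes the full leave-two-out mean accuracy. The
    p-value uses the add-one estimator ``(1 + #{null >= observed}) /
    (1 + n_perm)`` and the threshold is the empirical 95th percentile of
    the null accuracies.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if isinstance(alpha, str):
        raise ValueError(
            "permutation calibration needs a fixed numeric alpha: per-fold "
            "GCV would make the pair fits depend on the permuted labels"
        )
    Xv, Yv = _as_features(X), _as_targets(Y)
    hats = _PairHats(Xv, alpha)
    if observed is None:
        observed = float(_score_pairs(hats, Yv)[0].mean())
    rng = np.random.default_rng(seed)
    null = _null_accuracies(hats, Yv, n_perm, rng)
    p = (1.0 + np.count_nonzero(null >= observed)) / (1.0 + n_perm)
    return PermutationCalibration(
        null_accuracies=null,
        threshold=float(np.quantile(null, 0.95)),
        p_value=float(p),
        observed=float(observed),
    )


def within_category_accuracy(
    X, Y, categories: list[str], alpha: float = 1.0
) -> dict[str, DecodingResult]:
    """Leave-two-out evaluation restricted to within-category pairs.

    Training still uses all remaining n-2 items regardless of category;
    only the scored pairs are restricted. Every category needs >= 4 items.
    """
    Xv, Yv = _as_features(X), _as_targets(Y)
    categories = list(categories)
    if len(categories) != Xv.shape[0]:
        raise ValueError("one category label per item required")
    labels = sorted(set(categories))
    counts = {c: categories.count(c) for c in labels}
    small = [c for c, k in counts.items() if k < 4]
    if small:
        raise ValueError(f"categories with fewer than 4 items: {small}")
    items = Y.words if isinstance(Y, EmbeddingTable) else None
    hats = _PairHats(Xv, alpha)
    scores, d_ii, d_jj = _score_pairs(hats, Yv)
    ii, jj = hats.pairs[:, 0], hats.pairs[:, 1]
    cats = np.array(categories)
    out: dict[str, DecodingResult] = {}
    for cat in labels:
        members = np.flatnonzero(cats == cat)
        pos = {v: k for k, v in enumerate(members)}
        keep = np.flatnonzero((cats[ii] == cat) & (cats[jj] == cat))
        k = members.size
        mat = np.full((k, k), np.nan)
        cos_sum = np.zeros(k)
        for idx in keep:
            a, b = pos[ii[idx]], pos[jj[idx]]
            mat[a, b] = mat[b, a] = scores[idx]
            cos_sum[a] += d_ii[idx]
            cos_sum[b] += d_jj[idx]
        out[cat] = DecodingResult(
            pair_scores=mat,
            mean_accuracy=float(scores[keep].mean()),
            per_item_cosine=cos_sum / (k - 1),
            items=[items[m] for m in members] if items else None,
        )
    return out
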
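"""Population structure and decoding.

Glomeruli are grouped by the shape of their GI-versus-intermittency
profiles: the mean GI per intermittency bin of every glomerulus is
correlated with every other's, and agglomerative clustering on the
correlation distance d = 1 - r is cut at height 0.74. Trial identity
(CS+ vs CS-) is decoded from single-trial GI vectors with a threefold
cross-validated linear discriminant — trained on one third of trials with
stratified sampling over intermittency values, tested on the remaining
two thirds — repeated 20 times.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

log = logging.getLogger(__name__)

CLUSTER_CUTOFF = 0.74
GI_PROFILE_BINS = tuple(np.round(np.arange(0.1, 0.81, 0.1), 2))
N_FOLDS = 3
N_REPEATS = 20


# ---------------------------------------------------------------------------
# profiles and clustering


def gi_profiles(gi: np.ndarray, gamma: np.ndarray,
                bins: Sequence[float] = GI_PROFILE_BINS,
                tol: float = 0.05) -> np.ndarray:
    """Mean GI per intermittency bin for every glomerulus.

    ``gi`` is (n_trials, n_glomeruli); trials are assigned to the nearest
    bin within ``tol``. Bins with no trials give NaN columns.
    """
    gi = np.asarray(gi, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    bins = np.asarray(bins, dtype=float)
    d = np.abs(gamma[:, None] - bins[None, :])
    idx = d.argmin(axis=1)
    idx[d.min(axis=1) > tol + 1e-12] = -1
    out = np.full((gi.shape[1], bins.size), np.nan)
    for b in range(bins.size):
        mask = idx == b
        if np.any(mask):
            out[:, b] = np.nanmean(gi[mask], axis=0)
    return out


def interglomerular_corr(profiles: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r between every pair of GI profiles.

    Returns (corr, valid): zero-variance or <2-finite-bin profiles are
    flagged invalid and their rows/columns set to NaN; valid diagonal
    entries are exactly 1.
    """
    profiles = np.asarray(profiles, dtype=float)
    if profiles.shape[0] < 2:
        raise ValueError("need at least two profiles")
    finite_cols = np.all(np.isfinite(profiles), axis=0)
    p = profiles[:, finite_cols]
    if p.shape[1] < 2:
        raise ValueError("need >=2 intermittency bins with data")
    valid = p.std(axis=1) > 0
    corr = np.full((p.shape[0], p.shape[0]), np.nan)
    if np.any(valid):
        sub = np.corrcoef(p[valid])
        corr[np.ix_(valid, valid)] = np.atleast_2d(sub)
    return corr, valid


@dataclass
class ClusterAssignment:
    labels: np.ndarray           # 1-based cluster id per (valid) glomerulus
    linkage_matrix: np.ndarray
    valid: np.ndarray            # mask of glomeruli that entered clustering
    cutoff: float

    @property
    def n_clusters(self) -> int:
        return int(np.unique(self.labels[self.labels > 0]).size)


def hierarchical_cluster(corr: np.ndarray, cutoff: float = CLUSTER_CUTOFF,
                         method: str = "single") -> ClusterAssignment:
    """Agglomerative clustering on correlation distance d = 1 - r, cut at
    ``cutoff``. ``method='single'`` (MATLAB's linkage() default, kept for
    comparability) is the default; 'average' is available by argument.
    Invalid (NaN) rows receive label 0."""
    corr = np.asarray(corr, dtype=float)
    valid = np.all(np.isfinite(corr), axis=1)
    sub = corr[np.ix_(valid, valid)]
    n = sub.shape[0]
    labels = np.zeros(corr.shape[0], dtype=int)
    if n == 0:
        raise ValueError("no valid glomeruli to cluster")
    if n == 1:
        labels[valid] = 1
        return ClusterAssignment(labels=labels, linkage_matrix=np.empty((0, 4)),
                                 valid=valid, cutoff=cutoff)
    d = 1.0 - sub
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2, 0.0, None)
    z = linkage(squareform(d, checks=False), method=method)
    labels[valid] = fcluster(z, t=cutoff, criterion="distance")
    return ClusterAssignment(labels=labels, linkage_matrix=z, valid=valid,
                             cutoff=cutoff)


# ---------------------------------------------------------------------------
# linear discriminant decoding


class LinearDiscriminant:
    """Class-means / pooled-covariance linear discriminant, equal priors.

    A ridge term lambda = 1e-6 * trace(S)/d is added when the pooled
    covariance is ill-conditioned. With zero features the classifier
    degenerates to the (equal-prior) majority vote of the training set.
    """

    def __init__(self, ridge_rel: float = 1e-6):
        self.ridge_rel = ridge_rel
        self.classes_: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LinearDiscriminant":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("need at least two classes")
        n, d = X.shape
        self._d = d
        if d == 0:
            counts = [np.count_nonzero(y == c) for c in self.classes_]
            self._majority = self.classes_[int(np.argmax(counts))]
            return self
        means = np.stack([X[y == c].mean(axis=0) for c in self.classes_])
        resid = X - means[np.searchsorted(self.classes_, y)]
        dof = max(n - self.classes_.size, 1)
        cov = resid.T @ resid / dof
        if dof < d or not np.isfinite(np.linalg.cond(cov)) or \
                np.linalg.cond(cov) > 1e8 or np.trace(cov) == 0:
            # rank-deficient or ill-conditioned pooled covariance (e.g.
            # fewer training trials than glomeruli): ridge the retained
            # spectrum and truncate the null space — inverting ridged
            # near-null directions would amplify noise by 1/lambda
            warnings.warn("ill-conditioned pooled covariance: regularized "
                          "pseudo-inverse engaged", stacklevel=2)
            lam = self.ridge_rel * np.trace(cov) / d
            evals, evecs = np.linalg.eigh(cov)
            keep = evals > max(1e-10 * evals.max(initial=0.0), 0.0)
            if not np.any(keep):
                # zero pooled covariance (e.g. one training trial per
                # class): degenerate to the nearest-mean classifier
                self._icov = np.eye(d)
            else:
                inv_vals = np.where(keep, 1.0 / (evals + lam), 0.0)
                self._icov = (evecs * inv_vals) @ evecs.T
        else:
            self._icov = np.linalg.inv(cov)
        self._means = means
        return self

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        w = self._icov @ self._means.T                       # (d, k)
        b = -0.5 * np.einsum("kd,dk->k", self._means, w)     # equal priors
        return X @ w + b

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self._d == 0:
            return np.full(X.shape[0], self._majority)
        scores = self.decision_scores(X)
        return self.classes_[scores.argmax(axis=1)]


@dataclass
class ClassifierResult:
    accuracy: np.ndarray          # (n_repeats, n_folds)
    tpr: np.ndarray
    n_glomeruli: int
    mean_accuracy: float = field(init=False)
    se_accuracy: float = field(init=False)
    mean_tpr: float = field(init=False)
    se_tpr: float = field(init=False)

    def __post_init__(self) -> None:
        flat = self.accuracy.ravel()
        self.mean_accuracy = float(np.nanmean(flat))
        self.se_accuracy = float(np.nanstd(flat, ddof=1) / np.sqrt(flat.size))
        tf = self.tpr.ravel()
        self.mean_tpr = float(np.nanmean(tf))
        self.se_tpr = float(np.nanstd(tf, ddof=1) / np.sqrt(tf.size))


def _stratified_folds(strata: np.ndarray, n_folds: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Fold index per trial, stratified so each stratum spreads evenly."""
    fold = np.empty(strata.size, dtype=int)
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        idx = rng.permutation(idx)
        fold[idx] = np.arange(idx.size) % n_folds
    return fold


def crossval_classify(X: np.ndarray, y: np.ndarray,
                      strata: Optional[np.ndarray] = None,
                      n_folds: int = N_FOLDS, n_repeats: int = N_REPEATS,
                      seed: int = 0,
                      positive_label="CSplus") -> ClassifierResult:
    """Repeated threefold cross-validated linear discriminant decoding.

    Per repeat, trials are partitioned into ``n_folds`` groups stratified
    by ``strata`` (intermittency values when given, else class labels);
    the model is trained on one group and tested on the remaining ones —
    train on 1/3, test on 2/3 — for every group in turn. Accuracy is
    #correct / #test trials and the true-positive rate is
    #correctly-predicted-positive / #positive test trials.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    if X.shape[0] != y.size:
        raise ValueError("X and y disagree on trial count")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least two classes")
    if min(np.count_nonzero(y == c) for c in classes) < n_folds:
        raise ValueError("each class needs at least n_folds trials")
    if strata is None:
        strata = y
    strata = np.asarray(strata)
    acc = np.full((n_repeats, n_folds), np.nan)
    tpr = np.full((n_repeats, n_folds), np.nan)
    for rep in range(n_repeats):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), rep]))
        fold = None
        for attempt in range(10):
            cand = _stratified_folds(strata, n_folds, rng)
            ok = all(np.unique(y[cand == f]).size == classes.size
                     for f in range(n_folds))
            if ok:
                fold = cand
                break
            log.info("fold redraw: a class was absent from a training fold")
        if fold is None:
            fold = cand  # proceed with the last draw; folds lacking a
            # class are skipped below
        for f in range(n_folds):
            train = fold == f
            test = ~train
            if np.unique(y[train]).size < classes.size:
                continue
            model = LinearDiscriminant().fit(X[train], y[train])
            pred = model.predict(X[test])
            acc[rep, f] = np.mean(pred == y[test])
            pos = y[test] == positive_label
            if np.any(pos):
                tpr[rep, f] = np.mean(pred[pos] == positive_label)
    return ClassifierResult(accuracy=acc, tpr=tpr, n_glomeruli=X.shape[1])


def glomerulus_curves(X: np.ndarray, y: np.ndarray,
                      n_grid: Sequence[int],
                      ordering: str = "random",
                      slopes: Optional[np.ndarray] = None,
                      strata: Optional[np.ndarray] = None,
                      n_repeats: int = N_REPEATS, seed: int = 0,
                      ) -> dict[int, ClassifierResult]:
    """Decoding accuracy as a function of the number of glomeruli used.

    Orderings: 'random' draws a fresh random subset per count;
    'top_slope' / 'bottom_slope' take the glomeruli with the largest /
    smallest |GI slope| (requires ``slopes``). Counts above the pool size
    are truncated with a warning.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    pool = X.shape[1]
    rng = np.random.default_rng(seed)
    if ordering in ("top_slope", "bottom_slope"):
        if slopes is None:
            raise ValueError(f"ordering {ordering!r} requires GI slopes")
        order = np.argsort(np.abs(np.asarray(slopes)))
        if ordering == "top_slope":
            order = order[::-1]
    elif ordering != "random":
        raise ValueError(f"unknown ordering {ordering!r}")
    out: dict[int, ClassifierResult] = {}
    for n_req in n_grid:
        n = n_req
        if n > pool:
            warnings.warn(f"requested {n} glomeruli, pool has {pool}: truncating",
                          stacklevel=2)
            n = pool
        if ordering == "random":
            cols = rng.choice(pool, size=n, replace=False) if n else np.empty(0, int)
        else:
            cols = order[:n]
        out[n_req] = crossval_classify(X[:, sorted(cols)], y, strata=strata,
                                       n_repeats=n_repeats, seed=seed + 1000 + n)
    return out
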
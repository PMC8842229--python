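"""Feature-selection combinations: supervised ranking then redundancy removal.

A combination pairs one of four supervised rankers — Fisher score, ReliefF,
chi-square score, mutual information — with one of six unsupervised scorers
— variance score, Laplacian score, SPEC, MCFS, NDFS, UDFS — giving 24
ordered pairs.  Applied to training data only: the supervised ranker keeps
the top ``k_sup`` outcome-relevant features, then the unsupervised scorer
re-ranks those survivors (structure preservation / redundancy) and keeps
the top ``k_final``.

The unsupervised spectral methods (Laplacian score, SPEC, MCFS, NDFS,
UDFS) are compact implementations of the standard algorithms on a k-NN
heat-kernel sample graph; their fixed internal settings (k = 5 neighbours,
2 spectral clusters, 20 multiplicative-update iterations) are documented
here as the catalogue of record.

Selection stability across resampled training sets is the mean pairwise
Jaccard index; the AUC-vs-stability trade-off over the 24 combinations is
resolved by a decision graph: min-max normalise both axes and pick the
combination with the largest Euclidean norm.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.linalg import eigh
from sklearn.feature_selection import chi2 as sk_chi2
from sklearn.feature_selection import mutual_info_classif

log = logging.getLogger(__name__)

SUPERVISED_METHODS = ("fisher", "relieff", "chi2", "mutual_info")
UNSUPERVISED_METHODS = ("variance", "laplacian", "spec", "mcfs", "ndfs", "udfs")


@dataclass(frozen=True)
class FSCombination:
    supervised: str
    unsupervised: str

    def __post_init__(self) -> None:
        if self.supervised not in SUPERVISED_METHODS:
            raise ValueError(f"unknown supervised method {self.supervised!r}")
        if self.unsupervised not in UNSUPERVISED_METHODS:
            raise ValueError(f"unknown unsupervised method {self.unsupervised!r}")

    def __str__(self) -> str:
        return f"{self.supervised}+{self.unsupervised}"


def enumerate_combinations() -> List[FSCombination]:
    """All 24 supervised x unsupervised ordered pairs."""
    return [
        FSCombination(s, u)
        for s, u in itertools.product(SUPERVISED_METHODS, UNSUPERVISED_METHODS)
    ]


# ---------------------------------------------------------------------------
# supervised rankers: higher score = more outcome-relevant


def fisher_score(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Between-class over within-class variance ratio per feature."""
    scores = np.zeros(X.shape[1])
    mu = X.mean(axis=0)
    num = np.zeros(X.shape[1])
    den = np.zeros(X.shape[1])
    for c in np.unique(y):
        Xc = X[y == c]
        nc = len(Xc)
        num += nc * (Xc.mean(axis=0) - mu) ** 2
        den += nc * Xc.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(den > 0, num / den, np.inf * (num > 0))
    return np.nan_to_num(scores, nan=0.0, posinf=np.finfo(float).max)


def relieff_score(
    X: np.ndarray, y: np.ndarray, n_neighbors: int = 10
) -> np.ndarray:
    """ReliefF weights: margin between nearest misses and nearest hits.

    Features are min-max scaled internally; all samples are used as
    anchors (deterministic).
    """
    rng_span = X.max(axis=0) - X.min(axis=0)
    span = np.where(rng_span > 0, rng_span, 1.0)
    Z = (X - X.min(axis=0)) / span
    n = len(Z)
    d2 = np.sum((Z[:, None, :] - Z[None, :, :]) ** 2, axis=-1)
    np.fill_diagonal(d2, np.inf)
    w = np.zeros(X.shape[1])
    priors = {c: np.mean(y == c) for c in np.unique(y)}
    for i in range(n):
        same = (y == y[i]) & (np.arange(n) != i)
        hit_idx = np.flatnonzero(same)[np.argsort(d2[i][same])][:n_neighbors]
        if len(hit_idx):
            w -= np.abs(Z[i] - Z[hit_idx]).mean(axis=0)
        for c in np.unique(y):
            if c == y[i]:
                continue
            other = y == c
            miss_idx = np.flatnonzero(other)[np.argsort(d2[i][other])][:n_neighbors]
            if len(miss_idx):
                pc = priors[c] / (1 - priors[y[i]])
                w += pc * np.abs(Z[i] - Z[miss_idx]).mean(axis=0)
    return w / n


def chi2_score(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Chi-square statistic after min-max scaling to non-negative values."""
    span = X.max(axis=0) - X.min(axis=0)
    span = np.where(span > 0, span, 1.0)
    Xs = (X - X.min(axis=0)) / span
    stat, _ = sk_chi2(Xs, y)
    return np.nan_to_num(stat, nan=0.0)


def mutual_info_score_(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """k-NN mutual information estimate (deterministic seed)."""
    return mutual_info_classif(X, y, random_state=0)


# ---------------------------------------------------------------------------
# unsupervised scorers


def _knn_heat_graph(X: np.ndarray, k: int = 5) -> np.ndarray:
    """Symmetric k-NN affinity with a heat kernel (bandwidth = mean distance)."""
    n = len(X)
    k = min(k, n - 1)
    d2 = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=-1)
    sigma2 = np.mean(d2[d2 > 0]) if np.any(d2 > 0) else 1.0
    W = np.exp(-d2 / sigma2)
    np.fill_diagonal(d2, np.inf)
    nn = np.argsort(d2, axis=1)[:, :k]
    A = np.zeros((n, n), dtype=bool)
    rows = np.repeat(np.arange(n), k)
    A[rows, nn.ravel()] = True
    A |= A.T
    W = np.where(A, W, 0.0)
    np.fill_diagonal(W, 0.0)
    return W


def variance_score(X: np.ndarray) -> np.ndarray:
    """Plain variance; higher = retained first."""
    return X.var(axis=0)


def laplacian_score(X: np.ndarray, W: np.ndarray) -> np.ndarray:
    """He et al. Laplacian score (locality preservation); lower is better,
    returned negated so that higher = better uniformly."""
    D = W.sum(axis=1)
    L = np.diag(D) - W
    dsum = D.sum()
    scores = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        f = X[:, j]
        f = f - (f @ D) / dsum
        num = f @ L @ f
        den = f @ (D * f)
        scores[j] = num / den if den > 0 else np.inf
    return -scores


def spec_score(X: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Spectral feature selection: smoothness of the normalised feature on
    the normalised graph Laplacian (ranking function phi_1); negated so
    higher = better."""
    D = W.sum(axis=1)
    d_inv_sqrt = np.where(D > 0, 1.0 / np.sqrt(np.maximum(D, 1e-12)), 0.0)
    Lnorm = np.eye(len(W)) - (W * d_inv_sqrt[:, None]) * d_inv_sqrt[None, :]
    scores = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        f = X[:, j] * np.sqrt(np.maximum(D, 1e-12))
        norm = np.linalg.norm(f)
        if norm == 0:
            scores[j] = np.inf
            continue
        f = f / norm
        scores[j] = f @ Lnorm @ f
    return -scores


def _spectral_embedding(W: np.ndarray, n_components: int) -> np.ndarray:
    D = W.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(np.maximum(D, 1e-12))
    Lnorm = np.eye(len(W)) - (W * d_inv_sqrt[:, None]) * d_inv_sqrt[None, :]
    vals, vecs = eigh(Lnorm)
    # skip the trivial constant eigenvector
    return vecs[:, 1 : n_components + 1]


def mcfs_score(X: np.ndarray, W: np.ndarray, n_clusters: int = 2) -> np.ndarray:
    """Multi-cluster FS: sparse regression of spectral embedding axes on
    the features; score = max |coefficient| over axes."""
    from sklearn.linear_model import Lars

    Y = _spectral_embedding(W, n_clusters)
    n_select = min(X.shape[1], max(2, X.shape[0] // 2))
    scores = np.zeros(X.shape[1])
    for k in range(Y.shape[1]):
        model = Lars(n_nonzero_coefs=n_select)
        model.fit(X, Y[:, k])
        scores = np.maximum(scores, np.abs(model.coef_))
    return scores


def ndfs_score(
    X: np.ndarray, W: np.ndarray, n_clusters: int = 2, n_iter: int = 20,
    alpha: float = 1.0, beta: float = 1.0,
) -> np.ndarray:
    """Nonnegative discriminative FS: joint nonnegative spectral clustering
    and l2,1-sparse regression, by multiplicative updates; score = row norm
    of the projection matrix W_proj."""
    n, d = X.shape
    Dg = W.sum(axis=1)
    F = np.abs(_spectral_embedding(W, n_clusters)) + 0.01
    D_w = np.eye(d)
    lam = 1e4  # soft orthogonality of F
    for _ in range(n_iter):
        # projection given F: ridge solve with l2,1 reweighting
        A = X.T @ X + beta * D_w
        Wp = np.linalg.solve(A, X.T @ F)
        row_norms = np.sqrt((Wp**2).sum(axis=1))
        D_w = np.diag(1.0 / (2.0 * np.maximum(row_norms, 1e-8)))
        # nonnegative F update; the graph Laplacian L = diag(Dg) - W is
        # split into its positive and negative parts to keep F >= 0
        XW = X @ Wp
        numer = W @ F + alpha * np.maximum(XW, 0.0) + lam * F
        denom = Dg[:, None] * F + alpha * (F + np.maximum(-XW, 0.0)) + lam * F @ (F.T @ F)
        F = F * np.sqrt(numer / np.maximum(denom, 1e-12))
        F = np.maximum(F, 1e-8)
    Wp = np.linalg.solve(X.T @ X + beta * D_w, X.T @ F)
    return np.sqrt((Wp**2).sum(axis=1))


def udfs_score(
    X: np.ndarray, W_graph: np.ndarray, n_clusters: int = 2, n_iter: int = 20,
    gamma: float = 0.1,
) -> np.ndarray:
    """Unsupervised discriminative FS: minimise Tr(W' M W) + gamma ||W||_2,1
    with W'W = I via iterative reweighted eigendecomposition; score = row
    norm of W."""
    n, d = X.shape
    Xc = X - X.mean(axis=0)
    Dg = W_graph.sum(axis=1)
    L = np.diag(Dg) - W_graph
    M = Xc.T @ L @ Xc
    M = (M + M.T) / 2.0
    D_w = np.eye(d)
    Wm = None
    for _ in range(n_iter):
        A = M + gamma * D_w
        vals, vecs = eigh(A)
        Wm = vecs[:, :n_clusters]
        row_norms = np.sqrt((Wm**2).sum(axis=1))
        D_w = np.diag(1.0 / (2.0 * np.maximum(row_norms, 1e-8)))
    return np.sqrt((Wm**2).sum(axis=1))


# ---------------------------------------------------------------------------
# combination application


def _drop_constant(X: np.ndarray, keys: Sequence[str]):
    keep = X.max(axis=0) > X.min(axis=0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("dropping %d constant features before ranking", n_dropped)
    return X[:, keep], [k for k, m in zip(keys, keep) if m]


def supervised_scores(method: str, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    if method == "fisher":
        return fisher_score(X, y)
    if method == "relieff":
        return relieff_score(X, y)
    if method == "chi2":
        return chi2_score(X, y)
    if method == "mutual_info":
        return mutual_info_score_(X, y)
    raise ValueError(method)


def unsupervised_scores(method: str, X: np.ndarray, X_raw: Optional[np.ndarray] = None) -> np.ndarray:
    """Score features for retention; higher = kept.

    ``X`` is standardised (the graph methods need comparable scales);
    ``X_raw`` is the unstandardised view for the scale-sensitive variance
    score, which is degenerate (identically 1) on standardised data.
    """
    if method == "variance":
        return variance_score(X_raw if X_raw is not None else X)
    W = _knn_heat_graph(X)
    if method == "laplacian":
        return laplacian_score(X, W)
    if method == "spec":
        return spec_score(X, W)
    if method == "mcfs":
        return mcfs_score(X, W)
    if method == "ndfs":
        return ndfs_score(X, W)
    if method == "udfs":
        return udfs_score(X, W)
    raise ValueError(method)


def apply_combination(
    X_train: np.ndarray,
    y_train: np.ndarray,
    keys: Sequence[str],
    combo: FSCombination,
    k_sup: int = 100,
    k_final: int = 30,
) -> List[str]:
    """Select ``k_final`` feature keys from training data only.

    Constant (zero-variance) training features are dropped first; the
    supervised ranker keeps the top ``k_sup``; the unsupervised scorer
    (computed on the training rows of the survivors, standardised) keeps
    the top ``k_final``.  Stable ordering: ties resolve by feature order.
    """
    if len(np.unique(y_train)) < 2:
        raise ValueError("training data must contain both classes")
    X, kept = _drop_constant(np.asarray(X_train, dtype=np.float64), list(keys))
    k_sup = min(k_sup, X.shape[1])
    k_final = min(k_final, k_sup)
    s_scores = supervised_scores(combo.supervised, X, y_train)
    top = np.argsort(-s_scores, kind="stable")[:k_sup]
    Xs = X[:, top]
    mu, sd = Xs.mean(axis=0), Xs.std(axis=0)
    Z = (Xs - mu) / np.where(sd > 0, sd, 1.0)
    u_scores = unsupervised_scores(combo.unsupervised, Z, X_raw=Xs)
    final = top[np.argsort(-u_scores, kind="stable")[:k_final]]
    return [kept[j] for j in final]


# ---------------------------------------------------------------------------
# stability and decision graph


def stability_score(selections: Sequence[Sequence[str]]) -> float:
    """Mean pairwise Jaccard index over all pairs of selections."""
    sets = [set(s) for s in selections]
    if len(sets) < 2:
        raise ValueError("need >= 2 selections")
    if any(len(s) == 0 for s in sets):
        raise ValueError("empty selection")
    vals = [
        len(a & b) / len(a | b)
        for a, b in itertools.combinations(sets, 2)
    ]
    return float(np.mean(vals))


@dataclass
class FSEvaluation:
    combination: FSCombination
    mean_cv_auc: float
    stability: float
    selections: List[List[str]] = field(default_factory=list)


def decision_graph_select(evaluations: Sequence[FSEvaluation]) -> FSCombination:
    """Pick the AUC/stability trade-off winner on the decision graph.

    Both axes are min-max normalised across the candidates; the winner
    maximises the Euclidean norm of (auc_norm, stability_norm).  Ties go
    to the higher raw AUC, then to the lexicographically smaller name.
    """
    aucs = np.array([e.mean_cv_auc for e in evaluations])
    stabs = np.array([e.stability for e in evaluations])

    def norm(v):
        rng = v.max() - v.min()
        return (v - v.min()) / rng if rng > 0 else np.zeros_like(v)

    if np.ptp(aucs) == 0 and np.ptp(stabs) == 0:
        log.warning("all FS evaluations identical; returning first combination")
        return evaluations[0].combination
    score = np.sqrt(norm(aucs) ** 2 + norm(stabs) ** 2)
    order = sorted(
        range(len(evaluations)),
        key=lambda i: (-score[i], -aucs[i], str(evaluations[i].combination)),
    )
    return evaluations[order[0]].combination
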
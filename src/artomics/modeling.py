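"""Model building and evaluation under repeated stratified resampling.

The evaluation protocol: 20 stratified 70/30 train/hold-out splits; within
each training set a stratified 10-fold cross-validation tunes the model
(the Ridge penalty, or the kernel-ridge penalty of the multi-kernel
model).  Feature standardisation, selection and tuning use training rows
only.  Hold-out discrimination is the Mann-Whitney AUC; a model's headline
number is the mean hold-out AUC over the 20 iterations with its SD and
normal-approximation 95% CI (mean +/- 1.96 SD / sqrt(20)).

Single-omics models are Ridge classifiers (L2-penalised least squares on
+/-1 labels; the penalty is chosen on a logarithmic grid by inner-CV mean
AUC).  Multi-omics models use multi-kernel learning (MKL): per omics
block, Gaussian kernels over a range of widths and polynomial kernels of
degree 1-3 are built on the standardised block; kernels are combined with
non-negative weights proportional to their centred-kernel alignment with
the label kernel (normalised to sum 1) and the combined Gram matrix feeds
a kernel-ridge classifier.

Model-size optimisation is frequency-ranked backward elimination: starting
from the features most frequently selected across the 20 iterations, the
lowest-frequency feature is dropped (ties: smaller mean |standardised
ridge coefficient|, then lexicographic), the models retrained at every
size down to one feature, and the size maximising mean hold-out AUC kept
(ties favour the smaller set).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from .datamodel import FeatureTable
from .feature_selection import (
    FSCombination,
    FSEvaluation,
    apply_combination,
    stability_score,
)

log = logging.getLogger(__name__)

ALPHA_GRID = tuple(np.logspace(-3, 3, 13))
GAUSSIAN_GAMMAS = (1e-3, 1e-2, 1e-1, 1.0, 10.0)
POLY_DEGREES = (1, 2, 3)
PSD_TOL = 1e-8


# ---------------------------------------------------------------------------
# splits


@dataclass
class SplitIteration:
    train_idx: np.ndarray
    test_idx: np.ndarray
    fold_of_train_row: np.ndarray  # inner-CV fold id per training row


@dataclass
class SplitPlan:
    """20 stratified 70/30 partitions with inner 10-fold assignments."""

    iterations: List[SplitIteration]
    seed: int
    n_folds: int = 10


def make_split_plan(
    labels: np.ndarray,
    seed: int,
    n_iterations: int = 20,
    test_size: float = 0.3,
    n_folds: int = 10,
) -> SplitPlan:
    labels = np.asarray(labels, dtype=int)
    counts = np.bincount(labels, minlength=2)
    if counts.min() < 10:
        raise ValueError("need >= 10 members of each class for stratified folds")
    outer = StratifiedShuffleSplit(
        n_splits=n_iterations, test_size=test_size, random_state=seed
    )
    iterations = []
    for it, (tr, te) in enumerate(outer.split(np.zeros(len(labels)), labels)):
        kf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed + 1 + it)
        fold_of = np.empty(len(tr), dtype=int)
        for f, (_, val) in enumerate(kf.split(np.zeros(len(tr)), labels[tr])):
            fold_of[val] = f
        iterations.append(SplitIteration(tr, te, fold_of))
    return SplitPlan(iterations, seed, n_folds)


# ---------------------------------------------------------------------------
# AUC and summaries


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney probability AUC; tied scores count one half."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=np.float64)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("AUC requires both classes")
    ranks = stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n0 * n1))


def summarize(aucs: Sequence[float]) -> Dict[str, float]:
    """Mean, sample SD and normal-approximation 95% CI, to 3 decimals."""
    a = np.asarray(aucs, dtype=np.float64)
    mean = a.mean()
    sd = a.std(ddof=1) if len(a) > 1 else 0.0
    half = 1.96 * sd / np.sqrt(len(a))
    return {
        "mean": round(float(mean), 3),
        "sd": round(float(sd), 3),
        "ci_low": round(float(mean - half), 3),
        "ci_high": round(float(mean + half), 3),
        "n": len(a),
    }


def compare_models(aucs_a: Sequence[float], aucs_b: Sequence[float]) -> float:
    """Two-sided paired t-test p-value on per-iteration AUCs."""
    a = np.asarray(aucs_a, dtype=np.float64)
    b = np.asarray(aucs_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("paired comparison requires equal-length AUC vectors")
    diff = a - b
    if np.allclose(diff.std(), 0.0):
        if np.allclose(diff, 0.0):
            log.warning("identical AUC vectors; reporting p = 1")
            return 1.0
        return 0.0  # constant non-zero difference: infinitely strong evidence
    return float(stats.ttest_rel(a, b).pvalue)


def clinical_factor_tests(
    covariates, types: Dict[str, str], labels: np.ndarray
):
    """Chi-square (categorical) / two-sample t-test (continuous) per factor.

    ``types`` maps column name to 'categorical' or 'continuous'.  Expected
    chi-square cell counts below 1 are flagged in the output.
    """
    import pandas as pd

    labels = np.asarray(labels, dtype=int)
    rows = []
    for col, kind in types.items():
        x = covariates[col]
        flag = ""
        if kind == "categorical":
            table = pd.crosstab(x, labels)
            chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
            if (expected < 1).any():
                flag = "expected cell count < 1"
            rows.append({"factor": col, "test": "chi-square", "statistic": chi2, "p_value": p, "flag": flag})
        elif kind == "continuous":
            x0 = np.asarray(x)[labels == 0]
            x1 = np.asarray(x)[labels == 1]
            if np.var(x0) + np.var(x1) == 0:
                rows.append({"factor": col, "test": "t-test", "statistic": np.nan, "p_value": np.nan, "flag": "zero pooled variance"})
                continue
            t, p = stats.ttest_ind(x0, x1)
            rows.append({"factor": col, "test": "t-test", "statistic": t, "p_value": p, "flag": flag})
        else:
            raise ValueError(f"unknown covariate type {kind!r}")
    return pd.DataFrame(rows).set_index("factor")


# ---------------------------------------------------------------------------
# ridge classifier (L2-penalised least squares on +/-1 labels)


@dataclass
class RidgeModel:
    mu: np.ndarray
    sd: np.ndarray
    coef: np.ndarray
    alpha: float

    def decision(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, dtype=np.float64) - self.mu) / self.sd
        return Z @ self.coef


def _standardize_fit(X: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mu, sd


def _ridge_coefs_all_alphas(Z: np.ndarray, t: np.ndarray, alphas) -> np.ndarray:
    """Ridge solutions for every alpha from one SVD; rows = alphas."""
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    Uty = U.T @ t
    return np.stack([(Vt.T * (s / (s**2 + a))) @ Uty for a in alphas])


def train_ridge(
    X: np.ndarray,
    y: np.ndarray,
    fold_of_row: np.ndarray,
    alphas: Sequence[float] = ALPHA_GRID,
) -> RidgeModel:
    """CV-tuned ridge: penalty maximising mean inner-fold validation AUC."""
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("single-class training data")
    X = np.asarray(X, dtype=np.float64)
    mu, sd = _standardize_fit(X)
    Z = (X - mu) / sd
    t = 2.0 * y - 1.0
    per_alpha = [[] for _ in alphas]
    for f in np.unique(fold_of_row):
        val = fold_of_row == f
        if len(np.unique(y[val])) < 2 or len(np.unique(y[~val])) < 2:
            continue  # single-class fold carries no ranking information
        mu_f, sd_f = _standardize_fit(X[~val])
        Zf = (X[~val] - mu_f) / sd_f
        Zv = (X[val] - mu_f) / sd_f
        coefs = _ridge_coefs_all_alphas(Zf, t[~val], alphas)
        for k in range(len(alphas)):
            per_alpha[k].append(auc(Zv @ coefs[k], y[val]))
    mean_cv = np.array([np.mean(v) if v else 0.5 for v in per_alpha])
    best = int(np.argmax(mean_cv))
    coef = _ridge_coefs_all_alphas(Z, t, [alphas[best]])[0]
    return RidgeModel(mu, sd, coef, float(alphas[best]))


def ridge_cv_auc(
    X: np.ndarray, y: np.ndarray, fold_of_row: np.ndarray,
    alphas: Sequence[float] = ALPHA_GRID,
) -> float:
    """Best mean inner-fold validation AUC over the penalty grid."""
    y = np.asarray(y, dtype=int)
    X = np.asarray(X, dtype=np.float64)
    t = 2.0 * y - 1.0
    per_alpha = [[] for _ in alphas]
    for f in np.unique(fold_of_row):
        val = fold_of_row == f
        if len(np.unique(y[val])) < 2 or len(np.unique(y[~val])) < 2:
            continue
        mu_f, sd_f = _standardize_fit(X[~val])
        Zf = (X[~val] - mu_f) / sd_f
        Zv = (X[val] - mu_f) / sd_f
        coefs = _ridge_coefs_all_alphas(Zf, t[~val], alphas)
        for k in range(len(alphas)):
            per_alpha[k].append(auc(Zv @ coefs[k], y[val]))
    return float(max(np.mean(v) if v else 0.5 for v in per_alpha))


# ---------------------------------------------------------------------------
# multi-kernel learning


@dataclass(frozen=True)
class KernelSpec:
    family: str  # "gaussian" | "polynomial"
    parameter: float
    block: str

    def gram(self, A: np.ndarray, B: np.ndarray) -> np.ndarray:
        if self.family == "gaussian":
            d2 = (
                np.sum(A**2, axis=1)[:, None]
                + np.sum(B**2, axis=1)[None, :]
                - 2.0 * A @ B.T
            )
            return np.exp(-self.parameter * np.maximum(d2, 0.0))
        if self.family == "polynomial":
            scale = A.shape[1]
            return (A @ B.T / scale) ** int(self.parameter)
        raise ValueError(self.family)


def default_kernel_grid(block_names: Sequence[str]) -> List[KernelSpec]:
    specs = []
    for b in block_names:
        for g in GAUSSIAN_GAMMAS:
            specs.append(KernelSpec("gaussian", g, b))
        for d in POLY_DEGREES:
            specs.append(KernelSpec("polynomial", d, b))
    return specs


def _center_gram(K: np.ndarray) -> np.ndarray:
    n = K.shape[0]
    H = np.eye(n) - np.ones((n, n)) / n
    return H @ K @ H


def kernel_alignment(K: np.ndarray, y: np.ndarray) -> float:
    """Centred-kernel alignment of a Gram matrix with the label kernel."""
    t = 2.0 * np.asarray(y, dtype=np.float64) - 1.0
    Ky = np.outer(t, t)
    Kc = _center_gram(K)
    Kyc = _center_gram(Ky)
    denom = np.linalg.norm(Kc) * np.linalg.norm(Kyc)
    if denom == 0:
        return 0.0
    return float(np.sum(Kc * Kyc) / denom)


@dataclass
class MKLModel:
    blocks: Dict[str, Tuple[np.ndarray, np.ndarray]]  # name -> (mu, sd)
    train_blocks: Dict[str, np.ndarray]  # standardised training data
    specs: List[KernelSpec]
    weights: np.ndarray
    dual_coef: np.ndarray
    alpha: float

    def _combined(self, test_blocks: Optional[Dict[str, np.ndarray]] = None) -> np.ndarray:
        first = next(iter(self.train_blocks.values()))
        if test_blocks is None:
            n = first.shape[0]
            K = np.zeros((n, n))
            for w, spec in zip(self.weights, self.specs):
                A = self.train_blocks[spec.block]
                K += w * spec.gram(A, A)
        else:
            n = next(iter(test_blocks.values())).shape[0]
            K = np.zeros((n, first.shape[0]))
            for w, spec in zip(self.weights, self.specs):
                K += w * spec.gram(test_blocks[spec.block], self.train_blocks[spec.block])
        return K

    def decision(self, X_blocks: Dict[str, np.ndarray]) -> np.ndarray:
        test = {
            name: (np.asarray(X, dtype=np.float64) - self.blocks[name][0])
            / self.blocks[name][1]
            for name, X in X_blocks.items()
        }
        return self._combined(test) @ self.dual_coef


def train_mkl(
    X_blocks: Dict[str, np.ndarray],
    y: np.ndarray,
    fold_of_row: np.ndarray,
    specs: Optional[List[KernelSpec]] = None,
    alphas: Sequence[float] = ALPHA_GRID,
) -> MKLModel:
    """Alignment-weighted multi-kernel ridge classifier.

    Kernel weights are the positive parts of each kernel's centred
    alignment with the label kernel, normalised to sum 1 (uniform if all
    vanish); the kernel-ridge penalty comes from inner-CV AUC on the
    combined Gram matrix.
    """
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("single-class training data")
    if not X_blocks:
        raise ValueError("need at least one feature block")
    if specs is None:
        specs = default_kernel_grid(sorted(X_blocks))
    stats_: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    Z: Dict[str, np.ndarray] = {}
    for name, X in X_blocks.items():
        X = np.asarray(X, dtype=np.float64)
        mu, sd = _standardize_fit(X)
        stats_[name] = (mu, sd)
        Z[name] = (X - mu) / sd

    grams = [spec.gram(Z[spec.block], Z[spec.block]) for spec in specs]
    align = np.array([max(kernel_alignment(K, y), 0.0) for K in grams])
    weights = align / align.sum() if align.sum() > 0 else np.full(len(grams), 1.0 / len(grams))
    K = sum(w * G for w, G in zip(weights, grams))

    eigmin = float(np.linalg.eigvalsh(K).min())
    if eigmin < -PSD_TOL * max(1.0, float(np.abs(K).max())):
        raise ValueError(f"combined kernel not PSD (min eigenvalue {eigmin:.3e})")

    t = 2.0 * y - 1.0
    per_alpha = [[] for _ in alphas]
    for f in np.unique(fold_of_row):
        val = fold_of_row == f
        if len(np.unique(y[val])) < 2 or len(np.unique(y[~val])) < 2:
            continue
        Ktr = K[np.ix_(~val, ~val)]
        Kva = K[np.ix_(val, ~val)]
        for k, a in enumerate(alphas):
            c = np.linalg.solve(Ktr + a * np.eye(Ktr.shape[0]), t[~val])
            per_alpha[k].append(auc(Kva @ c, y[val]))
    mean_cv = np.array([np.mean(v) if v else 0.5 for v in per_alpha])
    best = int(np.argmax(mean_cv))
    a = float(alphas[best])
    dual = np.linalg.solve(K + a * np.eye(K.shape[0]), t)
    return MKLModel(stats_, Z, list(specs), weights, dual, a)


# ---------------------------------------------------------------------------
# model reports and backward elimination


@dataclass
class ModelReport:
    name: str
    feature_keys: List[str]
    train_aucs: List[float]
    test_aucs: List[float]
    train_summary: Dict[str, float]
    test_summary: Dict[str, float]
    family_shares: Dict[str, float]
    trajectory: List[Tuple[int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for a in self.train_aucs + self.test_aucs:
            if not 0.0 <= a <= 1.0:
                raise ValueError("AUC outside [0, 1]")


def _family_shares(keys: Sequence[str]) -> Dict[str, float]:
    fams = [k.split(":", 1)[0] for k in keys]
    return {f: fams.count(f) / len(fams) for f in sorted(set(fams))}


def _split_blocks(table: FeatureTable, keys: Sequence[str], rows: np.ndarray):
    """Feature sub-matrix split by omics family for MKL."""
    sub = table.select(list(keys))
    fams = sorted({c.family for c in sub.columns})
    out = {}
    for fam in fams:
        cols = [j for j, c in enumerate(sub.columns) if c.family == fam]
        out[fam] = sub.matrix[np.ix_(rows, cols)]
    return out


def _score_iteration(
    table: FeatureTable,
    labels: np.ndarray,
    it: SplitIteration,
    keys: Sequence[str],
    model: str,
) -> Tuple[float, float]:
    """Train and hold-out AUC for one iteration's own feature set."""
    X = table.select(list(keys)).matrix
    tr, te = it.train_idx, it.test_idx
    if model == "ridge":
        m = train_ridge(X[tr], labels[tr], it.fold_of_train_row)
        s_tr, s_te = m.decision(X[tr]), m.decision(X[te])
    elif model == "mkl":
        blocks_tr = _split_blocks(table, keys, tr)
        mm = train_mkl(blocks_tr, labels[tr], it.fold_of_train_row)
        s_tr = mm._combined() @ mm.dual_coef
        s_te = mm.decision(_split_blocks(table, keys, te))
    else:
        raise ValueError(model)
    return auc(s_tr, labels[tr]), auc(s_te, labels[te])


def score_selections(
    table: FeatureTable,
    labels: np.ndarray,
    plan: SplitPlan,
    per_iteration_keys: Sequence[Sequence[str]],
    model: str = "ridge",
) -> Tuple[List[float], List[float]]:
    """Per-iteration train/hold-out AUCs, each on its own feature set.

    Every iteration's model sees only features selected on that
    iteration's training rows — nothing derived from other iterations'
    data touches its hold-out evaluation.
    """
    train_aucs, test_aucs = [], []
    for it, keys in zip(plan.iterations, per_iteration_keys):
        a_tr, a_te = _score_iteration(table, labels, it, keys, model)
        train_aucs.append(a_tr)
        test_aucs.append(a_te)
    return train_aucs, test_aucs


def _frequency_order(
    selections: Sequence[Sequence[str]],
) -> Tuple[Dict[str, int], List[str]]:
    """Removal order over the union of selections.

    Primary key: selection frequency (ascending = removed first); ties
    resolve lexicographically.  The tie-break is deliberately
    label-blind: any label-informed ranking pooled across the 20
    iterations (e.g. mean ridge-coefficient magnitude) is correlated with
    every iteration's hold-out rows and re-introduces selection leakage
    into the elimination order.
    """
    freq: Dict[str, int] = {}
    for sel in selections:
        for k in set(sel):
            freq[k] = freq.get(k, 0) + 1
    keep_order = sorted(freq, key=lambda k: (-freq[k], k))
    return freq, keep_order


def backward_eliminate(
    table: FeatureTable,
    labels: np.ndarray,
    plan: SplitPlan,
    selections: Sequence[Sequence[str]],
    model: str = "ridge",
) -> Tuple[List[str], List[Tuple[int, float]], Tuple[List[float], List[float]]]:
    """Frequency-ranked backward elimination to the AUC-maximising size.

    Feature frequency = number of iterations selecting the feature.  The
    frequency ranking (ties: lexicographic) fixes a global removal order,
    but at every size each iteration's model is retrained on the
    surviving members of *its own* training-derived selection — so
    per-iteration hold-out AUCs never see feature choices informed by
    their own rows.
    Scoring runs at sizes K, K-1, ..., 1 (K = selection size); the size
    whose mean hold-out AUC is maximal wins (ties: the smaller size).

    Returns the global top-size feature set (by the same ranking), the
    (size, mean hold-out AUC) trajectory, and the per-iteration
    (train, hold-out) AUC vectors at the winning size.
    """
    if not selections or any(len(s) == 0 for s in selections):
        raise ValueError("empty initial selections")
    freq, keep_order = _frequency_order(selections)
    rank = {k: j for j, k in enumerate(keep_order)}
    k_init = len(selections[0])
    # each iteration's list ordered by the global ranking; truncating it
    # realises the elimination within that iteration's own selection
    ordered_sel = [sorted(sel, key=lambda k: rank[k]) for sel in selections]

    trajectory: List[Tuple[int, float]] = []
    best_size, best_auc, best_scores = None, -np.inf, None
    for size in range(k_init, 0, -1):
        per_iter = [sel[: min(size, len(sel))] for sel in ordered_sel]
        tr_a, te_a = score_selections(table, labels, plan, per_iter, model)
        mean_te = float(np.mean(te_a))
        trajectory.append((size, mean_te))
        if mean_te >= best_auc:  # sizes descend, so ties keep the smaller set
            best_size, best_auc, best_scores = size, mean_te, (tr_a, te_a)
    return keep_order[:best_size], trajectory, best_scores


def build_model(
    table: FeatureTable,
    labels: np.ndarray,
    plan: SplitPlan,
    combo: FSCombination,
    name: str,
    model: str = "ridge",
    k_sup: int = 100,
    k_final: int = 30,
    eliminate: bool = True,
) -> ModelReport:
    """End-to-end model for one omics dataset under the split plan."""
    labels = np.asarray(labels, dtype=int)
    selections = [
        apply_combination(
            table.matrix[it.train_idx], labels[it.train_idx], table.keys, combo,
            k_sup=k_sup, k_final=k_final,
        )
        for it in plan.iterations
    ]
    if eliminate:
        best_keys, trajectory, (train_aucs, test_aucs) = backward_eliminate(
            table, labels, plan, selections, model
        )
    else:
        freq: Dict[str, int] = {}
        for sel in selections:
            for k in set(sel):
                freq[k] = freq.get(k, 0) + 1
        best_keys = sorted(freq, key=lambda k: (-freq[k], k))[:k_final]
        trajectory = []
        train_aucs, test_aucs = score_selections(table, labels, plan, selections, model)
    return ModelReport(
        name=name,
        feature_keys=list(best_keys),
        train_aucs=train_aucs,
        test_aucs=test_aucs,
        train_summary=summarize(train_aucs),
        test_summary=summarize(test_aucs),
        family_shares=_family_shares(best_keys),
        trajectory=trajectory,
    )


# ---------------------------------------------------------------------------
# FS-combination evaluation (AUC + stability over the split plan)


def evaluate_combinations(
    table: FeatureTable,
    labels: np.ndarray,
    plan: SplitPlan,
    combos: Optional[Sequence[FSCombination]] = None,
    k_sup: int = 100,
    k_final: int = 30,
) -> List[FSEvaluation]:
    """Mean training-CV AUC and selection stability for each combination."""
    from .feature_selection import enumerate_combinations

    labels = np.asarray(labels, dtype=int)
    combos = list(combos) if combos is not None else enumerate_combinations()
    out = []
    for combo in combos:
        sels, cv_aucs = [], []
        for it in plan.iterations:
            tr = it.train_idx
            sel = apply_combination(
                table.matrix[tr], labels[tr], table.keys, combo,
                k_sup=k_sup, k_final=k_final,
            )
            sels.append(sel)
            Xsel = table.select(sel).matrix[tr]
            cv_aucs.append(ridge_cv_auc(Xsel, labels[tr], it.fold_of_train_row))
        out.append(
            FSEvaluation(combo, float(np.mean(cv_aucs)), stability_score(sels), sels)
        )
    return out
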
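"""Stepwise discriminant function analysis and the pairwise-F dissimilarity.

The acoustic side of the pipeline treats individual identity as the grouping
variable of a linear discriminant analysis.  Features are chosen by the
classic Wilks'-lambda stepwise procedure (probability-of-F to enter/remove,
defaults P_in = 0.05, P_out = 0.10).  From the fitted model we derive

* classification rates (resubstitution and exact leave-one-out), with the
  chance level 100/g % for g groups under equal priors, and
* the pairwise between-group F statistic

      F_ij = (N - g - p + 1) / (p (N - g)) * n_i n_j / (n_i + n_j) * D²_ij

  where D²_ij is the Mahalanobis distance between group centroids under the
  pooled within-group covariance of the p selected features.  For g = 2 this
  reduces to the two-sample Hotelling T² F statistic.  ln(1 + F) is the
  dyadic acoustic dissimilarity used downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import CallFeatureTable, DyadicMatrix

logger = logging.getLogger("convergekit")

__all__ = [
    "StepwiseModel",
    "ClassificationResult",
    "fit_model",
    "stepwise_select",
    "classify",
    "pairwise_f_matrix",
    "dissimilarity_from_f",
]

#: Condition-number threshold above which a candidate's total scatter is
#: treated as rank deficient and the candidate is skipped (logged).
RANK_TOL = 1e12


@dataclass
class StepRecord:
    action: str  # "enter" | "remove"
    feature: str
    partial_F: float
    p_value: float
    wilks_lambda: float  # lambda of the selected set AFTER the action


@dataclass
class StepwiseModel:
    """Result of the stepwise selection plus the fitted group statistics."""

    selected_features: list[str]
    trace: list[StepRecord]
    group_labels: list[str]
    group_means: np.ndarray        # (g, p)
    pooled_cov: np.ndarray         # (p, p), divisor N - g
    group_sizes: np.ndarray        # (g,)
    n_total: int
    canonical_coefficients: np.ndarray | None = None  # (p, n_funcs)
    notes: list[str] = field(default_factory=list)

    @property
    def g(self) -> int:
        return len(self.group_labels)

    @property
    def p(self) -> int:
        return len(self.selected_features)

    @property
    def is_empty(self) -> bool:
        return self.p == 0

    def trace_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "action": r.action,
                    "feature": r.feature,
                    "partial_F": r.partial_F,
                    "p_value": r.p_value,
                    "wilks_lambda": r.wilks_lambda,
                }
                for r in self.trace
            ]
        )


def _group_stats(X: np.ndarray, labels: np.ndarray):
    """Group labels (stable order of appearance), sizes, means, W and T scatter."""
    order: dict[object, int] = {}
    for v in labels:
        order.setdefault(v, len(order))
    glabels = list(order)
    gidx = np.array([order[v] for v in labels])
    g = len(glabels)
    N, K = X.shape
    sizes = np.bincount(gidx, minlength=g).astype(int)
    means = np.zeros((g, K))
    for j in range(g):
        means[j] = X[gidx == j].mean(axis=0)
    grand = X.mean(axis=0)
    Xc_w = X - means[gidx]
    W = Xc_w.T @ Xc_w
    Xc_t = X - grand
    T = Xc_t.T @ Xc_t
    return glabels, gidx, sizes, means, W, T


def _log_det(M: np.ndarray) -> float | None:
    """log(det(M)) for a PSD scatter submatrix, None if numerically singular."""
    if M.size == 0:
        return 0.0
    sign, logdet = np.linalg.slogdet(M)
    if sign <= 0:
        return None
    # condition check guards against near-singular sets that slogdet survives
    if np.linalg.cond(M) > RANK_TOL:
        return None
    return float(logdet)


def stepwise_select(
    table: CallFeatureTable, p_in: float = 0.05, p_out: float = 0.10
) -> StepwiseModel:
    """Wilks'-lambda stepwise feature selection with identity as grouping.

    At each step the partial F of adding (or removing) a feature given the
    current set is computed from the ratio of Wilks' lambdas,

        F_enter = (N - g - p) / (g - 1) * (Λ_S / Λ_{S∪v} - 1),

    with df (g-1, N-g-p), p = |S|; the candidate with the smallest p-value
    enters if p < ``p_in``, and an entered feature with the largest p-value
    is removed if p > ``p_out``.  Ties in p are broken by larger partial F,
    then by column order.  Features whose total scatter is rank deficient
    with the current set are skipped (logged).  If no feature qualifies at
    step 1 the returned model has an empty selection (flagged in ``notes``),
    not an exception.
    """
    if p_in > p_out:
        raise ValueError("p_in must be <= p_out (guards stepwise cycling)")
    X = table.X
    labels = table.labels
    glabels, gidx, sizes, means, W, T = _group_stats(X, labels)
    g = len(glabels)
    N, K = X.shape
    if (sizes < 1).any() or g < 2:
        raise ValueError("need at least two groups")
    feat_names = table.feature_names

    selected: list[int] = []
    trace: list[StepRecord] = []
    notes: list[str] = []
    # log-lambda of the current selected set; None encodes lambda == 0
    loglam_cache: dict[tuple[int, ...], float | None] = {}

    def log_lambda(idx: tuple[int, ...]) -> float | None:
        """log Wilks' lambda of the feature set, None if T singular there.

        Returns -inf when the within scatter is singular but the total
        scatter is not (perfect separation → lambda = 0).
        """
        if idx in loglam_cache:
            return loglam_cache[idx]
        sub = np.array(idx, dtype=int)
        ldT = _log_det(T[np.ix_(sub, sub)])
        if ldT is None:
            loglam_cache[idx] = None
            return None
        ldW = _log_det(W[np.ix_(sub, sub)])
        val = -np.inf if ldW is None else ldW - ldT
        loglam_cache[idx] = val
        return val

    def partial_f(lam_small: float, lam_big: float, p_current: int) -> tuple[float, float]:
        """(F, p) for the lambda change; lam_* are log-lambdas."""
        df2 = N - g - p_current
        if df2 <= 0:
            return 0.0, 1.0
        if lam_big == -np.inf:
            return np.inf, 0.0
        ratio = np.exp(lam_small - lam_big)  # Λ_S / Λ_{S∪v} >= 1
        F = df2 / (g - 1) * max(ratio - 1.0, 0.0)
        return F, float(stats.f.sf(F, g - 1, df2))

    while True:
        cur = tuple(selected)
        lam_cur = log_lambda(cur) if selected else 0.0
        changed = False

        if lam_cur is not None and lam_cur != -np.inf and N - g - len(selected) > 0:
            # --- entry scan
            best = None  # (p, -F, order, idx)
            for v in range(K):
                if v in selected:
                    continue
                lam_new = log_lambda(tuple(sorted(cur + (v,))))
                if lam_new is None:
                    logger.debug("stepwise: skipping rank-deficient candidate %s", feat_names[v])
                    continue
                F, pv = partial_f(lam_cur, lam_new, len(selected))
                key = (pv, -F, v)
                if F > 0 and (best is None or key < best[0]):
                    best = (key, v, F, pv, lam_new)
            if best is not None and best[0][0] < p_in:
                _, v, F, pv, lam_new = best
                selected.append(v)
                trace.append(StepRecord("enter", feat_names[v], F, pv,
                                        float(np.exp(lam_new)) if lam_new != -np.inf else 0.0))
                changed = True
                if lam_new == -np.inf:
                    notes.append("perfect separation: Wilks' lambda reached 0, selection stopped")
                    break

        # --- removal scan (never removes the variable just entered: its
        # p-to-remove equals its p-to-enter < p_in <= p_out)
        while len(selected) > 1:
            cur = tuple(selected)
            lam_cur = log_lambda(cur)
            if lam_cur is None or lam_cur == -np.inf:
                break
            worst = None
            for v in selected:
                rest = tuple(sorted(i for i in selected if i != v))
                lam_rest = log_lambda(rest) if rest else 0.0
                if lam_rest is None:
                    continue
                F, pv = partial_f(lam_rest, lam_cur, len(selected) - 1)
                key = (-pv, F, -selected.index(v))
                if worst is None or key < worst[0]:
                    worst = (key, v, F, pv)
            if worst is not None and worst[3] > p_out:
                _, v, F, pv = worst
                selected.remove(v)
                lam_after = log_lambda(tuple(sorted(selected)))
                trace.append(StepRecord("remove", feat_names[v], F, pv,
                                        float(np.exp(lam_after)) if lam_after not in (None, -np.inf) else np.nan))
                changed = True
            else:
                break

        if not changed:
            break
        if len(trace) > 4 * K:  # cycling guard; p_in <= p_out makes this unreachable in practice
            notes.append("stepwise iteration cap reached; selection truncated")
            logger.warning("stepwise iteration cap reached")
            break

    if not selected:
        notes.append("no feature met the entry criterion; selection is empty")
        logger.warning("stepwise selection empty (p_in=%.3g)", p_in)

    sub = np.array(selected, dtype=int)
    p = len(selected)
    pooled = W[np.ix_(sub, sub)] / (N - g) if p else np.zeros((0, 0))
    gmeans = means[:, sub] if p else np.zeros((g, 0))

    canon = None
    if p:
        B = T[np.ix_(sub, sub)] - W[np.ix_(sub, sub)]
        try:
            evals, evecs = np.linalg.eig(np.linalg.solve(W[np.ix_(sub, sub)], B))
            order2 = np.argsort(evals.real)[::-1][: min(p, g - 1)]
            canon = np.real(evecs[:, order2])
        except np.linalg.LinAlgError:
            notes.append("canonical coefficients unavailable (singular within scatter)")

    return StepwiseModel(
        selected_features=[feat_names[i] for i in selected],
        trace=trace,
        group_labels=[str(l) for l in glabels],
        group_means=gmeans,
        pooled_cov=pooled,
        group_sizes=sizes,
        n_total=N,
        canonical_coefficients=canon,
        notes=notes,
    )


def fit_model(table: CallFeatureTable, features: list[str] | None = None) -> StepwiseModel:
    """Fit the discriminant statistics on a fixed feature set (no selection).

    Useful when the analysis prescribes the feature list, or when no feature
    clears the stepwise entry criterion but a model is still wanted.
    """
    features = table.feature_names if features is None else list(features)
    X = table.select_features(features)
    labels = table.labels
    glabels, gidx, sizes, means, W, T = _group_stats(X, labels)
    g, N = len(glabels), len(X)
    return StepwiseModel(
        selected_features=features,
        trace=[],
        group_labels=[str(l) for l in glabels],
        group_means=means,
        pooled_cov=W / (N - g),
        group_sizes=sizes,
        n_total=N,
    )


@dataclass
class ClassificationResult:
    percent_correct: float
    confusion: pd.DataFrame
    chance_percent: float
    mode: str
    n_classified: int
    excluded_calls: list[str] = field(default_factory=list)


def _fit_rule(X: np.ndarray, labels: np.ndarray, glabels: list):
    """Group means + pooled covariance for the classification rule."""
    order = {v: k for k, v in enumerate(glabels)}
    gidx = np.array([order[v] for v in labels])
    g = len(glabels)
    N, p = X.shape
    sizes = np.bincount(gidx, minlength=g)
    means = np.zeros((g, p))
    for j in range(g):
        means[j] = X[gidx == j].mean(axis=0)
    Xc = X - means[gidx]
    pooled = Xc.T @ Xc / max(N - g, 1)
    return means, pooled


def _nearest_group(x: np.ndarray, means: np.ndarray, pooled: np.ndarray) -> int:
    """Index of the group with smallest Mahalanobis distance (equal priors)."""
    diff = means - x[None, :]
    if not np.any(pooled):
        d2 = (diff ** 2).sum(axis=1)  # zero within-variance: Euclidean
    else:
        try:
            sol = np.linalg.solve(pooled, diff.T)
        except np.linalg.LinAlgError:
            sol = np.linalg.pinv(pooled) @ diff.T
        d2 = (diff * sol.T).sum(axis=1)
    return int(np.argmin(d2))


def classify(
    model: StepwiseModel, table: CallFeatureTable, mode: str = "resubstitution"
) -> ClassificationResult:
    """Classify calls to individuals by the linear rule with equal priors.

    ``mode='leave_one_out'`` refits the group means and pooled covariance
    from scratch with the held-out call excluded; a call whose individual has
    only that one call cannot be held out and is excluded (logged).
    """
    if model.is_empty:
        raise ValueError("model has an empty selection; nothing to classify with")
    if mode not in ("resubstitution", "leave_one_out"):
        raise ValueError(f"unknown mode {mode!r}")
    X = table.select_features(model.selected_features)
    labels = table.labels
    glabels = model.group_labels
    unknown = sorted({str(l) for l in labels} - set(glabels))
    if unknown:
        raise ValueError(f"table contains individuals unseen by the model: {unknown}")
    order = {v: k for k, v in enumerate(glabels)}
    gidx = np.array([order[str(v)] for v in labels])
    g = len(glabels)
    N = len(X)

    predicted = np.full(N, -1, dtype=int)
    excluded: list[str] = []

    if mode == "resubstitution":
        means, pooled = _fit_rule(X, labels.astype(str), glabels)
        for i in range(N):
            predicted[i] = _nearest_group(X[i], means, pooled)
    else:
        counts = np.bincount(gidx, minlength=g)
        keep = np.ones(N, dtype=bool)
        for i in range(N):
            if counts[gidx[i]] < 2:
                keep[i] = False
                excluded.append(str(table.data["call_id"].iloc[i]))
                continue
            mask = np.ones(N, dtype=bool)
            mask[i] = False
            means, pooled = _fit_rule(X[mask], labels[mask].astype(str), glabels)
            predicted[i] = _nearest_group(X[i], means, pooled)
        if excluded:
            logger.info("LOO: excluded %d singleton-individual calls", len(excluded))

    used = predicted >= 0
    correct = (predicted[used] == gidx[used]).mean() * 100.0 if used.any() else np.nan
    conf = pd.DataFrame(0, index=glabels, columns=glabels)
    for t, pr in zip(gidx[used], predicted[used]):
        conf.iloc[t, pr] += 1
    return ClassificationResult(
        percent_correct=float(correct),
        confusion=conf,
        chance_percent=100.0 / g,
        mode=mode,
        n_classified=int(used.sum()),
        excluded_calls=excluded,
    )


def pairwise_f_matrix(model: StepwiseModel) -> DyadicMatrix:
    """Pairwise between-group F statistics from the fitted model.

    Fails (rather than silently regularising) if the pooled within-group
    covariance of the selected features is singular, and requires
    N - g - p + 1 > 0 residual degrees of freedom.
    """
    if model.is_empty:
        raise ValueError("cannot compute pairwise F from an empty selection")
    N, g, p = model.n_total, model.g, model.p
    if N - g - p + 1 <= 0:
        raise ValueError("no residual degrees of freedom: N - g - p + 1 <= 0")
    try:
        chol = np.linalg.cholesky(model.pooled_cov)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "pooled within-group covariance is singular; reduce the number of "
            "selected features before computing pairwise F"
        ) from None
    # Mahalanobis distances between all group centroids via whitened means
    Y = np.linalg.solve(chol, model.group_means.T).T  # (g, p)
    sq = ((Y[:, None, :] - Y[None, :, :]) ** 2).sum(axis=2)  # D² matrix
    n = model.group_sizes.astype(float)
    nn = n[:, None] * n[None, :] / (n[:, None] + n[None, :])
    F = (N - g - p + 1) / (p * (N - g)) * nn * sq
    np.fill_diagonal(F, 0.0)
    return DyadicMatrix(tuple(model.group_labels), F, kind="pairwise_F")


def dissimilarity_from_f(fmat: DyadicMatrix) -> DyadicMatrix:
    """Elementwise ln(1 + F); order-preserving transform of the F matrix."""
    if fmat.kind != "pairwise_F":
        raise ValueError(f"expected a pairwise_F matrix, got kind {fmat.kind!r}")
    if (fmat.values < 0).any():
        raise ValueError("negative pairwise F values violate the F-matrix invariant")
    return DyadicMatrix(fmat.ids, np.log1p(fmat.values), kind="dissimilarity_lnF")
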
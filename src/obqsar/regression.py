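"""The three model families: stepwise MLR, PLS, and ε-SVR with RBF kernel.

All three are implemented here rather than wrapped, because the
selection mechanics (partial-F stepwise entry/removal, Q²-maximising
latent-variable count, cross-validated log2 grid search) are the point of
the pipeline and need to be inspectable end to end.

* :func:`stepwise_mlr` — forward entry / backward removal on partial-F
  p-values (enter when p <= 0.05, remove when p >= 0.10 by default), with
  final ordinary-least-squares coefficients on the raw descriptor scales.
* :func:`fit_pls` — PLS1 by NIPALS with deflation; predictors are
  z-scored with training statistics.  At full rank the predictions
  coincide with least squares.
* :func:`fit_svr` — the ε-insensitive support vector regression dual
  (box constraints [0, C], equality constraint) solved by a pairwise
  working-set method (SMO) on the net dual coefficients
  ``beta_i = alpha_i - alpha_i*``; RBF kernel
  ``K(x, x') = exp(-gamma * ||x - x'||^2)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist

__all__ = [
    "EmptyFeatureError",
    "MLRModel",
    "PLSModel",
    "SVRModel",
    "prefilter_descriptors",
    "stepwise_mlr",
    "fit_pls",
    "select_pls_components",
    "fit_svr",
    "grid_search_svr",
    "stratified_folds",
]


class EmptyFeatureError(ValueError):
    """Every descriptor column was filtered away."""


# --------------------------------------------------------------------------
# descriptor pre-filtering


def prefilter_descriptors(
    X: np.ndarray,
    names: Sequence[str] | None = None,
    zero_fraction_threshold: float = 0.8,
) -> tuple[np.ndarray, list[str]]:
    """Drop descriptor columns that are zero in more than the given fraction.

    Sparse functional-group counts that are zero for almost every compound
    carry next to no information and destabilise stepwise selection.  A
    column is dropped when its zero fraction strictly exceeds the
    threshold (a column at exactly the threshold is kept).
    """
    X = np.asarray(X, dtype=float)
    if names is None:
        names = [f"X{j}" for j in range(X.shape[1])]
    frac_zero = (X == 0).mean(axis=0)
    keep = frac_zero <= zero_fraction_threshold
    if not keep.any():
        raise EmptyFeatureError("all descriptor columns exceeded the zero-fraction threshold")
    return X[:, keep], [nm for nm, k in zip(names, keep) if k]


# --------------------------------------------------------------------------
# stepwise multiple linear regression


@dataclass
class MLRModel:
    selected_terms: list[str]
    coefficients: np.ndarray  # per selected term, raw descriptor scale
    intercept: float
    selection_trace: list[dict] = field(default_factory=list)
    feature_names: list[str] = field(default_factory=list)

    @property
    def n_params(self) -> int:
        return len(self.selected_terms)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        cols = [self.feature_names.index(t) for t in self.selected_terms]
        return self.intercept + X[:, cols] @ self.coefficients

    def to_dict(self) -> dict:
        return {
            "kind": "mlr",
            "selected_terms": self.selected_terms,
            "coefficients": [float(c) for c in self.coefficients],
            "intercept": float(self.intercept),
            "feature_names": self.feature_names,
        }


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, int]:
    """Least squares with intercept: (coefs incl. intercept first, RSS, rank)."""
    A = np.column_stack([np.ones(len(y)), X]) if X.shape[1] else np.ones((len(y), 1))
    coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    rss = float(((y - A @ coef) ** 2).sum())
    return coef, rss, rank


def _partial_f_p(rss_small: float, rss_big: float, df_resid_big: int) -> float:
    """p-value of the partial F statistic for one added term."""
    if df_resid_big <= 0:
        return np.nan
    num = rss_small - rss_big
    if rss_big <= 1e-30:
        return 0.0 if num > 1e-30 else np.nan
    F = num / (rss_big / df_resid_big)
    if not np.isfinite(F) or F < 0:
        return np.nan
    return float(stats.f.sf(F, 1, df_resid_big))


def stepwise_mlr(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: Sequence[str] | None = None,
    *,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    max_steps: int = 200,
) -> MLRModel:
    """Classic forward-entry / backward-removal stepwise regression.

    At each round the unselected candidate with the smallest partial-F
    p-value enters if p <= ``p_enter`` (ties to the earlier column), then
    included terms with removal p >= ``p_remove`` leave, worst first.
    Candidates that would make the design rank-deficient are skipped with a
    trace note.  Final coefficients are the OLS fit on the selected set.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if feature_names is None:
        feature_names = [f"X{j}" for j in range(p)]
    feature_names = list(feature_names)

    selected: list[int] = []
    trace: list[dict] = []
    seen: set[frozenset] = set()
    # below this, the fit is exact and partial-F tests are numerical noise
    tss = float(((y - y.mean()) ** 2).sum())
    zero_tol = 1e-10 * max(tss, 1e-12)

    for _ in range(max_steps):
        moved = False
        k = len(selected)
        _, rss_cur, _ = _ols(X[:, selected], y)
        df_new = n - (k + 1) - 1
        if df_new > 0 and rss_cur > zero_tol:
            best_j, best_p = -1, np.inf
            for j in range(p):
                if j in selected:
                    continue
                coef, rss_j, rank = _ols(X[:, selected + [j]], y)
                if rank < k + 2:
                    trace.append({"event": "skip_rank_deficient", "term": feature_names[j]})
                    continue
                pj = _partial_f_p(rss_cur, rss_j, df_new)
                if np.isfinite(pj) and pj < best_p:
                    best_j, best_p = j, pj
            if best_j >= 0 and best_p <= p_enter:
                selected.append(best_j)
                trace.append(
                    {"event": "enter", "term": feature_names[best_j], "p": best_p}
                )
                moved = True

        # backward removal until stable
        while selected:
            k = len(selected)
            _, rss_full, _ = _ols(X[:, selected], y)
            df_full = n - k - 1
            worst_t, worst_p = -1, -np.inf
            for t in selected:
                others = [s for s in selected if s != t]
                _, rss_wo, _ = _ols(X[:, others], y)
                if rss_full <= zero_tol:
                    # exact fit: a term is redundant iff the fit stays exact
                    pt = 1.0 if rss_wo <= zero_tol else 0.0
                else:
                    pt = _partial_f_p(rss_wo, rss_full, df_full)
                    pt = 1.0 if not np.isfinite(pt) else pt
                if pt > worst_p:
                    worst_t, worst_p = t, pt
            if worst_t >= 0 and worst_p >= p_remove:
                selected.remove(worst_t)
                trace.append(
                    {"event": "remove", "term": feature_names[worst_t], "p": worst_p}
                )
                moved = True
            else:
                break

        state = frozenset(selected)
        if not moved or state in seen:
            break
        seen.add(state)

    coef, _, _ = _ols(X[:, selected], y)
    return MLRModel(
        selected_terms=[feature_names[j] for j in selected],
        coefficients=coef[1:],
        intercept=float(coef[0]),
        selection_trace=trace,
        feature_names=feature_names,
    )


# --------------------------------------------------------------------------
# partial least squares (PLS1, NIPALS)


@dataclass
class PLSModel:
    n_latent: int
    x_weights: np.ndarray  # (p, a)
    x_loadings: np.ndarray  # (p, a)
    y_loadings: np.ndarray  # (a,)
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    coefficients: np.ndarray  # (p,), on the scaled-X scale
    q2_by_lv: dict[int, float] = field(default_factory=dict)

    def scores(self, X: np.ndarray) -> np.ndarray:
        """Latent-variable scores T for new data (same recursion as training)."""
        Xs = (np.asarray(X, dtype=float) - self.x_mean) / self.x_scale
        T = np.empty((Xs.shape[0], self.n_latent))
        E = Xs.copy()
        for a in range(self.n_latent):
            t = E @ self.x_weights[:, a]
            T[:, a] = t
            E = E - np.outer(t, self.x_loadings[:, a])
        return T

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, dtype=float) - self.x_mean) / self.x_scale
        return self.y_mean + Xs @ self.coefficients

    def to_dict(self) -> dict:
        return {
            "kind": "pls",
            "n_latent": int(self.n_latent),
            "coefficients": self.coefficients.tolist(),
            "x_mean": self.x_mean.tolist(),
            "x_scale": self.x_scale.tolist(),
            "y_mean": float(self.y_mean),
            "q2_by_lv": {str(k): float(v) for k, v in self.q2_by_lv.items()},
        }


def fit_pls(X: np.ndarray, y: np.ndarray, n_latent: int, *, scale: bool = True) -> PLSModel:
    """PLS1 by NIPALS: sequential covariance-maximising components with deflation.

    ``n_latent`` greater than the rank of the (centred, scaled) predictor
    block is capped with a warning.  If y has no covariance left with the
    deflated predictors, extraction stops early and the missing components
    contribute nothing (predictions fall back toward mean y).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0, ddof=1) if scale else np.ones(X.shape[1])
    x_scale = np.where(x_scale > 0, x_scale, 1.0)
    y_mean = float(y.mean())
    E = (X - x_mean) / x_scale
    f = y - y_mean

    rank = int(np.linalg.matrix_rank(E)) if min(E.shape) else 0
    if n_latent > rank:
        warnings.warn(
            f"n_latent={n_latent} exceeds rank {rank}; capping", stacklevel=2
        )
        n_latent = max(rank, 0)

    p = X.shape[1]
    W = np.zeros((p, n_latent))
    P = np.zeros((p, n_latent))
    q = np.zeros(n_latent)
    used = 0
    for a in range(n_latent):
        w = E.T @ f
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            break  # no covariance left to model
        w /= nw
        t = E @ w
        tt = float(t @ t)
        if tt < 1e-24:
            break
        pl = E.T @ t / tt
        ql = float(f @ t / tt)
        E = E - np.outer(t, pl)
        f = f - ql * t
        W[:, a], P[:, a], q[a] = w, pl, ql
        used += 1
    W, P, q = W[:, :used], P[:, :used], q[:used]
    if used:
        coefficients = W @ np.linalg.solve(P.T @ W, q)
    else:
        coefficients = np.zeros(p)
    return PLSModel(
        n_latent=used,
        x_weights=W,
        x_loadings=P,
        y_loadings=q,
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        coefficients=coefficients,
    )


def stratified_folds(y: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Fold labels stratified by the response's quantile blocks, seeded.

    Compounds are sorted by y; within each consecutive block of
    ``n_folds`` the fold labels are a fresh random permutation, so every
    fold spans the whole response range.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n_folds > n:
        raise ValueError(f"cannot make {n_folds} folds from {n} samples")
    rng = np.random.default_rng(seed)
    order = np.argsort(y, kind="stable")
    folds = np.empty(n, dtype=int)
    for start in range(0, n, n_folds):
        block = order[start : start + n_folds]
        folds[block] = rng.permutation(n_folds)[: len(block)]
    return folds


def select_pls_components(
    X: np.ndarray,
    y: np.ndarray,
    *,
    lv_range: Sequence[int] = tuple(range(3, 21)),
    cv_folds: int = 5,
    seed: int = 0,
    parsimony_tol: float = 0.01,
) -> tuple[int, dict[int, float]]:
    """Choose the latent-variable count maximising cross-validated Q².

    Q² = 1 - PRESS / TSS from seeded, response-stratified folds.  Among
    counts whose Q² is within ``parsimony_tol`` of the maximum, the
    smallest is returned.  The full Q²-vs-count curve is returned alongside.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    max_rank = min(n - max(2, int(np.ceil(n / cv_folds))) - 1, X.shape[1])
    lvs = sorted({int(a) for a in lv_range if 1 <= a <= max(max_rank, 1)})
    if not lvs:
        raise ValueError("lv_range is empty after rank capping")
    folds = stratified_folds(y, cv_folds, seed)
    tss = float(((y - y.mean()) ** 2).sum())
    press = {a: 0.0 for a in lvs}
    for f in range(cv_folds):
        tr, te = folds != f, folds == f
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_pls(X[tr], y[tr], max(lvs))
        # reuse one deflation pass: predictions for every truncation depth
        T = model.scores(X[te])
        base = np.full(te.sum(), model.y_mean)
        for a in lvs:
            a_eff = min(a, model.n_latent)
            pred = base + T[:, :a_eff] @ model.y_loadings[:a_eff]
            press[a] += float(((y[te] - pred) ** 2).sum())
    q2 = {a: 1.0 - press[a] / tss for a in lvs}
    best = max(q2.values())
    chosen = min(a for a in lvs if q2[a] >= best - parsimony_tol)
    return chosen, q2


# --------------------------------------------------------------------------
# epsilon-SVR with RBF kernel (SMO working-set solver)


@dataclass
class SVRModel:
    C: float
    gamma: float
    epsilon: float
    dual_coef: np.ndarray  # beta_i = alpha_i - alpha_i^* for support vectors
    bias: float
    support_vectors: np.ndarray  # scaled feature rows
    x_mean: np.ndarray
    x_scale: np.ndarray
    n_iter: int = 0

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, dtype=float) - self.x_mean) / self.x_scale
        if len(self.dual_coef) == 0:
            return np.full(Xs.shape[0], self.bias)
        K = _rbf_kernel(Xs, self.support_vectors, self.gamma)
        return K @ self.dual_coef + self.bias

    def to_dict(self) -> dict:
        return {
            "kind": "svr",
            "C": float(self.C),
            "gamma": float(self.gamma),
            "epsilon": float(self.epsilon),
            "dual_coef": self.dual_coef.tolist(),
            "bias": float(self.bias),
            "support_vectors": self.support_vectors.tolist(),
            "x_mean": self.x_mean.tolist(),
            "x_scale": self.x_scale.tolist(),
        }


def _rbf_kernel(A: np.ndarray, B: np.ndarray, gamma: float) -> np.ndarray:
    return np.exp(-gamma * cdist(A, B, "sqeuclidean"))


def _solve_svr_dual(
    K: np.ndarray,
    y: np.ndarray,
    C: float,
    epsilon: float,
    tol: float = 1e-6,
    max_iter: int = 100_000,
) -> tuple[np.ndarray, float, int]:
    """Minimise 0.5 b'Kb - y'b + eps*||b||_1  s.t.  sum(b)=0, |b_i| <= C.

    Pairwise (SMO-style) updates along e_i - e_j keep the equality
    constraint exact and the box constraints exact by clipping; the
    one-dimensional subproblem is piecewise quadratic (kinks where a
    coefficient crosses zero) and is solved by evaluating the segment
    minimisers and breakpoints.
    """
    n = len(y)
    beta = np.zeros(n)
    F = -y.copy()  # F = K beta - y

    def g_up(b, f):  # right-derivative along +e_i
        return f + np.where(b >= 0, epsilon, -epsilon)

    def g_dn(b, f):  # right-derivative along -e_i, negated (left derivative)
        return f + np.where(b > 0, epsilon, -epsilon)

    it = 0
    for it in range(1, max_iter + 1):
        up_ok = beta < C - 1e-14
        dn_ok = beta > -C + 1e-14
        gu = np.where(up_ok, g_up(beta, F), np.inf)
        gd = np.where(dn_ok, g_dn(beta, F), -np.inf)
        i = int(np.argmin(gu))
        j = int(np.argmax(gd))
        gap = gd[j] - gu[i]
        if gap <= tol:
            break
        t_max = min(C - beta[i], beta[j] + C)
        if t_max <= 0:
            break
        eta = K[i, i] + K[j, j] - 2.0 * K[i, j]
        # candidate step sizes: segment breakpoints, box edge, and the
        # unconstrained minimiser of each smooth segment
        cands = {t_max}
        if beta[i] < 0 and 0 < -beta[i] < t_max:
            cands.add(-beta[i])
        if beta[j] > 0 and 0 < beta[j] < t_max:
            cands.add(beta[j])
        if eta > 1e-14:
            for si in (-1.0, 1.0):
                for sj in (-1.0, 1.0):
                    t = -(F[i] - F[j] + epsilon * (si - sj)) / eta
                    if 0 < t < t_max:
                        cands.add(t)

        def delta(t: float) -> float:
            return (
                0.5 * eta * t * t
                + (F[i] - F[j]) * t
                + epsilon * (abs(beta[i] + t) - abs(beta[i]))
                + epsilon * (abs(beta[j] - t) - abs(beta[j]))
            )

        t_best = min(cands, key=delta)
        if delta(t_best) >= -1e-15:
            break
        beta[i] = np.clip(beta[i] + t_best, -C, C)
        beta[j] = np.clip(beta[j] - t_best, -C, C)
        F += t_best * (K[:, i] - K[:, j])

    # bias from free support vectors, else the midpoint of the KKT interval
    free = (np.abs(beta) > 1e-9) & (np.abs(beta) < C - 1e-9)
    if free.any():
        # K beta = F + y, and for free vectors y_i - f(x_i) = eps*sign(beta_i)
        b = float(np.mean(-epsilon * np.sign(beta[free]) - F[free]))
    else:
        gu = np.where(beta < C - 1e-14, g_up(beta, F), np.inf)
        gd = np.where(beta > -C + 1e-14, g_dn(beta, F), -np.inf)
        b = float(-(np.min(gu) + np.max(gd)) / 2.0)
    return beta, b, it


def fit_svr(
    X: np.ndarray,
    y: np.ndarray,
    C: float,
    gamma: float,
    epsilon: float = 0.1,
    *,
    tol: float = 1e-6,
    max_iter: int = 100_000,
) -> SVRModel:
    """Fit ε-SVR with an RBF kernel; predictors are z-scored internally."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in SVR inputs")
    if C <= 0 or gamma <= 0 or epsilon < 0:
        raise ValueError("require C > 0, gamma > 0, epsilon >= 0")
    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0, ddof=1)
    x_scale = np.where(x_scale > 0, x_scale, 1.0)
    Xs = (X - x_mean) / x_scale
    K = _rbf_kernel(Xs, Xs, gamma)
    beta, b, n_iter = _solve_svr_dual(K, y, C, epsilon, tol=tol, max_iter=max_iter)
    sv = np.abs(beta) > 1e-10
    return SVRModel(
        C=C,
        gamma=gamma,
        epsilon=epsilon,
        dual_coef=beta[sv],
        bias=b,
        support_vectors=Xs[sv],
        x_mean=x_mean,
        x_scale=x_scale,
        n_iter=n_iter,
    )


def grid_search_svr(
    X: np.ndarray,
    y: np.ndarray,
    *,
    log2C_range: tuple[int, int] = (-4, 12),
    log2gamma_range: tuple[int, int] = (-12, 8),
    step: int = 1,
    cv_folds: int = 5,
    epsilon: float = 0.1,
    seed: int = 0,
    loo: bool = False,
) -> tuple[float, float, "np.ndarray", list[int], list[int]]:
    """Exhaustive (C, gamma) search on an integer log2 grid by CV error.

    The score is the cross-validated standard error of prediction (pooled
    held-out RMSE); folds are seeded and stratified by the response.  With
    ``loo=True`` leave-one-out replaces k-fold.  Ties break toward smaller
    C, then smaller gamma.  Returns (C, gamma, SEP surface, log2C axis,
    log2gamma axis).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    folds = np.arange(n) if loo else stratified_folds(y, cv_folds, seed)
    n_folds = n if loo else cv_folds
    if n_folds > n:
        raise ValueError("more folds than samples")
    c_axis = list(range(log2C_range[0], log2C_range[1] + 1, step))
    g_axis = list(range(log2gamma_range[0], log2gamma_range[1] + 1, step))
    if not c_axis or not g_axis:
        raise ValueError("empty grid")
    surface = np.full((len(c_axis), len(g_axis)), np.nan)
    # precompute per-fold squared-distance matrices once; kernels per gamma
    # are then just exponentials of a shared matrix
    fold_data = []
    for f in range(n_folds):
        tr, te = folds != f, folds == f
        mu = X[tr].mean(axis=0)
        sd = X[tr].std(axis=0, ddof=1)
        sd = np.where(sd > 0, sd, 1.0)
        Xtr, Xte = (X[tr] - mu) / sd, (X[te] - mu) / sd
        fold_data.append(
            (
                cdist(Xtr, Xtr, "sqeuclidean"),
                cdist(Xte, Xtr, "sqeuclidean"),
                y[tr],
                y[te],
            )
        )
    best = None
    for gi, lg in enumerate(g_axis):
        gamma = 2.0**lg
        kernels = [
            (np.exp(-gamma * d2tr), np.exp(-gamma * d2te), ytr, yte)
            for d2tr, d2te, ytr, yte in fold_data
        ]
        for ci, lc in enumerate(c_axis):
            C = 2.0**lc
            sse = 0.0
            for Ktr, Kte, ytr, yte in kernels:
                # looser tolerance and capped iterations: approximate solves
                # are ample for ranking hyperparameter candidates
                beta, b, _ = _solve_svr_dual(
                    Ktr, ytr, C, epsilon, tol=1e-3, max_iter=20_000
                )
                resid = yte - (Kte @ beta + b)
                sse += float((resid**2).sum())
            sep = np.sqrt(sse / n)
            surface[ci, gi] = sep
            if (
                best is None
                or sep < best[0] - 1e-15
                or (abs(sep - best[0]) <= 1e-15 and (C, gamma) < (best[1], best[2]))
            ):
                best = (sep, C, gamma)
    assert best is not None
    return best[1], best[2], surface, c_axis, g_axis
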
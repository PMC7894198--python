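"""Five feature-ranking methods for subjects x features tables.

Supervised: LASSO (L1-penalized least squares on the labels), SVM-RFE
(backward elimination by linear-SVM weight magnitude), CFS (greedy forward
search on a correlation-based merit).  Unsupervised: FSASL (joint global
sparse reconstruction + local probabilistic neighborhoods with an L2,1
projection) and LLCFS (local-learning clustering with simplex-constrained
feature weights).

Every method returns a :class:`Ranking`: a true permutation of feature
indices, best first, with per-feature scores.  Ties are broken by
ascending feature index.  All methods assume features were standardized
(zero mean, unit sd) beforehand — :func:`standardize` records the
statistics so test folds can be transformed with train-fold parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from sklearn.linear_model import Lasso
from sklearn.svm import SVC

__all__ = [
    "Ranking", "standardize", "apply_standardization",
    "lasso_rank", "svm_rfe_rank", "fsasl_select", "llcfs_weights", "cfs_rank",
    "get_ranker", "FS_METHODS",
]


@dataclass
class Ranking:
    """Permutation of feature indices (best first) with scores."""

    order: np.ndarray
    scores: np.ndarray
    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order, dtype=np.int64)
        d = self.order.size
        if not np.array_equal(np.sort(self.order), np.arange(d)):
            raise ValueError("ranking order must be a permutation of 0..D-1")

    def top(self, k: int) -> np.ndarray:
        return self.order[:k]


def standardize(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise z-scoring; zero-sd columns map to zero (sd recorded as 1)."""
    x = np.asarray(x, dtype=float)
    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (x - mean) / sd_safe, mean, sd_safe


def apply_standardization(x: np.ndarray, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    return (np.asarray(x, dtype=float) - mean) / sd


def _rank_with_ties(primary: np.ndarray, secondary: np.ndarray | None = None) -> np.ndarray:
    """Descending order on primary (then secondary), ties by ascending index."""
    d = primary.size
    keys = [np.arange(d)]
    if secondary is not None:
        keys.append(-secondary)
    keys.append(-primary)
    return np.lexsort(tuple(keys))


def _binary_response(y: np.ndarray) -> np.ndarray:
    """Encode two-class labels as -1/+1 (order of np.unique)."""
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"expected a binary label vector, got classes {classes}")
    return np.where(np.asarray(y) == classes[1], 1.0, -1.0)


# ---------------------------------------------------------------------------
# LASSO
# ---------------------------------------------------------------------------

def lasso_rank(x: np.ndarray, y: np.ndarray, alpha: float = 0.01
               ) -> tuple[Ranking, np.ndarray, float]:
    """L1-penalized least-squares ranking by coefficient magnitude.

    The penalized objective follows the 1/(2n) residual normalization of
    cyclic coordinate descent solvers: ``(1/2n)||y - Xb - b0||^2 + alpha
    ||b||_1``, so all coefficients vanish exactly when ``alpha >=
    max_j |x_j^T (y - ybar)| / n``.  Zero-coefficient features are ranked
    after the active set by absolute marginal correlation with ``y``.
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    x = np.asarray(x, dtype=float)
    yv = _binary_response(y) if np.asarray(y).dtype.kind in "USO" else np.asarray(y, dtype=float)
    if alpha == 0:
        alpha = 1e-12  # coordinate descent needs a strictly positive penalty
    model = Lasso(alpha=alpha, fit_intercept=True, max_iter=100000, tol=1e-10)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(x, yv)
    beta = model.coef_.copy()
    sd = x.std(axis=0)
    yc = yv - yv.mean()
    denom = sd * yc.std() * x.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        marginal = np.abs(np.where(denom > 0, (x - x.mean(0)).T @ yc / np.where(denom > 0, denom, 1.0), 0.0))
    active = np.abs(beta) > 0
    # active features by |beta| desc, then inactive by |marginal corr| desc
    primary = np.where(active, np.abs(beta) + 1.0 + marginal.max(initial=0.0), marginal)
    order = _rank_with_ties(primary)
    return (Ranking(order, primary, "lasso", {"alpha": alpha}),
            beta, float(model.intercept_))


# ---------------------------------------------------------------------------
# SVM-RFE
# ---------------------------------------------------------------------------

def svm_rfe_rank(x: np.ndarray, y: np.ndarray, c: float = 1.0,
                 step: int | float = 1) -> Ranking:
    """Recursive feature elimination driven by linear-SVM weights.

    Repeatedly fits a linear SVM on the surviving features, scores each by
    its squared weight, removes the lowest-scoring ``step`` features (a
    fraction of survivors if ``step`` < 1), and reverses the elimination
    order into a ranking.  Features are re-standardized at each round so a
    constant feature gets zero weight and is eliminated first.
    """
    x = np.asarray(x, dtype=float)
    yv = _binary_response(y)
    d = x.shape[1]
    if d < 2:
        raise ValueError("SVM-RFE needs at least two features")
    eliminated: list[int] = []
    remaining = np.arange(d)
    while remaining.size > 0:
        if remaining.size == 1:
            eliminated.append(int(remaining[0]))
            break
        xs, _, _ = standardize(x[:, remaining])
        svm = SVC(kernel="linear", C=c)
        svm.fit(xs, yv)
        scores = svm.coef_[0] ** 2
        if isinstance(step, float) and 0 < step < 1:
            n_drop = max(1, int(step * remaining.size))
        else:
            n_drop = max(1, int(step))
        n_drop = min(n_drop, remaining.size - 1) if remaining.size > 1 else 1
        # drop lowest scores; among ties, higher original index goes first
        drop_order = np.lexsort((-remaining, scores))[:n_drop]
        # within one round, record worse (lower-score) features as eliminated earlier
        keys = np.lexsort((-remaining[drop_order], scores[drop_order]))
        for i in keys:
            eliminated.append(int(remaining[drop_order[i]]))
        remaining = np.delete(remaining, drop_order)
    order = np.asarray(eliminated[::-1], dtype=np.int64)
    ranks = np.empty(d)
    ranks[order] = np.arange(d, 0, -1)
    return Ranking(order, ranks, "svmrfe", {"C": c, "step": step})


# ---------------------------------------------------------------------------
# FSASL
# ---------------------------------------------------------------------------

def _project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection onto the probability simplex."""
    u = np.sort(v)[::-1]
    css = np.cumsum(u) - 1.0
    idx = np.arange(1, v.size + 1)
    cond = u - css / idx > 0
    rho = idx[cond][-1]
    theta = css[rho - 1] / rho
    return np.clip(v - theta, 0.0, None)


@dataclass
class FsaslResult:
    ranking: Ranking
    w: np.ndarray           # D x d_out projection
    s: np.ndarray           # n x n sparse reconstruction codes, S_ii = 0
    p: np.ndarray           # n x n probabilistic neighborhoods, rows on simplex
    objective_history: list[float]


def _fsasl_objective(xd: np.ndarray, w: np.ndarray, s: np.ndarray, p: np.ndarray,
                     alpha: float, beta: float, gamma: float, mu: float) -> float:
    z = w.T @ xd                                     # d_out x n projected data
    recon = float(np.sum((z - z @ s) ** 2))
    sparsity = alpha * float(np.abs(s).sum())
    d2 = _pairwise_sq(z)
    local = beta * float(np.sum(d2 * p) + mu * np.sum(p ** 2))
    l21 = gamma * float(np.sqrt((w ** 2).sum(axis=1)).sum())
    return recon + sparsity + local + l21


def _pairwise_sq(z: np.ndarray) -> np.ndarray:
    g = z.T @ z
    sq = np.diag(g)
    d2 = sq[:, None] + sq[None, :] - 2 * g
    return np.clip(d2, 0.0, None)


def fsasl_select(x: np.ndarray, alpha: float = 1.0, beta: float = 1.0,
                 gamma: float = 1.0, mu: float = 0.5, d_out: int = 5,
                 max_sweeps: int = 10, tol: float = 1e-6) -> FsaslResult:
    """Unsupervised selection with adaptive global + local structure.

    Alternating minimization of

        ||W'X - W'XS||^2 + alpha ||S||_1
          + beta sum_ij (||W'x_i - W'x_j||^2 P_ij + mu P_ij^2)
          + gamma ||W||_{2,1}
        s.t. S_ii = 0,  P 1 = 1,  P >= 0,  W' X X' W = I

    (i) S: per-sample L1-regularized reconstruction in the projected space;
    (ii) P: closed-form row-wise simplex projection of -d^2/(2 mu)
    (self-neighborhood excluded); (iii) W: L2,1-reweighted generalized
    eigenproblem on the structured scatter, constrained by a ridge-
    stabilized X X'.  Features ranked by descending row L2-norm of W.
    """
    xs = np.asarray(x, dtype=float)
    n, d = xs.shape
    d_out = min(d_out, d)
    xd = xs.T                                        # D x n (features x samples)
    b_mat = xd @ xd.T
    b_mat = b_mat + (1e-6 * np.trace(b_mat) / max(d, 1) + 1e-12) * np.eye(d)

    s = np.zeros((n, n))
    p = np.full((n, n), 1.0 / max(n - 1, 1))
    np.fill_diagonal(p, 0.0)
    w = _fsasl_w_update(xd, b_mat, s, p, beta, gamma, d_out, w_prev=None)

    history: list[float] = []
    lasso_alpha_scale = 1.0 / (2.0 * d_out)          # match min ||.||^2 + alpha||.||_1
    for _ in range(max_sweeps):
        z = w.T @ xd                                 # d_out x n
        # (i) S update: column-separable lasso with the diagonal excluded
        for i in range(n):
            zi = z[:, i]
            others = np.delete(np.arange(n), i)
            lam = max(alpha * lasso_alpha_scale, 1e-12)
            model = Lasso(alpha=lam, fit_intercept=False, max_iter=5000, tol=1e-8)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(z[:, others], zi)
            s[others, i] = model.coef_
            s[i, i] = 0.0
        # (ii) P update: row-wise simplex projection, self excluded
        d2 = _pairwise_sq(w.T @ xd)
        for i in range(n):
            row = -d2[i] / (2.0 * mu)
            row[i] = -np.inf                         # forbid self-neighborhood
            finite = np.isfinite(row)
            proj = _project_simplex(row[finite])
            p[i, finite] = proj
            p[i, i] = 0.0
        # (iii) W update (L2,1 via iterative reweighting)
        w = _fsasl_w_update(xd, b_mat, s, p, beta, gamma, d_out, w_prev=w)
        history.append(_fsasl_objective(xd, w, s, p, alpha, beta, gamma, mu))
        if len(history) >= 2 and abs(history[-2] - history[-1]) <= tol * max(1.0, abs(history[-2])):
            break
    else:
        if len(history) >= 2 and history[-1] > history[0]:
            warnings.warn("FSASL did not converge within max_sweeps; "
                          "returning best iterate", stacklevel=2)
    row_norms = np.sqrt((w ** 2).sum(axis=1))
    order = _rank_with_ties(row_norms)
    ranking = Ranking(order, row_norms, "fsasl",
                      {"alpha": alpha, "beta": beta, "gamma": gamma,
                       "mu": mu, "d_out": d_out})
    return FsaslResult(ranking, w, s, p, history)


def _fsasl_w_update(xd: np.ndarray, b_mat: np.ndarray, s: np.ndarray,
                    p: np.ndarray, beta: float, gamma: float, d_out: int,
                    w_prev: np.ndarray | None, n_irls: int = 2) -> np.ndarray:
    n = s.shape[0]
    ident = np.eye(n)
    rs = ident - s
    p_sym = (p + p.T) / 2.0
    lap = np.diag(p_sym.sum(axis=1)) - p_sym
    m = xd @ (rs @ rs.T + beta * lap) @ xd.T
    m = (m + m.T) / 2.0
    w = w_prev
    for _ in range(n_irls):
        if w is None:
            dg = np.eye(xd.shape[0])
        else:
            norms = np.sqrt((w ** 2).sum(axis=1))
            dg = np.diag(1.0 / (2.0 * np.maximum(norms, 1e-8)))
        a = m + gamma * dg
        a = (a + a.T) / 2.0
        _, vecs = eigh(a, b_mat, subset_by_index=[0, d_out - 1])
        w = vecs
    return w


# ---------------------------------------------------------------------------
# LLCFS
# ---------------------------------------------------------------------------

def llcfs_weights(x: np.ndarray, k_neighbors: int = 5, n_clusters: int = 2,
                  max_iter: int = 4, tol: float = 1e-6, reg: float = 1.0,
                  seed: int = 0) -> tuple[np.ndarray, Ranking]:
    """Local-learning clustering-based feature weights on the simplex.

    Alternates (i) k-nearest-neighbor graph construction in the z-weighted
    feature space, (ii) cluster-indicator update (seeded k-means on the
    weighted data, the discretized stand-in for the relaxed indicator
    problem), and (iii) per-sample kernel ridge solves of the indicators on
    each neighborhood followed by the closed-form simplex update
    ``z_f = sqrt(h_f) / sum_g sqrt(h_g)``, where ``h_f`` aggregates the
    squared local regression weights of feature ``f`` (the minimizer of
    ``sum_f h_f / z_f`` subject to ``1'z = 1, z >= 0``).

    The z update is multiplicative, so weights concentrate exponentially on
    features the local models rely on; ``max_iter`` is deliberately small
    to keep pure-noise inputs from concentrating spuriously.
    """
    xs = np.asarray(x, dtype=float)
    n, d = xs.shape
    if not 0 < k_neighbors < n:
        raise ValueError("k_neighbors must satisfy 0 < k < n_samples")
    from sklearn.cluster import KMeans
    z = np.full(d, 1.0 / d)
    hist_z = z.copy()
    for _ in range(max_iter):
        # (i) kNN graph in the z-weighted feature space
        xw = xs * np.sqrt(z)
        d2 = _pairwise_sq(xw.T)
        np.fill_diagonal(d2, np.inf)
        nbr = np.argsort(d2, axis=1, kind="stable")[:, :k_neighbors]
        if nbr.size == 0:
            raise ValueError("empty neighborhood")
        # (ii) discrete cluster indicators on the weighted data
        km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
        y_ind = np.eye(n_clusters)[km.fit(xw).labels_]
        # (iii) local ridge solves on {i} U kNN(i); aggregate squared weights
        h = np.zeros(d)
        for i in range(n):
            idx = np.concatenate(([i], nbr[i]))
            mloc = idx.size
            cm = np.eye(mloc) - np.full((mloc, mloc), 1.0 / mloc)
            xc = cm @ xs[idx]
            k_loc = (xc * z) @ xc.T                  # X~ diag(z) X~'
            yc = cm @ y_ind[idx]
            dual = np.linalg.solve(k_loc + reg * np.eye(mloc), yc)
            w_loc = (xc * z).T @ dual                # d x c local weights
            h += (w_loc ** 2).sum(axis=1)
        if h.sum() <= 0:
            z = np.full(d, 1.0 / d)
        else:
            root = np.sqrt(h)
            z = root / root.sum()
        if np.abs(z - hist_z).max() < tol:
            break
        hist_z = z.copy()
    order = _rank_with_ties(z)
    return z, Ranking(order, z, "llcfs",
                      {"k_neighbors": k_neighbors, "n_clusters": n_clusters})


# ---------------------------------------------------------------------------
# CFS
# ---------------------------------------------------------------------------

def cfs_rank(x: np.ndarray, y: np.ndarray) -> Ranking:
    """Greedy forward search on the correlation-based merit

        merit(S) = k rbar_cf / sqrt(k + k (k-1) rbar_ff)

    where ``rbar_cf`` is the mean absolute feature-class correlation of the
    selected subset and ``rbar_ff`` the mean absolute feature-feature
    correlation.  Selection stops when no candidate improves the merit;
    unselected features are appended by descending ``|r_cf|``.
    """
    xs = np.asarray(x, dtype=float)
    yv = _binary_response(y) if np.asarray(y).dtype.kind in "USO" else np.asarray(y, dtype=float)
    n, d = xs.shape
    xc = xs - xs.mean(axis=0)
    yc = yv - yv.mean()
    sx = xc.std(axis=0)
    sy = yc.std()
    with np.errstate(invalid="ignore", divide="ignore"):
        r_cf = np.abs(np.where((sx > 0) & (sy > 0), xc.T @ yc / (n * np.where(sx > 0, sx, 1.0) * (sy if sy > 0 else 1.0)), 0.0))
        xn = np.where(sx > 0, 1.0, 0.0) * xc / np.where(sx > 0, sx, 1.0)
        r_ff = np.abs(xn.T @ xn / n)
    selected: list[int] = []
    available = np.ones(d, dtype=bool)
    sum_cf = 0.0
    cross_ff = np.zeros(d)  # sum of |r_ff| between each candidate and selected set
    sum_ff_pairs = 0.0
    best_merit = -np.inf
    while available.any():
        k = len(selected) + 1
        cand_cf = (sum_cf + r_cf) / k
        cand_ff_pairs = sum_ff_pairs + cross_ff
        n_pairs = k * (k - 1) / 2.0
        rbar_ff = np.where(n_pairs > 0, cand_ff_pairs / max(n_pairs, 1.0), 0.0)
        merit = k * cand_cf / np.sqrt(k + k * (k - 1) * rbar_ff)
        merit = np.where(available, merit, -np.inf)
        j = int(np.argmax(merit))  # ties -> lowest index
        if merit[j] <= best_merit + 1e-12:
            break
        best_merit = float(merit[j])
        selected.append(j)
        available[j] = False
        sum_cf += r_cf[j]
        sum_ff_pairs += cross_ff[j]
        cross_ff += r_ff[:, j]
    rest = np.flatnonzero(available)
    rest = rest[_rank_with_ties(r_cf[rest])]
    order = np.concatenate([np.asarray(selected, dtype=np.int64),
                            rest.astype(np.int64)])
    scores = np.empty(d)
    scores[order] = np.arange(d, 0, -1)
    return Ranking(order, scores, "cfs", {})


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

FS_METHODS = ("lasso", "svmrfe", "fsasl", "llcfs", "cfs")


def get_ranker(method: str, **kwargs):
    """A uniform callable ``(X_train_std, y_train) -> Ranking``.

    FSASL and LLCFS are unsupervised and ignore the labels (they still only
    ever see training folds inside cross-validation, to rule out selection
    bias).
    """
    method = method.lower()
    if method == "lasso":
        return lambda x, y: lasso_rank(x, y, **kwargs)[0]
    if method in ("svmrfe", "svm-rfe", "svm_rfe"):
        return lambda x, y: svm_rfe_rank(x, y, **kwargs)
    if method == "fsasl":
        return lambda x, y: fsasl_select(x, **kwargs).ranking
    if method == "llcfs":
        return lambda x, y: llcfs_weights(x, n_clusters=np.unique(y).size, **kwargs)[1]
    if method == "cfs":
        return lambda x, y: cfs_rank(x, y)
    raise ValueError(f"unknown feature-selection method {method!r}")
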
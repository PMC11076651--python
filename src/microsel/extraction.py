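"""Per-sample dimensionality reduction for expression matrices.

Five methods reduce a gene vector to ``k`` features (default 6,000 from
12,600): Gaussian-mixture EM, nonlinear (exponential-decay) regression,
K-means gene clustering, PCA, and the 1-D orthonormal DCT-II.  Each
method also defines a retention rule mapping its own outputs to a
ranked gene/coefficient subset; retention is fitted on training samples
only so the extractors can be used fold-safely inside cross-validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import fft as _fft
from scipy.optimize import least_squares

METHODS = ("EM", "NLR", "KMEANS", "PCA", "DCT")

DEFAULT_K = 6_000


# ---------------------------------------------------------------------------
# Gaussian mixture via EM
# ---------------------------------------------------------------------------

@dataclass
class GMMParams:
    """Fitted univariate Gaussian mixture.

    ``responsibilities`` holds the posterior membership weights w_ij of
    every data point for every component; ``log_likelihood_trace`` is
    recorded per EM iteration and is non-decreasing.
    """

    n_components: int
    weights: np.ndarray          # mixing proportions pi_j, sum to 1
    means: np.ndarray
    variances: np.ndarray
    responsibilities: np.ndarray  # (n_points, n_components), rows sum to 1
    log_likelihood_trace: np.ndarray
    converged: bool
    variance_floored: bool = False


def _log_gauss(x: np.ndarray, mean: float, var: float) -> np.ndarray:
    return -0.5 * (np.log(2 * np.pi * var) + (x - mean) ** 2 / var)


def gmm_em_fit(
    values: np.ndarray,
    n_components: int = 2,
    tol: float = 1e-8,
    max_iter: int = 200,
    seed: int = 0,
) -> GMMParams:
    """Fit a univariate Gaussian mixture by expectation-maximization.

    The E-step computes posterior responsibilities by Bayes' rule; the
    M-step re-estimates mixing weights, means and (MLE, denominator-n)
    variances from them.  Iteration stops when the log-likelihood gain
    falls below ``tol``.  Components whose variance collapses are
    floored at 1e-6 times the data variance and flagged.
    """
    x = np.asarray(values, dtype=float).ravel()
    n = x.size
    if n < n_components:
        raise ValueError(f"need at least {n_components} points, got {n}")
    if tol <= 0:
        raise ValueError("tol must be > 0")
    rng = np.random.default_rng(seed)
    data_var = max(x.var(), np.finfo(float).tiny)
    floor = 1e-6 * data_var

    # init: spread quantiles as means (jittered if tied), global variance,
    # equal weights; identical means are a symmetric EM fixed point
    means = np.quantile(x, (np.arange(n_components) + 0.5) / n_components)
    if np.unique(means).size < n_components:
        means = means + rng.normal(scale=max(x.std(), 1.0) * 1e-3,
                                   size=n_components)
    variances = np.full(n_components, data_var)
    weights = np.full(n_components, 1.0 / n_components)

    trace: list[float] = []
    floored = False
    converged = False
    resp = np.full((n, n_components), 1.0 / n_components)
    for _ in range(max_iter):
        # E-step: w_ij = pi_j N(x_i | mu_j, var_j) / sum_l pi_l N(x_i | ...)
        log_p = _log_gauss(x[:, None], means[None, :], variances[None, :])
        log_p += np.log(weights)[None, :]
        log_norm = _logsumexp(log_p)
        resp = np.exp(log_p - log_norm[:, None])
        ll = float(log_norm.sum())
        trace.append(ll)
        if len(trace) >= 2 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
        # M-step
        nk = resp.sum(axis=0)
        weights = nk / n
        means = resp.T @ x / nk
        variances = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        if np.any(variances < floor):
            variances = np.maximum(variances, floor)
            floored = True
    return GMMParams(
        n_components=n_components,
        weights=weights,
        means=means,
        variances=variances,
        responsibilities=resp,
        log_likelihood_trace=np.asarray(trace),
        converged=converged,
        variance_floored=floored,
    )


def _logsumexp(a: np.ndarray) -> np.ndarray:
    m = a.max(axis=-1, keepdims=True)
    return (m + np.log(np.exp(a - m).sum(axis=-1, keepdims=True))).squeeze(-1)


def _batch_em_2comp(
    X: np.ndarray, max_iter: int = 60, tol: float = 1e-7, seed: int = 0
) -> np.ndarray:
    """Two-component univariate EM run independently for every column.

    Vectorized across genes; returns per-point responsibilities of the
    higher-mean component, shape (n_samples, n_genes).  Initialization
    splits each gene at its median.
    """
    n, g = X.shape
    lo = np.where(X <= np.median(X, axis=0, keepdims=True), 1.0, 0.0)
    resp1 = 1.0 - lo  # responsibility of the upper component
    floor = 1e-6 * np.maximum(X.var(axis=0), np.finfo(float).tiny)
    prev_ll = None
    for _ in range(max_iter):
        r = np.stack([1.0 - resp1, resp1], axis=0)       # (2, n, g)
        nk = r.sum(axis=1) + 1e-12                        # (2, g)
        w = nk / n
        mu = (r * X[None]).sum(axis=1) / nk               # (2, g)
        var = (r * (X[None] - mu[:, None, :]) ** 2).sum(axis=1) / nk
        var = np.maximum(var, floor[None, :])
        log_p = (
            -0.5 * (np.log(2 * np.pi * var[:, None, :]) + (X[None] - mu[:, None, :]) ** 2 / var[:, None, :])
            + np.log(w[:, None, :])
        )
        m = log_p.max(axis=0)
        norm = m + np.log(np.exp(log_p - m).sum(axis=0))
        resp1 = np.exp(log_p[1] - norm)
        ll = norm.sum()
        if prev_ll is not None and abs(ll - prev_ll) < tol * abs(ll):
            break
        prev_ll = ll
    return resp1


# ---------------------------------------------------------------------------
# Nonlinear regression: m = theta1 * exp(-theta2 * n) + theta3
# ---------------------------------------------------------------------------

@dataclass
class NLRFit:
    theta: np.ndarray            # (theta1, theta2, theta3)
    residual_ss: float
    converged: bool
    near_singular: bool = False  # unidentifiable parameters (e.g. theta2 ~ 0)


def _nlr_model(theta: np.ndarray, n: np.ndarray) -> np.ndarray:
    return theta[0] * np.exp(-theta[1] * n) + theta[2]


def nlr_fit(
    y: np.ndarray,
    init: tuple[float, float, float] | None = None,
    max_iter: int = 200,
) -> NLRFit:
    """Fit the exponential-decay model by damped least squares.

    The predictor is the index n = 0..N-1 of each observation.  The
    default initialization is (range(y), 0.1, min(y)).  A Jacobian
    whose condition number exceeds 1e8 at the solution marks the fit
    as near-singular (theta1/theta3 unidentifiable when theta2 ~ 0).
    """
    y = np.asarray(y, dtype=float).ravel()
    if y.size < 3:
        raise ValueError("need at least 3 observations")
    n = np.arange(y.size, dtype=float)
    if init is None:
        init = (float(np.ptp(y)), 0.1, float(y.min()))
    res = least_squares(
        lambda th: _nlr_model(th, n) - y,
        x0=np.asarray(init, dtype=float),
        method="lm",
        max_nfev=max_iter * 3,
    )
    jac = res.jac
    sv = np.linalg.svd(jac, compute_uv=False)
    near_singular = bool(sv[0] / max(sv[-1], np.finfo(float).tiny) > 1e8)
    return NLRFit(
        theta=res.x,
        residual_ss=float(2 * res.cost),
        converged=bool(res.status > 0 and res.nfev < max_iter * 3),
        near_singular=near_singular,
    )


def _batch_nlr_residuals(X: np.ndarray, n_grid: int = 25) -> np.ndarray:
    """Residual sum of squares of the decay model, per gene, by variable
    projection: for each decay rate on a log grid the optimal (theta1,
    theta3) are linear, so residuals for all genes come from one shared
    QR factorization per grid point."""
    n_samples, _ = X.shape
    t = np.arange(n_samples, dtype=float)
    best = np.full(X.shape[1], np.inf)
    rates = np.concatenate([[0.0], np.logspace(-3, 1, n_grid - 1)])
    for rate in rates:
        basis = np.column_stack([np.exp(-rate * t), np.ones(n_samples)])
        if rate == 0.0:  # theta1 and theta3 collinear: constant fit
            basis = basis[:, :1]
        q, _ = np.linalg.qr(basis)
        resid = X - q @ (q.T @ X)
        best = np.minimum(best, (resid**2).sum(axis=0))
    return best


# ---------------------------------------------------------------------------
# K-means (Lloyd)
# ---------------------------------------------------------------------------

@dataclass
class KMeansModel:
    n_clusters: int
    centroids: np.ndarray
    assignments: np.ndarray
    inertia: float
    inertia_trace: np.ndarray
    reseeded_clusters: list[int] = field(default_factory=list)


def _sq_dists(points: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    # (n, K) squared Euclidean distances
    return (
        (points**2).sum(axis=1, keepdims=True)
        - 2.0 * points @ centroids.T
        + (centroids**2).sum(axis=1)[None, :]
    )


def kmeans_fit(
    points: np.ndarray, n_clusters: int, seed: int = 0, max_iter: int = 100
) -> KMeansModel:
    """Lloyd's algorithm: assign to the nearest centroid (ties broken by
    the lowest cluster index via argmin), recompute centroids as cluster
    means, stop when assignments stabilize.  An emptied cluster is
    re-seeded at the point farthest from its centroid and recorded."""
    X = np.asarray(points, dtype=float)
    n = X.shape[0]
    if n < n_clusters:
        raise ValueError(f"need >= {n_clusters} points, got {n}")
    rng = np.random.default_rng(seed)
    centroids = X[rng.choice(n, size=n_clusters, replace=False)].copy()
    assignments = np.full(n, -1)
    trace: list[float] = []
    reseeded: list[int] = []
    for _ in range(max_iter):
        d2 = np.maximum(_sq_dists(X, centroids), 0.0)
        new_assign = d2.argmin(axis=1)
        trace.append(float(d2[np.arange(n), new_assign].sum()))
        if np.array_equal(new_assign, assignments):
            break
        assignments = new_assign
        for j in range(n_clusters):
            members = assignments == j
            if members.any():
                centroids[j] = X[members].mean(axis=0)
            else:
                far = d2[np.arange(n), assignments].argmax()
                centroids[j] = X[far]
                reseeded.append(j)
    d2 = np.maximum(_sq_dists(X, centroids), 0.0)
    inertia = float(d2[np.arange(n), assignments].sum())
    return KMeansModel(
        n_clusters=n_clusters,
        centroids=centroids,
        assignments=assignments,
        inertia=inertia,
        inertia_trace=np.asarray(trace),
        reseeded_clusters=reseeded,
    )


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    mean: np.ndarray
    covariance: np.ndarray
    eigenvalues: np.ndarray   # descending
    eigenvectors: np.ndarray  # columns, orthonormal
    degenerate: bool = False  # constant input, all eigenvalues zero


def pca_decompose(matrix: np.ndarray) -> PCAModel:
    """Eigendecomposition of the (denominator-n) covariance of centered
    data, eigenpairs sorted by eigenvalue descending."""
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = Xc.T @ Xc / X.shape[0]
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    vals = np.maximum(vals, 0.0)
    degenerate = bool(vals.max(initial=0.0) <= 1e-15)
    if degenerate:
        warnings.warn("constant input matrix: all eigenvalues are zero")
    return PCAModel(mean=mean, covariance=cov, eigenvalues=vals,
                    eigenvectors=vecs, degenerate=degenerate)


def _pca_svd(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean, eigenvalues and eigenvector columns of the denominator-n
    covariance via thin SVD of the centered matrix — equivalent to
    :func:`pca_decompose` on the nonzero spectrum but O(n² d) instead of
    O(d³), which is what makes gene-scale inputs tractable."""
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=0)
    _u, s, vt = np.linalg.svd(X - mean, full_matrices=False)
    return mean, s**2 / X.shape[0], vt.T


def pca_rank(model: PCAModel, rtol: float = 1e-12) -> int:
    thresh = model.eigenvalues.max(initial=0.0) * rtol
    return int((model.eigenvalues > thresh).sum())


def pca_project(model: PCAModel, matrix: np.ndarray, k: int) -> np.ndarray:
    """Project centered data on the first k eigenvector columns (Y = X_c V_k)."""
    rank = pca_rank(model)
    if k > model.eigenvectors.shape[1] or k > rank:
        raise ValueError(f"k={k} exceeds available rank; max usable k is {rank}")
    X = np.atleast_2d(np.asarray(matrix, dtype=float))
    return (X - model.mean) @ model.eigenvectors[:, :k]


# ---------------------------------------------------------------------------
# DCT-II (orthonormal)
# ---------------------------------------------------------------------------

@dataclass
class DCTSpectrum:
    coefficients: np.ndarray
    normalization: np.ndarray  # alpha(k): 1/sqrt(N) for k=0, sqrt(2/N) otherwise


def dct_alpha(n: int) -> np.ndarray:
    alpha = np.full(n, np.sqrt(2.0 / n))
    alpha[0] = np.sqrt(1.0 / n)
    return alpha


def dct_1d(x: np.ndarray) -> DCTSpectrum:
    """Orthonormal DCT-II: X(k) = alpha(k) sum_n x(n) cos[pi/N (n+1/2) k].

    With alpha(0)=1/sqrt(N), alpha(k>0)=sqrt(2/N) the transform is
    orthonormal, so Parseval holds and the inverse is the transpose.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty input")
    coeffs = _fft.dct(x, type=2, norm="ortho")
    return DCTSpectrum(coefficients=coeffs, normalization=dct_alpha(x.size))


def idct_1d(spectrum: DCTSpectrum) -> np.ndarray:
    return _fft.idct(spectrum.coefficients, type=2, norm="ortho")


# ---------------------------------------------------------------------------
# Extraction front-end: fold-safe fit/transform per method
# ---------------------------------------------------------------------------

@dataclass
class ExtractionResult:
    method: str
    features: np.ndarray       # samples x k
    retained_indices: np.ndarray
    k: int


class Extractor:
    """Fit a retention rule on training data, then transform any samples.

    Retention rules use only the method's own outputs:

    * ``DCT`` — per-sample orthonormal DCT; keep the k coefficients with
      the largest mean magnitude over training samples.
    * ``PCA`` — rank genes by eigenvalue-weighted absolute loading on the
      leading components and keep the top k gene columns (projection onto
      eigenvectors is available when ``mode='projection'`` and k <= rank).
    * ``EM`` — per-gene two-component mixture; rank genes by the
      between-class separation of mean component responsibilities.
    * ``NLR`` — per-gene exponential-decay fit over sample index; rank by
      residual sum of squares, worst fit (most structure) first.
    * ``KMEANS`` — cluster gene profiles; rank genes by the ratio of the
      distance to their own centroid over the distance to the nearest
      other centroid (most prototypical first).
    """

    def __init__(self, method: str, k: int = DEFAULT_K, seed: int = 0, **params):
        if method not in METHODS:
            raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
        self.method = method
        self.k = int(k)
        self.seed = seed
        self.params = params
        self.retained_: np.ndarray | None = None
        self._pca: tuple | None = None  # (mean, eigenvalues, eigenvectors)

    def fit(self, X: np.ndarray, y: np.ndarray | None = None) -> "Extractor":
        X = np.asarray(X, dtype=float)
        n, g = X.shape
        limit = g
        if self.method == "PCA" and self.params.get("mode") == "projection":
            limit = min(limit, n)
        if self.k > limit:
            raise ValueError(f"k={self.k} exceeds achievable dimension {limit}")
        if self.method == "DCT":
            coefs = _fft.dct(X, type=2, norm="ortho", axis=1)
            score = np.abs(coefs).mean(axis=0)
        elif self.method == "PCA":
            mean, vals, vecs = _pca_svd(X)
            self._pca = (mean, vals, vecs)
            rank = int((vals > vals.max(initial=0.0) * 1e-12).sum())
            if self.params.get("mode") == "projection":
                if self.k > rank:
                    raise ValueError(
                        f"k={self.k} exceeds rank; max usable k is {rank}")
                self.retained_ = np.arange(self.k)
                return self
            lead = max(rank, 1)
            score = (np.abs(vecs[:, :lead]) * vals[:lead][None, :]).sum(axis=1)
        elif self.method == "EM":
            if y is None:
                raise ValueError("EM retention requires class labels")
            resp1 = _batch_em_2comp(X, seed=self.seed)
            y = np.asarray(y)
            score = np.abs(resp1[y == 1].mean(axis=0) - resp1[y == 0].mean(axis=0))
        elif self.method == "NLR":
            score = _batch_nlr_residuals(X)
        elif self.method == "KMEANS":
            K = int(self.params.get("n_clusters", 8))
            model = kmeans_fit(X.T, n_clusters=K, seed=self.seed)
            d2 = np.maximum(_sq_dists(X.T, model.centroids), 0.0)
            own = d2[np.arange(g), model.assignments]
            d2_other = d2.copy()
            d2_other[np.arange(g), model.assignments] = np.inf
            other = d2_other.min(axis=1)
            score = -np.sqrt(own) / (np.sqrt(other) + 1e-12)  # negate: keep tightest
        # top-k by score, descending; stable ascending index order for output
        order = np.argsort(-score, kind="stable")[: self.k]
        self.retained_ = np.sort(order)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.retained_ is None:
            raise RuntimeError("extractor is not fitted")
        X = np.asarray(X, dtype=float)
        if self.method == "DCT":
            coefs = _fft.dct(X, type=2, norm="ortho", axis=1)
            return coefs[:, self.retained_]
        if self.method == "PCA" and self.params.get("mode") == "projection":
            mean, _vals, vecs = self._pca
            return (X - mean) @ vecs[:, : self.k]
        return X[:, self.retained_]


def extract_features(dataset, method: str, k: int = DEFAULT_K,
                     method_params: dict | None = None, seed: int = 0) -> ExtractionResult:
    """One-shot fit-and-transform of a dataset with one extraction method."""
    extractor = Extractor(method, k=k, seed=seed, **(method_params or {}))
    extractor.fit(dataset.matrix, dataset.y)
    features = extractor.transform(dataset.matrix)
    if not np.all(np.isfinite(features)):
        raise ValueError("extraction produced non-finite features")
    return ExtractionResult(method=method, features=features,
                            retained_indices=extractor.retained_, k=k)
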
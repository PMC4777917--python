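"""Clustering engines: k-means and a subspace-constrained Gaussian mixture.

The mixture model (HDDC, "high-dimensional data clustering") restricts each
cluster's covariance to a low-dimensional signal subspace plus isotropic
noise:  Sigma_k = Q_k diag(a_k1..a_kd_k, b_k, ..., b_k) Q_k^T  with
orthonormal Q_k, intrinsic dimension d_k, signal eigenvalues a_kj and noise
variance b_k.  This "free parameters" family is fitted by EM; the intrinsic
dimensions are chosen by a Cattell scree test on the eigenvalue differences
of the initial hard partition's covariances and then held fixed, so every
M-step maximizes within a fixed model structure and the log-likelihood
trace is non-decreasing.

With one variable no subspace structure exists and the model degenerates
to a plain univariate Gaussian mixture (d_k = 0; the covariance is the
noise variance alone), which the same EM code handles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)


class DegenerateClusterError(RuntimeError):
    """EM produced a cluster too small to estimate its covariance."""


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


# ---------------------------------------------------------------------------
# k-means
# ---------------------------------------------------------------------------

@dataclass
class KMeansResult:
    k: int
    centroids: np.ndarray          # (k, p)
    labels: np.ndarray             # (n,)
    within_ss: float
    seed: int
    n_init: int
    roles: tuple[str, ...] | None = None


def kmeans_fit(points: np.ndarray, k: int, seed: int = 0, n_init: int = 10,
               roles: tuple[str, ...] | None = None) -> KMeansResult:
    """Lloyd's k-means with k-means++ seeding, best of ``n_init`` starts.

    On very small inputs (n < 10k) the greedy k-means++ seeding is nearly
    deterministic, which collapses restart diversity and can trap Lloyd
    in a local optimum; plain random seeding is used there instead.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} points, got {n}")
    init = "random" if n < 10 * k else "k-means++"
    km = KMeans(n_clusters=k, init=init, n_init=n_init,
                random_state=seed % (2**31 - 1), algorithm="lloyd")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # duplicate-point convergence chatter
        labels = km.fit_predict(X)
    return KMeansResult(k=k, centroids=km.cluster_centers_, labels=labels,
                        within_ss=float(km.inertia_), seed=seed,
                        n_init=n_init, roles=roles)


# ---------------------------------------------------------------------------
# HDDC: subspace Gaussian mixture
# ---------------------------------------------------------------------------

@dataclass
class SubspaceMixtureModel:
    k: int
    weights: np.ndarray                 # (k,)
    means: np.ndarray                   # (k, p)
    bases: list[np.ndarray]             # per cluster (p, d_k), orthonormal
    dims: np.ndarray                    # (k,)
    signal: list[np.ndarray]            # per cluster (d_k,) eigenvalues a_kj
    noise: np.ndarray                   # (k,) isotropic variances b_k
    loglik_trace: np.ndarray
    seed: int
    roles: tuple[str, ...] | None = None
    labels: np.ndarray = field(default=None, repr=False)

    @property
    def centroids(self) -> np.ndarray:
        return self.means

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])

    def cluster_covariance(self, j: int) -> np.ndarray:
        """Reconstruct the restricted covariance of cluster ``j``."""
        p = self.means.shape[1]
        Q = self.bases[j]
        cov = self.noise[j] * np.eye(p)
        if Q.shape[1]:
            cov += Q @ np.diag(self.signal[j] - self.noise[j]) @ Q.T
        return cov

    def log_density(self, X: np.ndarray) -> np.ndarray:
        """Weighted per-cluster Gaussian log densities, shape (n, k)."""
        return _log_density(np.asarray(X, float), self._params())

    def _params(self) -> dict:
        return {"weights": self.weights, "means": self.means,
                "bases": self.bases, "signal": self.signal,
                "noise": self.noise, "dims": self.dims}

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.log_density(np.asarray(X, float)), axis=1)


def _log_density(X: np.ndarray, params: dict) -> np.ndarray:
    n, p = X.shape
    k = len(params["weights"])
    out = np.empty((n, k))
    for j in range(k):
        Y = X - params["means"][j]
        sq = np.einsum("ij,ij->i", Y, Y)
        d = int(params["dims"][j])
        b = params["noise"][j]
        if d:
            a = params["signal"][j]
            proj = Y @ params["bases"][j]
            proj2 = proj * proj
            m2 = proj2 @ (1.0 / a - 1.0 / b)
            m2 += sq / b
            logdet = float(np.log(a).sum()) + (p - d) * np.log(b)
        else:
            m2 = sq / b
            logdet = p * np.log(b)
        out[:, j] = np.log(params["weights"][j]) - 0.5 * (p * _LOG2PI + logdet + m2)
    return out


def cattell_dimension(eigvals: np.ndarray, threshold: float) -> int:
    """Intrinsic dimension by Cattell's scree test on eigenvalue gaps.

    Picks the last gap that is at least ``threshold`` times the largest
    gap; dimensions are clamped to [1, p-1] (0 when p = 1).
    """
    p = len(eigvals)
    if p < 2:
        return 0
    gaps = -np.diff(eigvals)
    top = gaps.max()
    if top <= 0:
        return 1
    keep = np.flatnonzero(gaps >= threshold * top)
    d = int(keep[-1]) + 1 if keep.size else 1
    return int(min(max(d, 1), p - 1))


def _m_step(X: np.ndarray, resp: np.ndarray, d_select_threshold: float,
            dims: np.ndarray | None) -> dict:
    n, p = X.shape
    k = resp.shape[1]
    nk = resp.sum(axis=0)
    if np.any(nk < max(p, 2)):
        raise DegenerateClusterError(
            f"cluster with effective size {nk.min():.2f} < {max(p, 2)}")
    weights = nk / n
    means = (resp.T @ X) / nk[:, None]
    bases, signal, noise, out_dims = [], [], [], []
    for j in range(k):
        Y = X - means[j]
        C = (resp[:, j][:, None] * Y).T @ Y / nk[j]
        eigval, eigvec = np.linalg.eigh(C)
        eigval, eigvec = eigval[::-1], eigvec[:, ::-1]
        eigval = np.maximum(eigval, 0.0)
        d = int(dims[j]) if dims is not None else cattell_dimension(
            eigval, d_select_threshold)
        floor = max(1e-10, 1e-8 * max(eigval[0], 1e-30))
        if d:
            a = np.maximum(eigval[:d], floor)
            b = max((eigval.sum() - eigval[:d].sum()) / (p - d), floor)
            a = np.maximum(a, b)
            Q = eigvec[:, :d]
        else:  # p == 1: plain variance
            a = np.empty(0)
            b = max(eigval.sum(), floor)
            Q = np.empty((p, 0))
        bases.append(Q)
        signal.append(a)
        noise.append(b)
        out_dims.append(d)
    return {"weights": weights, "means": means, "bases": bases,
            "signal": signal, "noise": np.array(noise),
            "dims": np.array(out_dims)}


def _em_iterate(X: np.ndarray, params: dict, dims: np.ndarray,
                trace: list[float], max_iter: int, tol: float,
                d_select_threshold: float,
                allow_collapse: bool = False) -> tuple[dict, np.ndarray, bool]:
    """Run EM iterations in place; returns (params, dims, converged).

    Intrinsic dimensions are re-selected by the scree test at every
    M-step, but an adaptive selection is only accepted when it does not
    decrease the observed log-likelihood; otherwise the M-step is redone
    with the current dimensions, whose Q-maximization guarantees a
    non-decreasing trace.  With ``allow_collapse`` a mid-run degenerate
    M-step (a component shrinking below p effective points) stops EM at
    the last valid parameters instead of raising.
    """
    for _ in range(max_iter):
        logdens = _log_density(X, params)
        norm = logsumexp(logdens, axis=1)
        trace.append(float(norm.sum()))
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol * abs(trace[-2]):
            return params, dims, True
        resp = np.exp(logdens - norm[:, None])
        try:
            cand = _m_step(X, resp, d_select_threshold, dims=None)
            if np.array_equal(cand["dims"], dims):
                params = cand
            else:
                ll_cand = float(logsumexp(_log_density(X, cand), axis=1).sum())
                if ll_cand >= trace[-1]:
                    params, dims = cand, cand["dims"]
                else:
                    params = _m_step(X, resp, d_select_threshold, dims=dims)
        except DegenerateClusterError:
            if allow_collapse:
                logger.info("EM stopped on component collapse after %d "
                            "iterations", len(trace))
                return params, dims, True
            raise
    return params, dims, False


def _em_run(X: np.ndarray, k: int, init_seed: int, d_select_threshold: float,
            max_iter: int, tol: float) -> tuple[dict, np.ndarray, list[float], bool]:
    """Initialize from a hard k-means partition and run EM for ``max_iter``."""
    n, _p = X.shape
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        labels0 = KMeans(n_clusters=k, n_init=1, random_state=init_seed,
                         algorithm="lloyd").fit_predict(X)
    resp = np.zeros((n, k))
    resp[np.arange(n), labels0] = 1.0
    params = _m_step(X, resp, d_select_threshold, dims=None)
    dims = params["dims"]
    trace: list[float] = []
    params, dims, converged = _em_iterate(X, params, dims, trace, max_iter,
                                          tol, d_select_threshold)
    return params, dims, trace, converged


def hddc_fit(points: np.ndarray, k: int, d_select_threshold: float = 0.2,
             max_iter: int = 200, tol: float = 1e-6, seed: int = 0,
             n_init: int = 5, roles: tuple[str, ...] | None = None,
             max_retries: int = 3, burn_iter: int = 15) -> SubspaceMixtureModel:
    """Fit the subspace Gaussian mixture by EM, best of ``n_init`` starts.

    Each start initializes responsibilities from a hard k-means partition
    and runs a short burn-in of ``burn_iter`` EM iterations; the start
    with the highest burn-in log-likelihood is continued to convergence
    (relative change < ``tol`` or ``max_iter`` total iterations).
    Degenerate starts (a cluster shrinking below p effective points) are
    retried with fresh initializations up to ``max_retries`` times each.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if n < k * (p + 1):
        raise ValueError(f"need at least k*(p+1)={k * (p + 1)} points, got {n}")
    seeds = _child_seeds(seed, n_init * (max_retries + 1))
    pool = iter(seeds)
    failures = 0
    best = None  # (params, dims, trace, converged)
    for _ in range(n_init):
        run = None
        for _attempt in range(max_retries + 1):
            try:
                run = _em_run(X, k, next(pool), d_select_threshold,
                              min(burn_iter, max_iter), tol)
                break
            except DegenerateClusterError:
                failures += 1
                continue
        if run is not None and (best is None or run[2][-1] > best[2][-1]):
            best = run
    if best is None:
        raise DegenerateClusterError(
            f"all {n_init} initializations degenerated ({failures} failures)")
    params, dims, trace, converged = best
    if not converged:
        params, dims, _ = _em_iterate(X, params, dims, trace,
                                      max_iter - len(trace), tol,
                                      d_select_threshold, allow_collapse=True)
    model = SubspaceMixtureModel(k=k, loglik_trace=np.asarray(trace),
                                 seed=seed, roles=roles, **params)
    model.labels = model.predict(X)
    return model


# ---------------------------------------------------------------------------
# centroid-based cluster selection
# ---------------------------------------------------------------------------

def select_cluster_by_centroid(result, channel_role: str | int,
                               mode: str = "max") -> int:
    """Index of the cluster whose centroid is extremal on one channel.

    ``result`` is any fit with ``.centroids`` (k, p); ``channel_role`` is a
    role name resolved against ``result.roles``, or a column index.  Exact
    ties go to the lowest cluster index with a warning.
    """
    if mode not in ("max", "min"):
        raise ValueError(f"mode must be 'max' or 'min', got {mode!r}")
    centroids = np.asarray(result.centroids, dtype=float)
    if isinstance(channel_role, str):
        roles = getattr(result, "roles", None)
        if roles is None or channel_role not in roles:
            raise KeyError(f"unknown channel role {channel_role!r} "
                           f"(available: {roles})")
        col = roles.index(channel_role)
    else:
        col = int(channel_role)
        if not 0 <= col < centroids.shape[1]:
            raise KeyError(f"channel index {col} out of range")
    coords = centroids[:, col]
    extremum = coords.max() if mode == "max" else coords.min()
    hits = np.flatnonzero(coords == extremum)
    if hits.size > 1:
        warnings.warn(f"centroid tie on {channel_role!r} between clusters "
                      f"{hits.tolist()}; choosing index {hits[0]}")
    return int(hits[0])
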
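"""Ellipsoid niche envelopes in environmental (PC) space.

Two estimators of the niche envelope are provided, mirroring the two
conventions of the ellipsoid-niche literature:

* **CVAE** ("common" ellipsoid): centroid = sample mean, shape = sample
  covariance, squared radius = the chi-square quantile at the requested
  coverage — the envelope a multivariate-normal niche would have.
* **MVE** (minimum volume ellipsoid): the smallest-volume ellipsoid that
  still contains ``ceil(coverage * n)`` of the points, found by an h-subset
  search (random elemental starts + concentration steps on Mahalanobis
  ranks, as in robust covariance estimation) followed by the minimum-volume
  enclosing ellipsoid of the best subset.  The MVE discounts outlying
  occurrences and therefore yields tighter envelopes than the CVAE.

Containment is closed (boundary points count as inside), which keeps
coverage counts deterministic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb, ceil, pi
from typing import Any

import numpy as np
from numba import njit
from scipy.special import gammaln
from scipy.stats import chi2

from .envspace import EnvMatrix
from .errors import DegenerateGeometryError, InvalidParameterError

_REL_TOL = 1e-9  # closed-containment slack for floating-point boundaries


def _as_points(points) -> np.ndarray:
    if isinstance(points, EnvMatrix):
        return points.values
    return np.atleast_2d(np.asarray(points, dtype=float))


@dataclass
class Ellipsoid:
    """Centroid + SPD shape matrix + squared radius in k dimensions.

    A point p is inside iff (p-c)' shape^{-1} (p-c) <= radius2.
    """

    centroid: np.ndarray
    shape: np.ndarray
    radius2: float
    method: str = "cvae"            # "cvae" | "mve"
    coverage: float = 0.95
    warnings: tuple[str, ...] = ()
    fit_info: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.centroid = np.asarray(self.centroid, dtype=float).ravel()
        self.shape = np.asarray(self.shape, dtype=float)
        k = self.centroid.size
        if self.shape.shape != (k, k):
            raise InvalidParameterError("shape matrix does not match centroid dimension")
        if not np.allclose(self.shape, self.shape.T, atol=1e-10):
            raise InvalidParameterError("shape matrix must be symmetric")
        if np.linalg.eigvalsh(self.shape).min() <= 0:
            raise DegenerateGeometryError("shape matrix is not positive definite")
        if not (self.radius2 > 0):
            raise InvalidParameterError("radius2 must be positive")
        if not (0 < self.coverage <= 1):
            raise InvalidParameterError("coverage must be in (0, 1]")

    @property
    def k(self) -> int:
        return self.centroid.size

    def to_dict(self) -> dict:
        return {
            "centroid": self.centroid.tolist(),
            "shape": self.shape.tolist(),
            "radius2": float(self.radius2),
            "method": self.method,
            "coverage": float(self.coverage),
            "warnings": list(self.warnings),
            "fit_info": {k: v for k, v in self.fit_info.items()
                         if isinstance(v, (int, float, str, bool, list))},
        }


def mahalanobis2(ellipsoid: Ellipsoid, points) -> np.ndarray:
    """Quadratic form (p-c)' shape^{-1} (p-c) for one or many points."""
    pts = _as_points(points)
    if pts.shape[1] != ellipsoid.k:
        raise InvalidParameterError(
            f"dimension mismatch: points are {pts.shape[1]}-D, ellipsoid is {ellipsoid.k}-D")
    dev = pts - ellipsoid.centroid
    sol = np.linalg.solve(ellipsoid.shape, dev.T)
    d2 = np.einsum("ij,ji->i", dev, sol)
    return d2 if d2.size > 1 else d2


def contains(ellipsoid: Ellipsoid, points) -> np.ndarray:
    """Closed containment test (boundary points count as inside)."""
    d2 = mahalanobis2(ellipsoid, points)
    return d2 <= ellipsoid.radius2 * (1 + _REL_TOL)


def volume(ellipsoid: Ellipsoid) -> float:
    """V = V_k * radius2^{k/2} * sqrt(det shape), V_k the unit k-ball volume."""
    k = ellipsoid.k
    log_vk = (k / 2) * np.log(pi) - gammaln(k / 2 + 1)
    sign, logdet = np.linalg.slogdet(ellipsoid.shape)
    if sign <= 0:
        raise DegenerateGeometryError("shape matrix has non-positive determinant")
    return float(np.exp(log_vk + (k / 2) * np.log(ellipsoid.radius2) + 0.5 * logdet))


def fit_cvae(points, coverage: float = 0.95) -> Ellipsoid:
    """Centroid-and-covariance ellipsoid with a chi-square coverage radius."""
    X = _as_points(points)
    n, k = X.shape
    if not (0 < coverage <= 1):
        raise InvalidParameterError("coverage must be in (0, 1]")
    if n < k + 2:
        raise DegenerateGeometryError(f"need at least k+2 = {k + 2} points, got {n}")
    centroid = X.mean(axis=0)
    shape = np.cov(X, rowvar=False, ddof=1).reshape(k, k)
    eig = np.linalg.eigvalsh(shape)
    if eig.min() <= 1e-12 * max(eig.max(), 1.0):
        raise DegenerateGeometryError("singular covariance (collinear points)")
    radius2 = float(chi2.ppf(coverage, df=k))
    ell = Ellipsoid(centroid, shape, radius2, method="cvae", coverage=coverage)
    h = ceil(coverage * n)
    n_inside = int(contains(ell, X).sum())
    if n_inside < h:
        ell.warnings = (f"coverage shortfall: {n_inside}/{n} points inside, "
                        f"needed {h}",)
    ell.fit_info = {"n_points": n, "n_inside": n_inside}
    return ell


# ---------------------------------------------------------------------------
# Minimum-volume enclosing ellipsoid (Khachiyan iteration, Wolfe–Atwood
# away steps for linear convergence at tight tolerances).
# ---------------------------------------------------------------------------

@njit(cache=True)
def _mvee_weights(Q: np.ndarray, tol: float, max_iter: int) -> np.ndarray:  # pragma: no cover
    """Optimal design weights of the lifted MVEE dual (numba kernel).

    Frank–Wolfe add steps with Wolfe–Atwood away steps; invM and the
    quadratic forms are maintained by Sherman–Morrison rank-1 updates and
    re-synced periodically against drift.  Returns NaN weights when the
    configuration is degenerate.
    """
    n, dd = Q.shape
    u = np.full(n, 1.0 / n)
    invM = np.empty((dd, dd))
    g = np.empty(n)
    nan = np.full(n, np.nan)
    for it in range(max_iter):
        if it % 128 == 0:  # periodic re-sync
            M = (Q * u.reshape(-1, 1)).T @ Q
            if np.abs(np.linalg.det(M)) < 1e-300:
                return nan
            invM = np.ascontiguousarray(np.linalg.inv(M))
            g = np.sum((Q @ invM) * Q, axis=1)
        j_add = int(np.argmax(g))
        eps_add = g[j_add] / dd - 1.0
        j_away = -1
        g_away = np.inf
        for i in range(n):
            if u[i] > 1e-12 and g[i] < g_away:
                g_away = g[i]
                j_away = i
        eps_away = 1.0 - g_away / dd
        if max(eps_add, eps_away) < tol:
            break
        if eps_add >= eps_away:
            j = j_add
            gj = g[j]
            step = (gj - dd) / (dd * (gj - 1.0))
        else:
            j = j_away
            gj = g[j]
            s1 = (gj - dd) / (dd * (gj - 1.0))
            s2 = -u[j] / (1.0 - u[j])
            step = s1 if s1 > s2 else s2
        u *= (1.0 - step)
        u[j] += step
        # M' = (1-step) M + step q_j q_j'
        a = 1.0 - step
        t = step / a
        w = invM @ Q[j]
        s = Q[j] @ w
        coef = t / (1.0 + t * s)
        invM = (invM - coef * np.outer(w, w)) / a
        qw = Q @ w
        g = (g - coef * qw * qw) / a
    return u


def minimum_enclosing_ellipsoid(points, tol: float = 1e-7,
                                max_iter: int = 100_000) -> Ellipsoid:
    """Minimum-volume ellipsoid enclosing *all* given points.

    Solves the D-optimal design dual on the lifted points, starting from
    uniform weights and alternating Frank–Wolfe add steps with away (drop)
    steps until the optimality gap falls below ``tol``.  The returned
    ``radius2`` is the maximum quadratic form over the inputs, so enclosure
    is exact regardless of the stopping tolerance.
    """
    P = _as_points(points)
    n, d = P.shape
    if n < d + 1:
        raise DegenerateGeometryError(
            f"need at least d+1 = {d + 1} points for a full-dimensional ellipsoid, got {n}")
    Q = np.column_stack([P, np.ones(n)])
    u = _mvee_weights(Q, tol, max_iter)
    if not np.all(np.isfinite(u)):
        raise DegenerateGeometryError("degenerate point configuration")
    c = P.T @ u
    S = P.T @ (u[:, None] * P) - np.outer(c, c)
    eig = np.linalg.eigvalsh(S)
    if eig.min() <= 1e-12 * max(eig.max(), 1.0):
        raise DegenerateGeometryError("points are degenerate (not full-dimensional)")
    dev = P - c
    d2 = np.einsum("ij,ji->i", dev, np.linalg.solve(S, dev.T))
    return Ellipsoid(c, S, float(d2.max()), method="mve", coverage=1.0)


def _log_vol_proxy(X: np.ndarray, subset: np.ndarray) -> float:
    """log det of the subset covariance — the concentration-search objective."""
    sub = X[subset]
    cov = np.cov(sub, rowvar=False, ddof=0).reshape(X.shape[1], X.shape[1])
    sign, logdet = np.linalg.slogdet(cov)
    return logdet if sign > 0 else np.inf


def _concentration_search(X: np.ndarray, h: int, rng: np.random.Generator,
                          n_starts: int, max_c_steps: int) -> np.ndarray:
    """Vectorised FAST-MCD-style search; returns distinct candidate h-subsets."""
    n, k = X.shape
    idx = np.argsort(rng.random((n_starts, n)), axis=1)[:, :k + 1]
    B = np.zeros((n_starts, n), dtype=bool)
    np.put_along_axis(B, idx, True, axis=1)
    prev = None
    for _ in range(max_c_steps):
        cnt = B.sum(axis=1).astype(float)
        Bf = B.astype(float)
        means = (Bf @ X) / cnt[:, None]
        XB = Bf[:, :, None] * X[None, :, :]
        covs = np.einsum("snk,nl->skl", XB, X) / cnt[:, None, None] \
            - means[:, :, None] * means[:, None, :]
        inv = np.linalg.pinv(covs)
        dev = X[None, :, :] - means[:, None, :]
        d2 = np.einsum("snk,skl,snl->sn", dev, inv, dev)
        sel = np.argpartition(d2, h - 1, axis=1)[:, :h]
        newB = np.zeros_like(B)
        np.put_along_axis(newB, sel, True, axis=1)
        if prev is not None and np.array_equal(newB, prev):
            B = newB
            break
        prev = newB
        B = newB
    subsets = np.sort(np.argsort(~B, axis=1)[:, :h], axis=1)
    return np.unique(subsets, axis=0)


def fit_mve(points, coverage: float = 0.95, seed: int = 0,
            n_starts: int = 500, n_candidates: int | None = 10,
            max_c_steps: int = 30, tol: float = 1e-7,
            exhaustive_limit: int = 64) -> Ellipsoid:
    """Minimum-volume ellipsoid covering ``ceil(coverage * n)`` points.

    When the number of possible h-subsets is small (``C(n, n-h)`` at most
    ``exhaustive_limit``) every subset is wrapped exactly; otherwise a seeded
    concentration search proposes candidate subsets, the lowest-determinant
    ``n_candidates`` of which are wrapped by their minimum-volume enclosing
    ellipsoid, and the smallest-volume wrap wins (ties broken by lexicographic
    subset order).
    """
    X = _as_points(points)
    n, k = X.shape
    if not (0 < coverage <= 1):
        raise InvalidParameterError("coverage must be in (0, 1]")
    h = ceil(coverage * n)
    if h < k + 1:
        raise DegenerateGeometryError(
            f"coverage {coverage} keeps only h={h} points; need h >= k+1 = {k + 1}")

    if h == n:
        candidates = [np.arange(n)]
    elif comb(n, n - h) <= exhaustive_limit:
        candidates = [np.array(c) for c in itertools.combinations(range(n), h)]
    else:
        rng = np.random.default_rng(seed)
        subsets = _concentration_search(X, h, rng, n_starts, max_c_steps)
        dets = np.array([_log_vol_proxy(X, s) for s in subsets])
        order = np.lexsort((*subsets.T[::-1], dets))
        m = len(order) if n_candidates is None else min(n_candidates, len(order))
        candidates = [subsets[i] for i in order[:m]]

    best: Ellipsoid | None = None
    best_vol = np.inf
    best_subset: tuple[int, ...] | None = None
    n_failed = 0
    for subset in candidates:
        try:
            ell = minimum_enclosing_ellipsoid(X[subset], tol=tol)
        except DegenerateGeometryError:
            n_failed += 1
            continue
        v = volume(ell)
        if v < best_vol:
            best, best_vol, best_subset = ell, v, tuple(int(i) for i in subset)
    if best is None:
        raise DegenerateGeometryError(
            f"all {len(candidates)} candidate subsets were degenerate")
    best.method = "mve"
    best.coverage = coverage
    best.fit_info = {"n_points": n, "h": h, "subset": list(best_subset),
                     "n_candidates_tried": len(candidates),
                     "n_degenerate_subsets": n_failed,
                     "volume": best_vol}
    n_inside = int(contains(best, X).sum())
    best.fit_info["n_inside"] = n_inside
    if n_inside < h:  # cannot happen by construction; belt and braces
        best.warnings = (f"coverage shortfall: {n_inside}/{n} inside, needed {h}",)
    return best
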
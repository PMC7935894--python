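"""Jaccard overlap of ellipsoid niches and its background-resampling test.

Overlap between two periods' niche envelopes is measured over the cloud of
points formed by the union of both periods' background environments: J =
|cloud points in A and B| / |cloud points in A or B|.  Significance comes
from a null distribution of J computed for pairs of "background ellipsoids"
fitted to random background samples of the same sizes as the occurrence
sets.  A small observed J relative to that null indicates that the two
niches share less environmental space than availability alone would predict
— a niche shift.  The test is one-sided in the low-overlap tail: the null
hypothesis of conserved overlap is rejected when the observed J is at or
below the null distribution's alpha-quantile.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .ellipsoids import Ellipsoid, contains, fit_cvae, fit_mve
from .envspace import EnvMatrix
from .errors import (DegenerateGeometryError, InvalidParameterError,
                     SpaceMismatchError, UndefinedOverlapError)

_MAX_RETRIES_PER_REPLICATE = 100


def union_cloud(background_a: EnvMatrix, background_b: EnvMatrix) -> EnvMatrix:
    """Row-concatenate the two backgrounds (no deduplication).

    Both matrices must live in the same space; PC matrices must come from
    the *same* PCA transform, otherwise their axes are not comparable.
    """
    if background_a.space_tag != background_b.space_tag:
        raise SpaceMismatchError(
            f"space mismatch: {background_a.space_tag} vs {background_b.space_tag}")
    if background_a.var_names != background_b.var_names:
        raise SpaceMismatchError(
            f"variable mismatch: {background_a.var_names} vs {background_b.var_names}")
    if (background_a.space_tag == "pc"
            and background_a.transform_ref is not background_b.transform_ref):
        raise SpaceMismatchError(
            "PC matrices were produced by different PCA transforms")
    if background_a.n_points == 0:
        return background_b
    if background_b.n_points == 0:
        return background_a
    values = np.vstack([background_a.values, background_b.values])
    return EnvMatrix(values, background_a.var_names, background_a.space_tag,
                     background_a.transform_ref)


def jaccard_overlap(ell_a: Ellipsoid, ell_b: Ellipsoid, cloud: EnvMatrix) -> float:
    """J = #(cloud in A and B) / #(cloud in A or B), over a shared cloud."""
    if cloud.n_points == 0:
        raise UndefinedOverlapError("empty cloud")
    in_a = contains(ell_a, cloud)
    in_b = contains(ell_b, cloud)
    n_union = int((in_a | in_b).sum())
    if n_union == 0:
        raise UndefinedOverlapError(
            "no cloud point falls inside either ellipsoid; J is undefined")
    return float((in_a & in_b).sum() / n_union)


@dataclass
class OverlapResult:
    """Observed Jaccard overlap, its resampling null and the decision."""

    observed_j: float
    null_j: np.ndarray
    p_value: float
    alpha: float
    method: str
    n_null: int
    seed: int
    reject: bool
    null_quantile: float
    n_retries: int = 0
    warnings: tuple[str, ...] = ()
    ellipsoid_a: Ellipsoid | None = None
    ellipsoid_b: Ellipsoid | None = None

    def to_json(self, path: str | Path, include_null: bool = True) -> None:
        payload = {
            "observed_j": self.observed_j,
            "p_value": self.p_value,
            "alpha": self.alpha,
            "method": self.method,
            "n_null": self.n_null,
            "seed": self.seed,
            "reject": bool(self.reject),
            "null_quantile": self.null_quantile,
            "n_retries": self.n_retries,
            "warnings": list(self.warnings),
        }
        if include_null:
            payload["null_j"] = [float(v) for v in self.null_j]
        if self.ellipsoid_a is not None:
            payload["ellipsoid_a"] = self.ellipsoid_a.to_dict()
            payload["ellipsoid_b"] = self.ellipsoid_b.to_dict()
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _fit(method: str, points: np.ndarray, coverage: float, seed: int,
         mve_kwargs: dict) -> Ellipsoid:
    if method == "cvae":
        return fit_cvae(points, coverage)
    if method == "mve":
        return fit_mve(points, coverage, seed=seed, **mve_kwargs)
    raise InvalidParameterError(f"unknown ellipsoid method {method!r}")


def overlap_significance(occ_a: EnvMatrix, occ_b: EnvMatrix,
                         background_a: EnvMatrix, background_b: EnvMatrix,
                         method: str = "mve", coverage: float = 0.95,
                         n_null: int = 1000, alpha: float = 0.05,
                         seed: int = 0, add_one: bool = False,
                         mve_kwargs: dict | None = None) -> OverlapResult:
    """Observed niche overlap versus a null of background-ellipsoid pairs.

    Each of the ``n_null`` replicates draws ``len(occ_a)`` points from
    background A and ``len(occ_b)`` from background B (without replacement
    within a replicate, independently across replicates), fits ellipsoids
    with the same method and coverage as the observed ones, and records J on
    the union cloud.  ``p_value`` is the plain proportion of null values at
    or below the observed J (``add_one`` applies the (r+1)/(n+1)
    correction); ``reject`` compares the observed J with the empirical
    alpha-quantile of the null.
    """
    if n_null < 1:
        raise InvalidParameterError("n_null must be >= 1")
    mve_kwargs = mve_kwargs or {}
    cloud = union_cloud(background_a, background_b)
    rng = np.random.default_rng(seed)

    ell_a = _fit(method, occ_a.values, coverage, int(rng.integers(2**31)), mve_kwargs)
    ell_b = _fit(method, occ_b.values, coverage, int(rng.integers(2**31)), mve_kwargs)
    observed_j = jaccard_overlap(ell_a, ell_b, cloud)

    na, nb = occ_a.n_points, occ_b.n_points
    if background_a.n_points < na or background_b.n_points < nb:
        raise InvalidParameterError("backgrounds are smaller than the occurrence sets")
    null_j = np.empty(n_null)
    n_retries = 0
    for i in range(n_null):
        for attempt in range(_MAX_RETRIES_PER_REPLICATE):
            ia = rng.choice(background_a.n_points, size=na, replace=False)
            ib = rng.choice(background_b.n_points, size=nb, replace=False)
            try:
                ba = _fit(method, background_a.values[ia], coverage,
                          int(rng.integers(2**31)), mve_kwargs)
                bb = _fit(method, background_b.values[ib], coverage,
                          int(rng.integers(2**31)), mve_kwargs)
                null_j[i] = jaccard_overlap(ba, bb, cloud)
                break
            except (DegenerateGeometryError, UndefinedOverlapError):
                n_retries += 1
        else:
            raise DegenerateGeometryError(
                f"replicate {i}: no non-degenerate background sample after "
                f"{_MAX_RETRIES_PER_REPLICATE} retries")

    r = int((null_j <= observed_j).sum())
    p_value = (r + 1) / (n_null + 1) if add_one else r / n_null
    q = float(np.quantile(null_j, alpha))
    warnings: tuple[str, ...] = ()
    if n_retries > 0.1 * n_null:
        warnings = (f"{n_retries} degenerate replicates resampled "
                    f"(> 10% of n_null = {n_null})",)
    return OverlapResult(
        observed_j=observed_j, null_j=null_j, p_value=float(p_value),
        alpha=alpha, method=method, n_null=n_null, seed=seed,
        reject=bool(observed_j <= q), null_quantile=q, n_retries=n_retries,
        warnings=warnings, ellipsoid_a=ell_a, ellipsoid_b=ell_b)
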
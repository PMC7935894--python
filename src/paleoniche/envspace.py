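"""Environmental space: point extraction, PCA fitting and cross-scenario projection.

The comparison of niches between climate states happens in a shared principal
component space: the PCA is fit once on the calibration period's background
environments and the second period is *projected* with the stored loadings —
never re-fit — so that both periods' conditions are expressed on identical
axes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ExtractionError, InvalidParameterError, SpaceMismatchError
from .scenario import EnvScenario, OccurrenceSet


@dataclass
class EnvMatrix:
    """Points-by-variables matrix with provenance.

    ``space_tag`` distinguishes raw environmental units from principal
    component scores; PC matrices carry a reference to the transform that
    produced them so downstream overlap code can assert comparability.
    """

    values: np.ndarray
    var_names: tuple[str, ...]
    space_tag: str = "raw"
    transform_ref: "PCATransform | None" = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.var_names = tuple(self.var_names)
        if self.space_tag not in ("raw", "pc"):
            raise InvalidParameterError(f"space_tag must be 'raw' or 'pc', got {self.space_tag!r}")
        if self.values.size and self.values.shape[1] != len(self.var_names):
            raise InvalidParameterError(
                f"{self.values.shape[1]} columns but {len(self.var_names)} var_names")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("EnvMatrix contains non-finite values")

    @property
    def n_points(self) -> int:
        return self.values.shape[0]

    def subset(self, names: Sequence[str]) -> "EnvMatrix":
        idx = [self.var_names.index(n) for n in names]
        return EnvMatrix(self.values[:, idx], tuple(names), self.space_tag, self.transform_ref)


def extract_values(scenario: EnvScenario, points) -> EnvMatrix:
    """Environmental vectors of the cells containing each point.

    ``points`` is an :class:`OccurrenceSet` or a sequence of ``(id, x, y)``
    tuples.  Points outside the grid or on masked cells raise an
    :class:`ExtractionError` naming the offending ids.
    """
    if isinstance(points, OccurrenceSet):
        sites = points.sites
    else:
        sites = [(str(i), float(x), float(y)) for i, x, y in points]
    if not sites:
        raise ExtractionError("no points to extract")
    ids = [s[0] for s in sites]
    xs = np.array([s[1] for s in sites])
    ys = np.array([s[2] for s in sites])
    rows, cols = scenario.cell_index(xs, ys)
    inb = scenario.in_bounds(rows, cols)
    off = [ids[i] for i in np.nonzero(~inb)[0]]
    if off:
        raise ExtractionError(f"points outside grid bounds: {off}")
    masked = ~scenario.mask[rows, cols]
    bad = [ids[i] for i in np.nonzero(masked)[0]]
    if bad:
        raise ExtractionError(f"points on masked (invalid) cells: {bad}")
    vals = scenario.values[:, rows, cols].T.copy()
    return EnvMatrix(vals, scenario.variables, "raw")


@dataclass
class PCATransform:
    """Frozen centering/scaling/rotation fitted on one period's background.

    Scaling uses the population standard deviation (divisor *n*) of the
    fitting set, so that with ``k = n_vars`` the explained variances sum
    exactly to ``n_vars`` on standardized data.
    """

    center: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray            # n_vars x k, orthonormal columns
    explained_variance: np.ndarray  # k, non-increasing
    var_names: tuple[str, ...]

    @property
    def k(self) -> int:
        return self.loadings.shape[1]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "loadings": self.loadings.tolist(),
            "explained_variance": self.explained_variance.tolist(),
            "var_names": list(self.var_names),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "PCATransform":
        d = json.loads(Path(path).read_text())
        return cls(np.array(d["center"]), np.array(d["scale"]),
                   np.array(d["loadings"]), np.array(d["explained_variance"]),
                   tuple(d["var_names"]))

    def inverse_standardized(self, pc_values: np.ndarray) -> np.ndarray:
        """Map PC scores back to standardized variable space (exact for k = n_vars)."""
        return np.atleast_2d(pc_values) @ self.loadings.T


def fit_pca(background: EnvMatrix, k: int = 3) -> PCATransform:
    """Fit a standardized PCA on the calibration background.

    Components are eigenvectors of the population correlation matrix, ordered
    by decreasing eigenvalue.  Sign convention: each loading column's
    largest-magnitude element is positive, for backend-independent output.
    """
    if background.space_tag != "raw":
        raise SpaceMismatchError("PCA must be fit on raw environmental values")
    X = background.values
    n, p = X.shape
    if n <= p:
        raise InvalidParameterError(f"need n_points > n_vars, got {n} <= {p}")
    if not 1 <= k <= p:
        raise InvalidParameterError(f"k must be in [1, {p}], got {k}")
    center = X.mean(axis=0)
    scale = X.std(axis=0)  # population sd (ddof=0)
    if np.any(scale == 0):
        const = [background.var_names[i] for i in np.nonzero(scale == 0)[0]]
        raise InvalidParameterError(f"constant variables (sd = 0): {const}")
    Z = (X - center) / scale
    corr = Z.T @ Z / n
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    loadings = eigvec[:, :k].copy()
    for j in range(k):
        if loadings[np.argmax(np.abs(loadings[:, j])), j] < 0:
            loadings[:, j] *= -1
    return PCATransform(center, scale, loadings, eigval[:k].copy(),
                        tuple(background.var_names))


def project(transform: PCATransform, data: EnvMatrix) -> EnvMatrix:
    """Project raw environmental values into the transform's PC space."""
    if data.space_tag != "raw":
        raise SpaceMismatchError("can only project raw-space matrices")
    if data.var_names != transform.var_names:
        raise SpaceMismatchError(
            f"variable mismatch: data {data.var_names} vs transform {transform.var_names}")
    Z = (data.values - transform.center) / transform.scale
    pc = Z @ transform.loadings
    names = tuple(f"PC{i + 1}" for i in range(transform.k))
    return EnvMatrix(pc, names, "pc", transform_ref=transform)
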
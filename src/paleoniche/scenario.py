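"""Core gridded-scenario and occurrence containers.

An :class:`EnvScenario` is a labelled stack of environmental variable bands on
a regular north-up lattice with a shared validity mask (the accessible area,
*M* in the BAM framework).  Coordinates follow cell-center registration: row 0
is the northernmost row, and the affine transform is the ESRI lower-left
corner convention with square cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from .errors import InvalidParameterError

#: canonical variable order used by the synthetic generator and the pipeline
DEFAULT_VARIABLES = ("t_cold", "t_warm", "precip", "npp", "biomass")

#: variables that are physically non-negative (truncated at 0 on generation)
NON_NEGATIVE_VARIABLES = frozenset({"precip", "npp", "biomass"})


@dataclass(frozen=True)
class GridTransform:
    """Affine mapping between cell indices and geographic coordinates.

    ESRI convention: ``(xll, yll)`` is the lower-left corner of the grid and
    cells are square with side ``cellsize`` (degrees for the default 0.16°
    lattice).
    """

    xll: float
    yll: float
    cellsize: float

    def cell_center(self, row: int | np.ndarray, col: int | np.ndarray,
                    n_rows: int) -> tuple[np.ndarray, np.ndarray]:
        x = self.xll + (np.asarray(col) + 0.5) * self.cellsize
        y = self.yll + (n_rows - np.asarray(row) - 0.5) * self.cellsize
        return x, y

    def cell_index(self, x: float | np.ndarray, y: float | np.ndarray,
                   n_rows: int) -> tuple[np.ndarray, np.ndarray]:
        col = np.floor((np.asarray(x) - self.xll) / self.cellsize).astype(int)
        row = (n_rows - 1 - np.floor((np.asarray(y) - self.yll) / self.cellsize)).astype(int)
        return row, col


@dataclass
class EnvScenario:
    """Multi-band environmental lattice for one climate state."""

    label: str
    variables: tuple[str, ...]
    values: np.ndarray          # (n_vars, n_rows, n_cols)
    mask: np.ndarray            # (n_rows, n_cols) bool, True = valid land cell
    transform: GridTransform

    def __post_init__(self) -> None:
        self.variables = tuple(self.variables)
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 3 or self.values.shape[0] != len(self.variables):
            raise InvalidParameterError(
                f"values must have shape (n_vars={len(self.variables)}, n_rows, n_cols), "
                f"got {self.values.shape}")
        if self.mask.shape != self.values.shape[1:]:
            raise InvalidParameterError(
                f"mask shape {self.mask.shape} does not match bands {self.values.shape[1:]}")
        if not self.mask.any():
            raise InvalidParameterError("mask has no valid cell")
        idx = {v: i for i, v in enumerate(self.variables)}
        if "t_cold" in idx and "t_warm" in idx:
            tc = self.values[idx["t_cold"]][self.mask]
            tw = self.values[idx["t_warm"]][self.mask]
            if np.any(tw < tc - 1e-9):
                raise InvalidParameterError("t_warm < t_cold on some valid cells")
        for name in NON_NEGATIVE_VARIABLES & set(self.variables):
            if np.any(self.values[idx[name]][self.mask] < -1e-9):
                raise InvalidParameterError(f"variable '{name}' is negative on valid cells")

    # -- geometry ---------------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.values.shape[1]

    @property
    def n_cols(self) -> int:
        return self.values.shape[2]

    def cell_center(self, row, col):
        return self.transform.cell_center(row, col, self.n_rows)

    def cell_index(self, x, y):
        return self.transform.cell_index(x, y, self.n_rows)

    def in_bounds(self, row, col) -> np.ndarray:
        row = np.asarray(row)
        col = np.asarray(col)
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)

    # -- value access -----------------------------------------------------
    def valid_cells(self) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of valid cells in row-major order."""
        return np.nonzero(self.mask)

    def env_table(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Environmental matrix over valid cells.

        Returns ``(values, rows, cols)`` where ``values`` has shape
        ``(n_valid, n_vars)`` in the scenario's variable order.
        """
        rows, cols = self.valid_cells()
        return self.values[:, rows, cols].T.copy(), rows, cols

    def band(self, name: str) -> np.ndarray:
        return self.values[self.variables.index(name)]


@dataclass
class OccurrenceSet:
    """Georeferenced presence records for one period."""

    period: str
    sites: list[tuple[str, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s[0] for s in self.sites]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise InvalidParameterError(f"duplicate site ids: {dupes}")

    @property
    def ids(self) -> list[str]:
        return [s[0] for s in self.sites]

    @property
    def xy(self) -> np.ndarray:
        return np.array([(s[1], s[2]) for s in self.sites], dtype=float).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.sites)


@dataclass(frozen=True)
class TrueNiche:
    """Ground-truth ellipsoidal niche in raw environmental units.

    Used by the synthetic generator to place occurrences and by
    parameter-recovery tests; not part of any inference path.
    """

    centroid: np.ndarray
    shape: np.ndarray
    radius2: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "centroid", np.asarray(self.centroid, dtype=float))
        object.__setattr__(self, "shape", np.asarray(self.shape, dtype=float))
        S = self.shape
        if S.shape != (self.centroid.size, self.centroid.size):
            raise InvalidParameterError("shape matrix does not match centroid dimension")
        if not np.allclose(S, S.T):
            raise InvalidParameterError("shape matrix must be symmetric")
        if np.linalg.eigvalsh(S).min() <= 0:
            raise InvalidParameterError("shape matrix must be positive definite")
        if self.radius2 <= 0:
            raise InvalidParameterError("radius2 must be positive")

    def mahalanobis2(self, points: np.ndarray) -> np.ndarray:
        dev = np.atleast_2d(points) - self.centroid
        sol = np.linalg.solve(self.shape, dev.T)
        return np.einsum("ij,ji->i", dev, sol)

    def contains(self, points: np.ndarray) -> np.ndarray:
        return self.mahalanobis2(points) <= self.radius2 * (1 + 1e-12)
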
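"""Geographic products: binary maps, stability comparisons, MOP surfaces.

Continuous suitability grids become binary suitable/unsuitable maps through
the occurrence-percentile rule (cells scoring below the bottom-E% of
occurrence-cell scores are non-suitable), pairs of binary maps become
stable/lost/gained category maps, and the mobility-oriented parity (MOP)
metric flags transfer-region cells whose environments are dissimilar to —
or strictly outside the range of — the calibration conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from typing import Any

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .envspace import EnvMatrix
from .errors import InvalidParameterError
from .scenario import EnvScenario, GridTransform, OccurrenceSet

#: category codes of a ComparisonMap
CATEGORY_CODES = {"stable_unsuitable": 0, "lost": 1, "gained": 2, "stable_suitable": 3}


@dataclass
class SuitabilityGrid:
    """Continuous model prediction in [0, 1] aligned to a scenario lattice."""

    scores: np.ndarray             # (n_rows, n_cols); undefined off-mask
    mask: np.ndarray
    transform: GridTransform
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.scores.shape != self.mask.shape:
            raise InvalidParameterError("scores and mask shapes differ")
        valid = self.scores[self.mask]
        if valid.size and (valid.min() < -1e-9 or valid.max() > 1 + 1e-9):
            raise InvalidParameterError("suitability scores outside [0, 1] on valid cells")

    @property
    def n_rows(self) -> int:
        return self.scores.shape[0]

    def values_at(self, points) -> np.ndarray:
        """Scores of the cells containing each (id, x, y) point or OccurrenceSet."""
        sites = points.sites if isinstance(points, OccurrenceSet) else \
            [(str(i), float(x), float(y)) for i, x, y in points]
        xs = np.array([s[1] for s in sites])
        ys = np.array([s[2] for s in sites])
        rows, cols = self.transform.cell_index(xs, ys, self.n_rows)
        inb = (rows >= 0) & (rows < self.scores.shape[0]) & \
              (cols >= 0) & (cols < self.scores.shape[1])
        if not inb.all():
            bad = [sites[i][0] for i in np.nonzero(~inb)[0]]
            raise InvalidParameterError(f"points outside grid: {bad}")
        if not self.mask[rows, cols].all():
            bad = [sites[i][0] for i in np.nonzero(~self.mask[rows, cols])[0]]
            raise InvalidParameterError(f"points on masked cells: {bad}")
        return self.scores[rows, cols]


@dataclass
class BinaryMap:
    """Thresholded suitable (1) / non-suitable (0) map."""

    values: np.ndarray
    mask: np.ndarray
    transform: GridTransform
    threshold: float
    rule: str


@dataclass
class ComparisonMap:
    """Between-period categorical map; codes per CATEGORY_CODES."""

    categories: np.ndarray
    mask: np.ndarray
    transform: GridTransform
    counts: dict[str, int]


@dataclass
class MOPGrid:
    """Mobility-oriented parity similarity surface plus strict-extrapolation flags."""

    similarity: np.ndarray
    strict_extrapolation: np.ndarray
    mask: np.ndarray
    transform: GridTransform
    reference_percent: float


def threshold_binary(grid: SuitabilityGrid, occurrence_points,
                     percentile: float = 5.0,
                     interpolation: str = "linear") -> BinaryMap:
    """Binarise at the bottom-percentile of occurrence-cell scores.

    The threshold is the ``percentile``-th percentile (linear interpolation
    by default; pass ``interpolation="lower"`` for the discrete order
    statistic) of suitability scores at cells containing an occurrence.
    Cells scoring *strictly below* the threshold become non-suitable, so
    occurrence cells sitting exactly at the threshold remain suitable.
    """
    if not 0 < percentile < 100:
        raise InvalidParameterError("percentile must be in (0, 100)")
    occ_scores = grid.values_at(occurrence_points)
    if occ_scores.size == 0:
        raise InvalidParameterError("no occurrence points for thresholding")
    threshold = float(np.percentile(occ_scores, percentile, method=interpolation))
    values = np.zeros(grid.scores.shape, dtype=np.uint8)
    values[grid.mask & (grid.scores >= threshold)] = 1
    rule = (f"bottom {percentile}% of occurrence-cell scores "
            f"({interpolation} percentile); score < threshold -> 0")
    return BinaryMap(values, grid.mask.copy(), grid.transform, threshold, rule)


def compare_binary(map_a: BinaryMap, map_b: BinaryMap) -> ComparisonMap:
    """Per-cell stability categories between two aligned binary maps.

    (1,1) -> stable_suitable, (1,0) -> lost, (0,1) -> gained,
    (0,0) -> stable_unsuitable.  Swapping the inputs swaps lost and gained.
    """
    if map_a.values.shape != map_b.values.shape:
        raise InvalidParameterError("binary maps have different shapes")
    if map_a.transform != map_b.transform:
        raise InvalidParameterError("binary maps have different affine transforms")
    if not np.array_equal(map_a.mask, map_b.mask):
        raise InvalidParameterError("binary maps have different masks")
    a = map_a.values.astype(int)
    b = map_b.values.astype(int)
    categories = np.zeros(a.shape, dtype=np.uint8)
    categories[(a == 1) & (b == 1)] = CATEGORY_CODES["stable_suitable"]
    categories[(a == 1) & (b == 0)] = CATEGORY_CODES["lost"]
    categories[(a == 0) & (b == 1)] = CATEGORY_CODES["gained"]
    counts = {name: int(((categories == code) & map_a.mask).sum())
              for name, code in CATEGORY_CODES.items()}
    return ComparisonMap(categories, map_a.mask.copy(), map_a.transform, counts)


def mop(calibration_env: EnvMatrix, transfer: EnvScenario | EnvMatrix,
        reference_percent: float = 0.1) -> MOPGrid | tuple[np.ndarray, np.ndarray]:
    """Mobility-oriented parity of transfer conditions to calibration conditions.

    For each transfer cell, similarity = 1 − (mean Euclidean distance in
    standardized variable space to the nearest ``ceil(reference_percent*m)``
    calibration points), normalised by the maximum such distance over the
    transfer region.  Strict extrapolation is flagged wherever any variable
    leaves the calibration min–max range.
    """
    if calibration_env.n_points == 0:
        raise InvalidParameterError("empty calibration set")
    if not 0 < reference_percent <= 1:
        raise InvalidParameterError("reference_percent must be in (0, 1]")
    C = calibration_env.values
    if isinstance(transfer, EnvScenario):
        if tuple(transfer.variables) != calibration_env.var_names:
            raise InvalidParameterError("transfer variables differ from calibration")
        T, rows, cols = transfer.env_table()
    else:
        if transfer.var_names != calibration_env.var_names:
            raise InvalidParameterError("transfer variables differ from calibration")
        T, rows, cols = transfer.values, None, None

    mu = C.mean(axis=0)
    sd = C.std(axis=0)
    sd[sd == 0] = 1.0
    Cs = (C - mu) / sd
    Ts = (T - mu) / sd
    k = ceil(reference_percent * C.shape[0])
    nn = NearestNeighbors(n_neighbors=k).fit(Cs)
    dist, _ = nn.kneighbors(Ts)
    mean_d = dist.mean(axis=1)
    dmax = mean_d.max()
    similarity = np.ones_like(mean_d) if dmax == 0 else 1.0 - mean_d / dmax
    strict = ((T < C.min(axis=0)) | (T > C.max(axis=0))).any(axis=1)

    if rows is None:
        return similarity, strict
    sim_grid = np.zeros(transfer.mask.shape)
    ext_grid = np.zeros(transfer.mask.shape, dtype=bool)
    sim_grid[rows, cols] = similarity
    ext_grid[rows, cols] = strict
    return MOPGrid(sim_grid, ext_grid, transfer.mask.copy(), transfer.transform,
                   reference_percent)
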
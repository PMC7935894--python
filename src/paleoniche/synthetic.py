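"""Synthetic paired climate scenarios and occurrence samples with known truth.

Emulates the downscaled simulation outputs the analysis consumes: spatially
smooth, cross-correlated variable fields for an "interglacial" calibration
state, a mean-shifted "glacial" state sharing the same lattice and mask, an
accessible-area mask, and occurrence points drawn from a known ellipsoidal
niche.  Every operation is a pure function of its inputs and seed.

Fields are built by smoothing white noise with an isotropic Gaussian kernel
(the stated correlation length, in cells), re-standardising each band
empirically, then linearly mixing bands through a factor of the requested
correlation matrix.  Non-negative variables are truncated at 0 and the
warmest-month temperature is clipped to stay above the coldest-month band, so
moment checks should use post-truncation targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .envspace import EnvMatrix
from .errors import InfeasibleSamplingError, InvalidParameterError
from .scenario import (DEFAULT_VARIABLES, NON_NEGATIVE_VARIABLES, EnvScenario,
                       GridTransform, OccurrenceSet, TrueNiche)


@dataclass
class VarParams:
    """Per-variable means/sds and cross-variable correlation for generation."""

    names: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray
    corr: np.ndarray

    def __post_init__(self) -> None:
        self.names = tuple(self.names)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.corr = np.asarray(self.corr, dtype=float)
        p = len(self.names)
        if self.means.shape != (p,) or self.sds.shape != (p,):
            raise InvalidParameterError("means/sds length must match names")
        if self.corr.shape != (p, p):
            raise InvalidParameterError("corr must be n_vars x n_vars")
        if not np.allclose(self.corr, self.corr.T) or not np.allclose(np.diag(self.corr), 1.0):
            raise InvalidParameterError("corr must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(self.corr).min() < -1e-10:
            raise InvalidParameterError("correlation matrix is not positive semi-definite")
        if np.any(self.sds <= 0):
            raise InvalidParameterError("sds must be positive")


def default_var_params() -> VarParams:
    """Interglacial-like defaults for the five standard variables.

    Temperatures in °C, precipitation in mm/yr, NPP in gC/m²/yr, biomass in
    g/m².  Correlations encode the usual covariation of temperate Europe:
    warmer, wetter cells carry more productivity and standing biomass.
    """
    names = DEFAULT_VARIABLES
    means = np.array([1.0, 17.0, 800.0, 550.0, 9000.0])
    sds = np.array([4.0, 3.0, 250.0, 180.0, 3500.0])
    corr = np.array([
        [1.00, 0.60, 0.20, 0.55, 0.45],
        [0.60, 1.00, 0.10, 0.50, 0.40],
        [0.20, 0.10, 1.00, 0.45, 0.35],
        [0.55, 0.50, 0.45, 1.00, 0.70],
        [0.45, 0.40, 0.35, 0.70, 1.00],
    ])
    return VarParams(names, means, sds, corr)


def glacial_deltas() -> np.ndarray:
    """Default interglacial → glacial mean shifts (same order as default vars)."""
    return np.array([-8.0, -5.0, -300.0, -250.0, -4500.0])


def default_true_niche(params: VarParams | None = None,
                       scale: float = 1.0) -> TrueNiche:
    """Ellipsoidal truth centred on slightly-warmer-than-mean conditions.

    The shape is the diagonal of squared variable sds shrunk to cover a
    sub-volume of the environmental cloud; ``radius2`` is the chi-square 0.95
    quantile so roughly the central band of conditions is 'in niche'.
    """
    from scipy.stats import chi2

    p = params or default_var_params()
    centroid = p.means + 0.3 * p.sds
    shape = np.diag((0.8 * p.sds) ** 2) * scale
    return TrueNiche(centroid, shape, float(chi2.ppf(0.95, len(p.names))))


def _smooth_standard_fields(rng: np.random.Generator, n_fields: int,
                            n_rows: int, n_cols: int,
                            corr_length: float) -> np.ndarray:
    """White noise → Gaussian-smoothed, empirically standardized fields."""
    fields = rng.standard_normal((n_fields, n_rows, n_cols))
    if corr_length > 0:
        fields = ndimage.gaussian_filter(fields, sigma=(0, corr_length, corr_length),
                                         mode="reflect")
    mean = fields.mean(axis=(1, 2), keepdims=True)
    sd = fields.std(axis=(1, 2), keepdims=True)
    return (fields - mean) / sd


def _psd_factor(corr: np.ndarray) -> np.ndarray:
    """Square factor L with L Lᵀ = corr, valid for singular PSD matrices."""
    w, v = np.linalg.eigh(corr)
    w = np.clip(w, 0.0, None)
    return v * np.sqrt(w)


def _apply_physical_constraints(values: np.ndarray, names: tuple[str, ...]) -> np.ndarray:
    idx = {v: i for i, v in enumerate(names)}
    for name in NON_NEGATIVE_VARIABLES & set(names):
        np.clip(values[idx[name]], 0.0, None, out=values[idx[name]])
    if "t_cold" in idx and "t_warm" in idx:
        values[idx["t_warm"]] = np.maximum(values[idx["t_warm"]], values[idx["t_cold"]])
    return values


def generate_scenario(n_rows: int = 100, n_cols: int = 100,
                      var_params: VarParams | None = None,
                      spatial_corr_length: float = 3.0,
                      seed: int = 0,
                      label: str = "interglacial",
                      mask: np.ndarray | None = None,
                      land_fraction: float = 0.85,
                      transform: GridTransform | None = None) -> EnvScenario:
    """Generate one scenario of spatially smooth, correlated variable fields.

    The default 100x100 lattice at 0.16° spacing matches the scale of the
    downscaled paleoclimate grids the pipeline is designed for.  When ``mask``
    is None an accessible-area mask covering ``land_fraction`` of cells is
    carved from an independent smooth field.
    """
    if n_rows < 8 or n_cols < 8:
        raise InvalidParameterError("n_rows and n_cols must be >= 8")
    params = var_params or default_var_params()
    p = len(params.names)
    rng = np.random.default_rng(seed)

    fields = _smooth_standard_fields(rng, p, n_rows, n_cols, spatial_corr_length)
    L = _psd_factor(params.corr)
    mixed = np.einsum("ij,jrc->irc", L, fields)
    values = params.means[:, None, None] + params.sds[:, None, None] * mixed
    values = _apply_physical_constraints(values, params.names)

    if mask is None:
        mfield = _smooth_standard_fields(rng, 1, n_rows, n_cols,
                                         max(spatial_corr_length, 2.0))[0]
        if land_fraction >= 1.0:
            mask = np.ones((n_rows, n_cols), dtype=bool)
        else:
            mask = mfield >= np.quantile(mfield, 1.0 - land_fraction)
    else:
        mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise InvalidParameterError("mask has zero valid area")

    tfm = transform or GridTransform(xll=-8.0, yll=38.0, cellsize=0.16)
    return EnvScenario(label, params.names, values, mask, tfm)


def shift_scenario(scenario: EnvScenario, mean_deltas, seed: int = 0,
                   noise_sds=None, spatial_corr_length: float = 3.0,
                   label: str | None = None) -> EnvScenario:
    """Mean-shifted copy of a scenario (the interglacial → glacial transition).

    ``mean_deltas`` has one entry per variable.  With ``noise_sds`` given, an
    independent smooth field scaled by the per-variable sd is added, so the
    two states share spatial structure but are not deterministically related.
    Physical constraints (non-negativity, t_warm >= t_cold) are re-applied.
    """
    deltas = np.asarray(mean_deltas, dtype=float)
    if deltas.shape != (len(scenario.variables),):
        raise InvalidParameterError(
            f"expected {len(scenario.variables)} deltas, got {deltas.shape}")
    values = scenario.values + deltas[:, None, None]
    if noise_sds is not None:
        nsd = np.asarray(noise_sds, dtype=float)
        if nsd.shape != deltas.shape:
            raise InvalidParameterError("noise_sds length must match variables")
        rng = np.random.default_rng(seed)
        noise = _smooth_standard_fields(rng, len(nsd), scenario.n_rows,
                                        scenario.n_cols, spatial_corr_length)
        values = values + nsd[:, None, None] * noise
    values = _apply_physical_constraints(values, scenario.variables)
    return EnvScenario(label or f"{scenario.label}_shifted", scenario.variables,
                       values, scenario.mask.copy(), scenario.transform)


def sample_occurrences(scenario: EnvScenario, true_niche: TrueNiche, n: int,
                       seed: int = 0, period: str = "A",
                       id_prefix: str = "site") -> OccurrenceSet:
    """Sample n sites uniformly among distinct valid cells inside the niche."""
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    env, rows, cols = scenario.env_table()
    inside = true_niche.contains(env)
    eligible = np.nonzero(inside)[0]
    if eligible.size < n:
        raise InfeasibleSamplingError(
            f"only {eligible.size} valid cells inside the true niche, need {n}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(eligible, size=n, replace=False)
    x, y = scenario.cell_center(rows[chosen], cols[chosen])
    sites = [(f"{id_prefix}{i:03d}", float(xi), float(yi))
             for i, (xi, yi) in enumerate(zip(x, y))]
    return OccurrenceSet(period, sites)


def make_background(scenario: EnvScenario, max_points: int = 10_000,
                    seed: int = 0) -> tuple[EnvMatrix, np.ndarray]:
    """Uniform no-replacement sample of valid cells (the modelling background).

    Returns the environmental matrix and the (x, y) cell-center coordinates;
    the sample size is ``min(max_points, n_valid_cells)``.
    """
    if max_points < 1:
        raise InvalidParameterError("max_points must be >= 1")
    env, rows, cols = scenario.env_table()
    m = min(max_points, env.shape[0])
    rng = np.random.default_rng(seed)
    chosen = rng.choice(env.shape[0], size=m, replace=False)
    chosen.sort()
    x, y = scenario.cell_center(rows[chosen], cols[chosen])
    coords = np.column_stack([x, y])
    return EnvMatrix(env[chosen], scenario.variables, "raw"), coords
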
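"""Presence-background suitability modelling and kuenm-style calibration.

The model is the exponential family over the finite background: p(x) ∝
exp(λᵀf(x)), normalised so that the raw scores of the background cells sum
to one — the same object Maxent estimates.  Feature expansions follow the
Maxent letter codes on standardized variables (l: xᵢ, q: xᵢ², p: xᵢxⱼ for
i<j), weights are fit by maximising the presence log-likelihood with an L1
penalty proportional to the regularization multiplier, and calibration
proceeds through the classic three-stage selection: partial-ROC
significance, omission rate at the error level E, and ΔAICc < 2.

Candidate models form the Cartesian product of variable subsets (size >= 2),
regularization multipliers and feature classes; with the five standard
variables, the 17 default multipliers and the five feature classes this grid
has 26 x 17 x 5 = 2210 members.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import ceil
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .envspace import EnvMatrix
from .errors import InvalidParameterError
from .geographic import SuitabilityGrid
from .scenario import EnvScenario, OccurrenceSet

FEATURE_CLASSES = ("q", "qp", "lp", "lq", "lqp")

#: weights below this count as zero when counting AICc parameters
_LAMBDA_ZERO_TOL = 1e-8


def default_multipliers() -> list[float]:
    """0.1–1.0 by 0.1, 2–6 by 1, then 8 and 10 (17 values)."""
    return [round(0.1 * i, 1) for i in range(1, 11)] + [2.0, 3.0, 4.0, 5.0, 6.0, 8.0, 10.0]


@dataclass(frozen=True)
class CandidateSpec:
    """One candidate parameterization: variable subset x multiplier x features."""

    variables: tuple[str, ...]
    reg_multiplier: float
    feature_class: str

    def __post_init__(self) -> None:
        if len(self.variables) < 2:
            raise InvalidParameterError("variable subset must have size >= 2")
        if self.reg_multiplier <= 0:
            raise InvalidParameterError("reg_multiplier must be positive")
        if self.feature_class not in FEATURE_CLASSES:
            raise InvalidParameterError(
                f"feature_class must be one of {FEATURE_CLASSES}, got {self.feature_class!r}")

    def key(self) -> str:
        return f"{'+'.join(self.variables)}|m{self.reg_multiplier}|{self.feature_class}"


def candidate_grid(variables: Sequence[str],
                   multipliers: Sequence[float] | None = None,
                   feature_classes: Sequence[str] = FEATURE_CLASSES
                   ) -> list[CandidateSpec]:
    """All subsets of size >= 2, crossed with multipliers and feature classes.

    Deterministic order: subsets by size then lexicographically, multipliers
    and feature classes in the order given.
    """
    variables = tuple(variables)
    if len(variables) < 2:
        raise InvalidParameterError("need at least 2 variables")
    multipliers = list(default_multipliers() if multipliers is None else multipliers)
    feature_classes = list(feature_classes)
    if not multipliers or not feature_classes:
        raise InvalidParameterError("multipliers and feature_classes must be non-empty")
    subsets = [combo for r in range(2, len(variables) + 1)
               for combo in itertools.combinations(variables, r)]
    return [CandidateSpec(s, float(m), fc)
            for s in subsets for m in multipliers for fc in feature_classes]


def split_indices(n: int, test_fraction: float = 0.25,
                  seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Seeded disjoint exhaustive split with |test| = round(test_fraction * n)."""
    if n < 4:
        raise InvalidParameterError("need at least 4 occurrences to split")
    n_test = int(round(test_fraction * n))
    perm = np.random.default_rng(seed).permutation(n)
    return np.sort(perm[n_test:]), np.sort(perm[:n_test])


def split_occurrences(occ: OccurrenceSet, test_fraction: float = 0.25,
                      seed: int = 0) -> tuple[OccurrenceSet, OccurrenceSet]:
    train_idx, test_idx = split_indices(len(occ), test_fraction, seed)
    return (OccurrenceSet(occ.period, [occ.sites[i] for i in train_idx]),
            OccurrenceSet(occ.period, [occ.sites[i] for i in test_idx]))


def expand_features(Z: np.ndarray, var_names: Sequence[str],
                    feature_class: str) -> tuple[np.ndarray, list[str]]:
    """Polynomial expansion of standardized variables per the letter codes."""
    cols, names = [], []
    if "l" in feature_class:
        for j, v in enumerate(var_names):
            cols.append(Z[:, j])
            names.append(v)
    if "q" in feature_class:
        for j, v in enumerate(var_names):
            cols.append(Z[:, j] ** 2)
            names.append(f"{v}^2")
    if "p" in feature_class:
        for i, j in itertools.combinations(range(len(var_names)), 2):
            cols.append(Z[:, i] * Z[:, j])
            names.append(f"{var_names[i]}*{var_names[j]}")
    return np.column_stack(cols), names


@dataclass
class FittedModel:
    """Exponential-family suitability model normalised over its background."""

    spec: CandidateSpec
    lambdas: np.ndarray
    feature_names: list[str]
    bg_mean: np.ndarray
    bg_sd: np.ndarray
    log_z: float
    max_log_raw: float
    converged: bool
    n_train: int
    train_ids: list[str] | None = None
    test_ids: list[str] | None = None

    def _features(self, values: np.ndarray) -> np.ndarray:
        Z = (values - self.bg_mean) / self.bg_sd
        F, _ = expand_features(Z, self.spec.variables, self.spec.feature_class)
        return F

    def _subset_values(self, env: EnvMatrix) -> np.ndarray:
        missing = [v for v in self.spec.variables if v not in env.var_names]
        if missing:
            raise InvalidParameterError(f"environment lacks model variables: {missing}")
        idx = [env.var_names.index(v) for v in self.spec.variables]
        return env.values[:, idx]

    def log_raw(self, env: EnvMatrix) -> np.ndarray:
        """log of the background-normalised raw score at each point."""
        return self._features(self._subset_values(env)) @ self.lambdas - self.log_z

    def suitability(self, env: EnvMatrix) -> np.ndarray:
        """Raw score rescaled to [0, 1] by the background maximum (clipped
        at 1 under free extrapolation)."""
        return np.clip(np.exp(self.log_raw(env) - self.max_log_raw), 0.0, 1.0)

    @property
    def n_parameters(self) -> int:
        return int((np.abs(self.lambdas) > _LAMBDA_ZERO_TOL).sum())

    def to_dict(self) -> dict:
        return {
            "variables": list(self.spec.variables),
            "reg_multiplier": self.spec.reg_multiplier,
            "feature_class": self.spec.feature_class,
            "lambdas": self.lambdas.tolist(),
            "feature_names": self.feature_names,
            "bg_mean": self.bg_mean.tolist(),
            "bg_sd": self.bg_sd.tolist(),
            "log_z": self.log_z,
            "max_log_raw": self.max_log_raw,
            "converged": self.converged,
            "n_train": self.n_train,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedModel":
        spec = CandidateSpec(tuple(d["variables"]), d["reg_multiplier"], d["feature_class"])
        return cls(spec, np.array(d["lambdas"]), list(d["feature_names"]),
                   np.array(d["bg_mean"]), np.array(d["bg_sd"]), d["log_z"],
                   d["max_log_raw"], d["converged"], d["n_train"])


def fit_suitability(train_env: EnvMatrix, background_env: EnvMatrix,
                    spec: CandidateSpec, max_iter: int = 500) -> FittedModel:
    """Fit the penalized exponential-family model for one candidate spec.

    Maximises mean presence log-likelihood minus an L1 penalty of
    ``reg_multiplier / sqrt(n_train)`` per feature weight, via L-BFGS-B on
    the positive/negative split of λ (an exact reformulation of the L1
    problem).  Variables are standardized by the background mean and sd.
    """
    idx_bg = [background_env.var_names.index(v) for v in spec.variables]
    idx_tr = [train_env.var_names.index(v) for v in spec.variables]
    Xb = background_env.values[:, idx_bg]
    Xt = train_env.values[:, idx_tr]
    mu = Xb.mean(axis=0)
    sd = Xb.std(axis=0)
    if np.any(sd == 0):
        raise InvalidParameterError("constant variable in background")
    Fb, names = expand_features((Xb - mu) / sd, spec.variables, spec.feature_class)
    Ft, _ = expand_features((Xt - mu) / sd, spec.variables, spec.feature_class)
    q = Fb.shape[1]
    n_train = Ft.shape[0]
    beta = spec.reg_multiplier / np.sqrt(n_train)
    f_mean = Ft.mean(axis=0)

    def objective(theta: np.ndarray):
        lam = theta[:q] - theta[q:]
        s = Fb @ lam
        lz = logsumexp(s)
        negll = -f_mean @ lam + lz
        w = np.exp(s - lz)
        grad_lam = -f_mean + w @ Fb
        grad = np.concatenate([grad_lam + beta, -grad_lam + beta])
        return negll + beta * theta.sum(), grad

    res = minimize(objective, np.zeros(2 * q), jac=True, method="L-BFGS-B",
                   bounds=[(0, None)] * (2 * q),
                   options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-8})
    lam = res.x[:q] - res.x[q:]
    s_bg = Fb @ lam
    log_z = float(logsumexp(s_bg))
    return FittedModel(spec, lam, names, mu, sd, log_z,
                       float(s_bg.max() - log_z), bool(res.success), n_train)


def predict_suitability(model: FittedModel,
                        env: EnvMatrix | EnvScenario) -> np.ndarray | SuitabilityGrid:
    """Suitability scores for points (EnvMatrix) or a whole scenario lattice."""
    if isinstance(env, EnvMatrix):
        return model.suitability(env)
    values, rows, cols = env.env_table()
    scores = model.suitability(EnvMatrix(values, env.variables, "raw"))
    grid = np.zeros(env.mask.shape)
    grid[rows, cols] = scores
    return SuitabilityGrid(grid, env.mask.copy(), env.transform,
                           provenance={"model": model.spec.key(), "scenario": env.label})


# ---------------------------------------------------------------------------
# Evaluation metrics
# ---------------------------------------------------------------------------

def train_threshold(train_scores: np.ndarray, E: float = 0.05) -> float:
    """E-percentile of training-occurrence scores (the omission threshold)."""
    return float(np.percentile(np.asarray(train_scores), 100 * E))


def omission_rate(test_scores: np.ndarray, threshold: float) -> float:
    """Proportion of test occurrences scoring strictly below the threshold."""
    test_scores = np.asarray(test_scores)
    if test_scores.size == 0:
        raise InvalidParameterError("empty test set")
    return float((test_scores < threshold).mean())


@dataclass
class PartialROCResult:
    mean_auc_ratio: float
    proc_p: float
    ratios: np.ndarray


def partial_roc(test_scores: np.ndarray, grid_scores: np.ndarray,
                E: float = 0.05, n_iter: int = 500,
                bootstrap_fraction: float = 0.5, seed: int = 0) -> PartialROCResult:
    """Bootstrap partial-ROC AUC ratios above the omission level E.

    Each iteration resamples ``ceil(bootstrap_fraction * n_test)`` test
    points with replacement and computes (partial AUC of the model where
    sensitivity >= 1-E) / (partial AUC of the random-prediction diagonal on
    the same proportional-area interval).  ``proc_p`` is the proportion of
    ratios <= 1 (the model no better than random).
    """
    test_scores = np.asarray(test_scores, dtype=float)
    grid_scores = np.asarray(grid_scores, dtype=float)
    if n_iter < 1 or not 0 < bootstrap_fraction <= 1 or not 0 < E < 0.5:
        raise InvalidParameterError("invalid partial ROC parameters")
    if test_scores.size == 0:
        raise InvalidParameterError("empty test set")
    if np.ptp(grid_scores) == 0:
        raise InvalidParameterError("constant grid scores: partial ROC undefined")

    thresholds = np.unique(np.quantile(grid_scores, np.linspace(0, 1, 201)))
    area = (grid_scores[:, None] >= thresholds[None, :]).mean(axis=0)
    rng = np.random.default_rng(seed)
    m = ceil(bootstrap_fraction * test_scores.size)
    samples = rng.choice(test_scores, size=(n_iter, m), replace=True)
    sens = (samples[:, :, None] >= thresholds[None, None, :]).mean(axis=1)

    ratios = np.full(n_iter, np.nan)
    for i in range(n_iter):
        keep = sens[i] >= 1 - E
        if keep.sum() < 2:
            continue
        xs, ys = area[keep], sens[i][keep]
        order = np.argsort(xs)
        xs, ys = xs[order], ys[order]
        auc_model = np.trapezoid(ys, xs)
        auc_random = np.trapezoid(xs, xs)
        if auc_random > 0:
            ratios[i] = auc_model / auc_random
    valid = ratios[np.isfinite(ratios)]
    if valid.size == 0:
        raise InvalidParameterError("no iteration produced a defined AUC ratio")
    return PartialROCResult(float(valid.mean()), float((valid <= 1).mean()), ratios)


def aicc(model: FittedModel, occ_log_raw: np.ndarray, n_occ: int | None = None) -> float:
    """Small-sample AIC from the normalised raw scores at the occurrences.

    ``occ_log_raw`` holds log background-normalised raw scores; k is the
    count of non-zero weights.  Undefined when n - k - 1 <= 0.
    """
    occ_log_raw = np.asarray(occ_log_raw)
    n = int(n_occ if n_occ is not None else occ_log_raw.size)
    k = model.n_parameters
    if n - k - 1 <= 0:
        raise InvalidParameterError(
            f"AICc undefined: n={n}, k={k} gives n-k-1 <= 0")
    ll = float(occ_log_raw.sum())
    return 2 * k - 2 * ll + 2 * k * (k + 1) / (n - k - 1)


# ---------------------------------------------------------------------------
# Candidate evaluation and three-stage selection
# ---------------------------------------------------------------------------

@dataclass
class EvaluationResult:
    spec: CandidateSpec
    mean_auc_ratio: float = np.nan
    proc_p: float = np.nan
    omission_rate: float = np.nan
    aicc: float = np.nan
    delta_aicc: float = np.nan
    selected: bool = False
    excluded_reason: str | None = None


@dataclass
class SelectionResult:
    """Survivors of the sequential significance → omission → ΔAICc filter."""

    selected: list[CandidateSpec]
    stage_counts: dict[str, int]
    evaluations: list[EvaluationResult]


def evaluate_candidates(occ_env: EnvMatrix, background_env: EnvMatrix,
                        specs: Sequence[CandidateSpec], E: float = 0.05,
                        test_fraction: float = 0.25, n_proc_iter: int = 500,
                        bootstrap_fraction: float = 0.5,
                        seed: int = 0) -> list[EvaluationResult]:
    """Fit and evaluate every candidate on one shared train/test split.

    Partial ROC and omission use the 75/25 split; AICc uses a model refit to
    all occurrences (the kuenm convention).  Candidates that fail to
    converge or whose AICc is undefined carry an ``excluded_reason`` and do
    not enter selection.
    """
    train_idx, test_idx = split_indices(occ_env.n_points, test_fraction, seed)
    train_env = EnvMatrix(occ_env.values[train_idx], occ_env.var_names, "raw")
    test_env = EnvMatrix(occ_env.values[test_idx], occ_env.var_names, "raw")
    results = []
    for i, spec in enumerate(specs):
        result = EvaluationResult(spec)
        try:
            model = fit_suitability(train_env, background_env, spec)
            if not model.converged:
                result.excluded_reason = "optimizer did not converge"
                results.append(result)
                continue
            train_scores = model.suitability(train_env)
            test_scores = model.suitability(test_env)
            grid_scores = model.suitability(background_env)
            result.omission_rate = omission_rate(
                test_scores, train_threshold(train_scores, E))
            proc = partial_roc(test_scores, grid_scores, E, n_proc_iter,
                               bootstrap_fraction, seed=seed + 7919 * i)
            result.mean_auc_ratio = proc.mean_auc_ratio
            result.proc_p = proc.proc_p
            full = fit_suitability(occ_env, background_env, spec)
            result.aicc = aicc(full, full.log_raw(occ_env))
        except InvalidParameterError as exc:
            result.excluded_reason = str(exc)
        results.append(result)
    finite = [r.aicc for r in results if np.isfinite(r.aicc)]
    if finite:
        best = min(finite)
        for r in results:
            if np.isfinite(r.aicc):
                r.delta_aicc = r.aicc - best
    return results


def select_models(evaluations: Sequence[EvaluationResult], E: float = 0.05,
                  alpha: float = 0.05, delta_cap: float = 2.0) -> SelectionResult:
    """Sequential filter: proc_p < alpha, then omission < E, then ΔAICc.

    ΔAICc is recomputed among the survivors of the first two stages, per the
    calibration protocol; several specs can survive.  An empty selection is
    returned explicitly with per-stage counts rather than raised.
    """
    usable = [e for e in evaluations if e.excluded_reason is None]
    stage1 = [e for e in usable if e.proc_p < alpha]
    stage2 = [e for e in stage1 if e.omission_rate < E]
    with_aicc = [e for e in stage2 if np.isfinite(e.aicc)]
    counts = {"candidates": len(list(evaluations)), "usable": len(usable),
              "significant": len(stage1), "low_omission": len(stage2),
              "with_aicc": len(with_aicc)}
    if not with_aicc:
        counts["selected"] = 0
        return SelectionResult([], counts, list(evaluations))
    best = min(e.aicc for e in with_aicc)
    survivors = sorted((e for e in with_aicc if e.aicc - best < delta_cap),
                       key=lambda e: e.aicc)
    for e in evaluations:
        e.selected = False
    for e in survivors:
        e.selected = True
    counts["selected"] = len(survivors)
    return SelectionResult([e.spec for e in survivors], counts, list(evaluations))


# ---------------------------------------------------------------------------
# Final models
# ---------------------------------------------------------------------------

def final_models(spec: CandidateSpec, occ_env: EnvMatrix,
                 background_env: EnvMatrix, n_reps: int = 10,
                 seed: int = 0) -> list[FittedModel]:
    """Bootstrap-replicate final fits of the selected parameterization."""
    if n_reps < 1:
        raise InvalidParameterError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    models = []
    for _ in range(n_reps):
        idx = rng.choice(occ_env.n_points, size=occ_env.n_points, replace=True)
        boot = EnvMatrix(occ_env.values[idx], occ_env.var_names, "raw")
        models.append(fit_suitability(boot, background_env, spec))
    return models


def median_suitability(models: Sequence[FittedModel], scenario: EnvScenario
                       ) -> tuple[SuitabilityGrid, list[SuitabilityGrid]]:
    """Cell-wise median grid over replicate model predictions."""
    grids = [predict_suitability(m, scenario) for m in models]
    stack = np.stack([g.scores for g in grids])
    med = np.median(stack, axis=0)
    med[~scenario.mask] = 0.0
    grid = SuitabilityGrid(med, scenario.mask.copy(), scenario.transform,
                           provenance={"model": models[0].spec.key(),
                                       "scenario": scenario.label,
                                       "n_replicates": len(models),
                                       "aggregate": "median"})
    return grid, grids
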
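"""End-to-end orchestration: simulate → calibrate → finalize → transfer →
threshold → compare → overlap-test → MOP → report.

Every stage is a function of ``(config, outdir)`` that reads its inputs from
and writes its artifacts into the run directory, so any stage can be
replayed in isolation (the CLI exposes one subcommand per stage).  All
randomness flows from a single master seed through per-stage seeds derived
as ``sha256(f"{master_seed}:{stage}") mod 2^31``; identical configurations
therefore produce byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .envspace import EnvMatrix, extract_values, fit_pca, project
from .errors import InvalidParameterError, PipelineStageError
from .geographic import compare_binary, mop, threshold_binary
from .overlap import overlap_significance
from .scenario import EnvScenario, OccurrenceSet
from .suitability import (FEATURE_CLASSES, CandidateSpec, FittedModel,
                          candidate_grid, evaluate_candidates, final_models,
                          median_suitability, select_models)
from .synthetic import (default_true_niche, default_var_params,
                        generate_scenario, glacial_deltas, make_background,
                        shift_scenario)

logger = logging.getLogger("paleoniche")

STAGES = ("simulate", "background", "calibrate", "finalize", "transfer",
          "threshold", "compare", "overlap", "mop", "report")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:8], "big") % (2**31)


@dataclass
class RunConfig:
    """All pipeline parameters; defaults reproduce the calibration protocol
    (E = 5%, 17 multipliers x 5 feature classes, 500 pROC iterations at 50%
    bootstrap, 25% test split, 10 bootstrap replicates, 1000 null ellipsoid
    pairs, bottom-5% binary threshold)."""

    # inputs: either simulate, or point at scenario dirs + occurrence CSV
    simulate: bool = True
    scenario_a_dir: str | None = None
    scenario_b_dir: str | None = None
    occurrences_path: str | None = None
    period_a: str = "A"
    period_b: str = "B"
    # synthetic-scenario conditions
    n_rows: int = 100
    n_cols: int = 100
    spatial_corr_length: float = 3.0
    land_fraction: float = 0.85
    shift_noise_fraction: float = 0.3
    n_occ_a: int = 30
    n_occ_b: int = 30
    occupancy: str = "territorial"   # or "niche_tracking"
    # modelling settings
    background_max: int = 10_000
    E: float = 0.05
    alpha: float = 0.05
    delta_cap: float = 2.0
    multipliers: list[float] | None = None
    feature_classes: list[str] = field(default_factory=lambda: list(FEATURE_CLASSES))
    test_fraction: float = 0.25
    n_proc_iter: int = 500
    bootstrap_fraction: float = 0.5
    n_reps: int = 10
    # environmental-space / overlap settings
    pca_components: int = 3
    coverage: float = 0.95
    n_null: int = 1000
    mve_n_starts: int = 500
    mve_n_candidates: int = 10
    # geographic settings
    percentile: float = 5.0
    mop_reference: float = 0.1
    master_seed: int = 1

    def __post_init__(self) -> None:
        for name in ("E", "alpha", "test_fraction", "bootstrap_fraction",
                     "coverage", "mop_reference"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise InvalidParameterError(f"{name} must be in (0, 1], got {v}")
        if not 0 < self.percentile < 100:
            raise InvalidParameterError("percentile must be in (0, 100)")
        if self.occupancy not in ("territorial", "niche_tracking"):
            raise InvalidParameterError("occupancy must be territorial|niche_tracking")
        if not self.simulate:
            missing = [n for n in ("scenario_a_dir", "scenario_b_dir", "occurrences_path")
                       if getattr(self, n) is None]
            if missing:
                raise InvalidParameterError(
                    f"simulate=false requires paths: missing {missing}")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# artifact helpers
# ---------------------------------------------------------------------------

def _load_scenario(config: RunConfig, outdir: Path, which: str) -> EnvScenario:
    if config.simulate:
        return pio.read_scenario(outdir / f"scenario_{which}")
    return pio.read_scenario(getattr(config, f"scenario_{which}_dir"))


def _load_occurrences(config: RunConfig, outdir: Path) -> dict[str, OccurrenceSet]:
    path = (outdir / "occurrences.csv") if config.simulate else config.occurrences_path
    return pio.read_occurrences(path, [config.period_a, config.period_b])


def _write_background(env: EnvMatrix, coords: np.ndarray, path: Path) -> None:
    df = pd.DataFrame(env.values, columns=list(env.var_names))
    df.insert(0, "y", coords[:, 1])
    df.insert(0, "x", coords[:, 0])
    df.to_csv(path, index=False)


def _read_background(path: Path) -> tuple[EnvMatrix, np.ndarray]:
    df = pd.read_csv(path)
    coords = df[["x", "y"]].to_numpy()
    names = tuple(c for c in df.columns if c not in ("x", "y"))
    return EnvMatrix(df[list(names)].to_numpy(), names, "raw"), coords


def _suffix(config: RunConfig, period: str) -> str:
    return "a" if period == config.period_a else "b"


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: RunConfig, outdir: Path) -> None:
    """Generate the paired scenarios and occurrence sets with known truth."""
    if not config.simulate:
        logger.info("simulate: skipped (external inputs configured)")
        return
    params = default_var_params()
    scn_a = generate_scenario(config.n_rows, config.n_cols, params,
                              config.spatial_corr_length,
                              seed=stage_seed(config.master_seed, "simulate:a"),
                              label=config.period_a,
                              land_fraction=config.land_fraction)
    noise = config.shift_noise_fraction * params.sds if config.shift_noise_fraction else None
    scn_b = shift_scenario(scn_a, glacial_deltas(),
                           seed=stage_seed(config.master_seed, "simulate:b"),
                           noise_sds=noise, label=config.period_b)
    niche = default_true_niche(params)

    env_a, rows, cols = scn_a.env_table()
    eligible = np.nonzero(niche.contains(env_a))[0]
    if config.occupancy == "territorial":
        # period-B groups keep period-A territories: same eligible cells,
        # whose environments have meanwhile changed
        eligible_b = eligible
    else:
        env_b, _, _ = scn_b.env_table()
        eligible_b = np.nonzero(niche.contains(env_b))[0]
    occ_sets = []
    for period, elig, n, tag in ((config.period_a, eligible, config.n_occ_a, "occ:a"),
                                 (config.period_b, eligible_b, config.n_occ_b, "occ:b")):
        if elig.size < n:
            raise InvalidParameterError(
                f"only {elig.size} eligible cells for period {period}, need {n}")
        rng = np.random.default_rng(stage_seed(config.master_seed, tag))
        chosen = rng.choice(elig, size=n, replace=False)
        x, y = scn_a.cell_center(rows[chosen], cols[chosen])
        sites = [(f"{period}_site{i:03d}", float(xi), float(yi))
                 for i, (xi, yi) in enumerate(zip(x, y))]
        occ_sets.append(OccurrenceSet(period, sites))

    pio.write_scenario(scn_a, outdir / "scenario_a")
    pio.write_scenario(scn_b, outdir / "scenario_b")
    pio.write_occurrences(occ_sets, outdir / "occurrences.csv")
    pio.save_json({"centroid": niche.centroid.tolist(),
                   "shape": niche.shape.tolist(),
                   "radius2": niche.radius2,
                   "occupancy": config.occupancy}, outdir / "true_niche.json")


def stage_background(config: RunConfig, outdir: Path) -> None:
    for which in ("a", "b"):
        scn = _load_scenario(config, outdir, which)
        env, coords = make_background(scn, config.background_max,
                                      seed=stage_seed(config.master_seed,
                                                      f"background:{which}"))
        _write_background(env, coords, outdir / f"background_{which}.csv")


def stage_calibrate(config: RunConfig, outdir: Path,
                    periods: tuple[str, ...] | None = None) -> None:
    """Evaluate the candidate grid and select parameterizations per period.

    If the strict three-stage filter leaves no survivor, selection falls
    back (recorded in the artifact) to significant models under ΔAICc only,
    then to the single best-AICc usable model.
    """
    occ_all = _load_occurrences(config, outdir)
    for period in periods or (config.period_a, config.period_b):
        which = _suffix(config, period)
        scn = _load_scenario(config, outdir, which)
        background, _ = _read_background(outdir / f"background_{which}.csv")
        occ_env = extract_values(scn, occ_all[period])
        specs = candidate_grid(scn.variables, config.multipliers,
                               config.feature_classes)
        seed = stage_seed(config.master_seed, f"calibrate:{which}")
        evals = evaluate_candidates(occ_env, background, specs, config.E,
                                    config.test_fraction, config.n_proc_iter,
                                    config.bootstrap_fraction, seed)
        sel = select_models(evals, config.E, config.alpha, config.delta_cap)
        rule = "strict"
        chosen = sel.selected
        if not chosen:
            significant = [e for e in evals if e.excluded_reason is None
                           and e.proc_p < config.alpha and np.isfinite(e.aicc)]
            pool = significant or [e for e in evals if e.excluded_reason is None
                                   and np.isfinite(e.aicc)]
            rule = "no_omission" if significant else "best_aicc"
            if not pool:
                raise PipelineStageError(
                    "calibrate", f"period {period}: no usable candidate "
                    f"(stage counts {sel.stage_counts})")
            chosen = [min(pool, key=lambda e: e.aicc).spec]
        pd.DataFrame([{
            "candidate": e.spec.key(),
            "variables": "+".join(e.spec.variables),
            "reg_multiplier": e.spec.reg_multiplier,
            "feature_class": e.spec.feature_class,
            "mean_auc_ratio": e.mean_auc_ratio, "proc_p": e.proc_p,
            "omission_rate": e.omission_rate, "aicc": e.aicc,
            "delta_aicc": e.delta_aicc, "selected": e.selected,
            "excluded_reason": e.excluded_reason or "",
        } for e in evals]).to_csv(outdir / f"evaluations_{which}.csv", index=False)
        pio.save_json({
            "period": period,
            "n_candidates": len(specs),
            "stage_counts": sel.stage_counts,
            "selection_rule": rule,
            "selected": [dataclasses.asdict(s) for s in sel.selected],
            "chosen": dataclasses.asdict(chosen[0]),
        }, outdir / f"selection_{which}.json")


def _chosen_spec(outdir: Path, which: str) -> CandidateSpec:
    d = json.loads((outdir / f"selection_{which}.json").read_text())["chosen"]
    return CandidateSpec(tuple(d["variables"]), d["reg_multiplier"], d["feature_class"])


def _load_models(outdir: Path, which: str) -> list[FittedModel]:
    payload = json.loads((outdir / f"final_models_{which}.json").read_text())
    return [FittedModel.from_dict(d) for d in payload["replicates"]]


def stage_finalize(config: RunConfig, outdir: Path,
                   periods: tuple[str, ...] | None = None) -> None:
    """Bootstrap-replicate final models and their median grids per period."""
    occ_all = _load_occurrences(config, outdir)
    for period in periods or (config.period_a, config.period_b):
        which = _suffix(config, period)
        scn = _load_scenario(config, outdir, which)
        background, _ = _read_background(outdir / f"background_{which}.csv")
        occ_env = extract_values(scn, occ_all[period])
        spec = _chosen_spec(outdir, which)
        models = final_models(spec, occ_env, background, config.n_reps,
                              seed=stage_seed(config.master_seed, f"finalize:{which}"))
        pio.save_json({"spec": dataclasses.asdict(spec),
                       "replicates": [m.to_dict() for m in models]},
                      outdir / f"final_models_{which}.json")
        median, _ = median_suitability(models, scn)
        pio.write_ascii_grid(outdir / f"median_{which}.asc", median.scores,
                             scn.transform, scn.mask)


def stage_transfer(config: RunConfig, outdir: Path) -> None:
    """Project the period-A replicate models onto period-B conditions."""
    scn_b = _load_scenario(config, outdir, "b")
    models = _load_models(outdir, "a")
    median, _ = median_suitability(models, scn_b)
    pio.write_ascii_grid(outdir / "median_a_on_b.asc", median.scores,
                         scn_b.transform, scn_b.mask)


def _read_suitability(outdir: Path, name: str):
    from .geographic import SuitabilityGrid
    values, mask, tfm = pio.read_ascii_grid(outdir / f"{name}.asc")
    values[~mask] = 0.0
    return SuitabilityGrid(values, mask, tfm, provenance={"file": f"{name}.asc"})


def stage_threshold(config: RunConfig, outdir: Path) -> None:
    """Binarise the three median grids at the bottom-percentile rule.

    The period-A occurrences threshold both the period-A grid and its
    transfer onto period B (the sites are geographic and persist); period-B
    occurrences threshold the period-B grid.
    """
    occ_all = _load_occurrences(config, outdir)
    jobs = (("median_a", "binary_a", config.period_a),
            ("median_a_on_b", "binary_a_on_b", config.period_a),
            ("median_b", "binary_b", config.period_b))
    thresholds = {}
    for src, dst, period in jobs:
        grid = _read_suitability(outdir, src)
        binary = threshold_binary(grid, occ_all[period], config.percentile)
        pio.write_ascii_grid(outdir / f"{dst}.asc", binary.values.astype(float),
                             binary.transform, binary.mask)
        thresholds[dst] = {"threshold": binary.threshold, "rule": binary.rule,
                           "occurrence_period": period}
    pio.save_json(thresholds, outdir / "thresholds.json")


def _read_binary(outdir: Path, name: str):
    from .geographic import BinaryMap
    values, mask, tfm = pio.read_ascii_grid(outdir / f"{name}.asc")
    values[~mask] = 0.0
    return BinaryMap(values.astype(np.uint8), mask, tfm, np.nan, name)


def stage_compare(config: RunConfig, outdir: Path) -> None:
    b_a = _read_binary(outdir, "binary_a")
    b_ab = _read_binary(outdir, "binary_a_on_b")
    b_b = _read_binary(outdir, "binary_b")
    counts = {}
    for name, m1, m2 in (("a_vs_a_on_b", b_a, b_ab), ("a_vs_b", b_a, b_b)):
        cmp = compare_binary(m1, m2)
        pio.write_ascii_grid(outdir / f"comparison_{name}.asc",
                             cmp.categories.astype(float), cmp.transform, cmp.mask)
        counts[name] = cmp.counts
    pio.save_json(counts, outdir / "comparison_counts.json")


def stage_overlap(config: RunConfig, outdir: Path) -> None:
    """PCA on the period-A background, projection of both periods, and the
    background-resampling overlap test with both ellipsoid methods."""
    occ_all = _load_occurrences(config, outdir)
    scn_a = _load_scenario(config, outdir, "a")
    scn_b = _load_scenario(config, outdir, "b")
    bg_a, _ = _read_background(outdir / "background_a.csv")
    bg_b, _ = _read_background(outdir / "background_b.csv")
    occ_env_a = extract_values(scn_a, occ_all[config.period_a])
    occ_env_b = extract_values(scn_b, occ_all[config.period_b])

    pca = fit_pca(bg_a, config.pca_components)
    pca.to_json(outdir / "pca.json")
    pc = {"occ_a": project(pca, occ_env_a), "occ_b": project(pca, occ_env_b),
          "bg_a": project(pca, bg_a), "bg_b": project(pca, bg_b)}
    for method in ("mve", "cvae"):
        result = overlap_significance(
            pc["occ_a"], pc["occ_b"], pc["bg_a"], pc["bg_b"], method=method,
            coverage=config.coverage, n_null=config.n_null, alpha=config.alpha,
            seed=stage_seed(config.master_seed, f"overlap:{method}"),
            mve_kwargs={"n_starts": config.mve_n_starts,
                        "n_candidates": config.mve_n_candidates})
        result.to_json(outdir / f"overlap_{method}.json")


def stage_mop(config: RunConfig, outdir: Path) -> None:
    scn_b = _load_scenario(config, outdir, "b")
    bg_a, _ = _read_background(outdir / "background_a.csv")
    grid = mop(bg_a, scn_b, config.mop_reference)
    pio.write_ascii_grid(outdir / "mop_similarity.asc", grid.similarity,
                         grid.transform, grid.mask)
    pio.write_ascii_grid(outdir / "mop_strict.asc",
                         grid.strict_extrapolation.astype(float),
                         grid.transform, grid.mask)
    n_valid = int(grid.mask.sum())
    n_strict = int(grid.strict_extrapolation[grid.mask].sum())
    pio.save_json({"reference_percent": config.mop_reference,
                   "n_valid_cells": n_valid, "n_strict_extrapolation": n_strict,
                   "strict_fraction": n_strict / n_valid}, outdir / "mop.json")


@dataclass
class RunReport:
    config: dict
    stage_seeds: dict[str, int]
    candidates_per_period: dict[str, int]
    selection: dict[str, dict]
    overlap: dict[str, dict]
    comparison_counts: dict[str, dict]
    mop: dict
    manifest: dict[str, str]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def stage_report(config: RunConfig, outdir: Path) -> RunReport:
    selection, candidates = {}, {}
    for which in ("a", "b"):
        sel = json.loads((outdir / f"selection_{which}.json").read_text())
        selection[which] = {k: sel[k] for k in
                            ("stage_counts", "selection_rule", "chosen", "period")}
        candidates[which] = sel["n_candidates"]
    overlap_summary = {}
    for method in ("mve", "cvae"):
        d = json.loads((outdir / f"overlap_{method}.json").read_text())
        overlap_summary[method] = {k: d[k] for k in
                                   ("observed_j", "p_value", "reject", "n_null",
                                    "null_quantile", "alpha")}
    report = RunReport(
        config=dataclasses.asdict(config),
        stage_seeds={s: stage_seed(config.master_seed, s) for s in STAGES},
        candidates_per_period=candidates,
        selection=selection,
        overlap=overlap_summary,
        comparison_counts=json.loads((outdir / "comparison_counts.json").read_text()),
        mop=json.loads((outdir / "mop.json").read_text()),
        manifest={p.relative_to(outdir).as_posix(): pio.sha256_file(p)
                  for p in sorted(outdir.rglob("*"))
                  if p.is_file() and p.name != "report.json"},
    )
    pio.save_json(report.to_dict(), outdir / "report.json")
    return report


_STAGE_FUNCS = {
    "simulate": stage_simulate, "background": stage_background,
    "calibrate": stage_calibrate, "finalize": stage_finalize,
    "transfer": stage_transfer, "threshold": stage_threshold,
    "compare": stage_compare, "overlap": stage_overlap, "mop": stage_mop,
}


def run_pipeline(config: RunConfig, outdir: str | Path) -> RunReport:
    """Execute all stages in order; any stage error aborts with its name."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    for stage in STAGES[:-1]:
        logger.info("running stage %s", stage)
        try:
            _STAGE_FUNCS[stage](config, outdir)
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError(stage, str(exc)) from exc
    return stage_report(config, outdir)
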
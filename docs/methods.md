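# Methods

This note documents the models, algorithms, defaults and known limitations
of `paleoniche`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The modelling problem

Given georeferenced presence records for two climatic periods and gridded
environmental variables for each period, the pipeline estimates each
period's existing fundamental niche (suitable conditions ∩ accessible area),
transfers the earlier period's model onto the later period's conditions,
and tests whether the two niches overlap less in environmental space than
availability alone would predict. Biotic interactions are assumed
non-limiting at this spatial scale (the Eltonian noise assumption), which
is what licenses transfer across scenarios.

## Suitability model

The density model is the exponential family over the finite background
sample: p(x) ∝ exp(λᵀ f(x)), normalised so the raw scores of the background
cells sum to 1. Feature maps follow the Maxent letter codes applied to
variables standardized by the background mean and sd — `l`: xᵢ, `q`: xᵢ²,
`p`: xᵢxⱼ (i<j) — and candidate models combine a variable subset (size ≥ 2),
a feature class from {q, qp, lp, lq, lqp} and a regularization multiplier
from {0.1…1.0 step 0.1, 2…6 step 1, 8, 10}. Weights maximise the presence
log-likelihood minus an L1 penalty of `multiplier / sqrt(n_train)` per
feature, solved exactly by L-BFGS-B on the positive/negative split of λ.
Suitability output is the raw score rescaled by the background maximum and
clipped to [0, 1]; transfer onto a second scenario reuses λ and the
normalizer without clamping the features (free extrapolation), so transfer
cells can saturate at 1.

With this penalty scaling, both the regularization and the sampling noise
of the presence feature means shrink as 1/√n, so at multiplier 1 a
no-signal fit (presences drawn from the background itself) retains small
residual weights (~0.1–0.2 on standardized features) rather than exactly
zero; by multiplier ≈ 3–4 such fits are flat. This matters when reading
small-multiplier candidates: their extra parameters are partly noise, which
is exactly what the AICc stage is there to penalise.

### Calibration and selection

Occurrences are split once 75/25 (seeded); all candidates share the split.
Three metrics are computed per candidate:

* **Partial ROC** — 500 bootstrap iterations resampling 50% of the test
  points; each iteration integrates the (proportion-of-area, sensitivity)
  curve over the region with sensitivity ≥ 1 − E and divides by the area
  under the diagonal on the same interval; `proc_p` is the fraction of
  ratios ≤ 1. Note a structural small-sample property: when
  ⌈0.5·n_test⌉ < 1/E the bootstrap sensitivity is quantized coarser than E,
  the kept region forces sensitivity = 1, and every ratio exceeds 1 —
  `proc_p` is then 0 regardless of model quality. This anticonservatism is
  inherent to the metric at archaeological sample sizes and is why the
  selection protocol does not stop at significance.
* **Omission rate** — fraction of test occurrences strictly below the
  E-percentile (default 5%) of training-occurrence scores.
* **AICc** — 2k − 2LL + 2k(k+1)/(n−k−1) with LL the log of normalised raw
  scores of a model refit to *all* occurrences and k the count of weights
  with |λ| > 1e−8. Candidates with n − k − 1 ≤ 0 are excluded with a
  logged reason.

Selection filters sequentially: proc_p < 0.05, omission < E, then
ΔAICc < 2 recomputed among the survivors. The pipeline (not the library
`select_models`, which reports an explicit empty selection with per-stage
counts) falls back when the strict filter is empty — first to significant
models under ΔAICc alone, then to the single best-AICc usable candidate —
and records which rule applied in the run report. Final models refit the
chosen parameterization on 10 bootstrap resamples of all occurrences; the
reported grid is the cell-wise median.

## Ellipsoid niches and the overlap test

Envelopes are fitted in the space of the first three principal components
of a PCA computed on the **calibration period's background sample** (the
fitting set is configurable; background fitting matches the reference
toolchain's behaviour). Scaling uses the population sd of the fitting set,
eigenvectors come from the correlation matrix, and each loading column's
largest-magnitude element is made positive so output is identical across
linear-algebra backends. The second period is *projected* with the stored
loadings, never re-fit; overlap code asserts that both clouds carry the
same transform object.

Two envelope estimators, both at coverage 1 − E = 0.95:

* **CVAE**: centroid = sample mean, shape = sample covariance (n−1),
  squared radius = χ²₀.₉₅ quantile with k degrees of freedom.
* **MVE**: the minimum-volume ellipsoid containing h = ⌈coverage·n⌉ points.
  The h-subset is found by a seeded, vectorised concentration search
  (random (k+1)-point elemental starts, Mahalanobis-rank concentration
  steps to a fixpoint, as in robust covariance estimation); the best
  subsets by covariance determinant are wrapped by their minimum-volume
  enclosing ellipsoid and the smallest wrap wins, ties broken by
  lexicographic subset order. When C(n, n−h) ≤ 64 every h-subset is wrapped
  exactly instead — the exact solver is affordable precisely at the sample
  sizes where the heuristic would be least reliable. The enclosing
  ellipsoid itself is computed by the Khachiyan dual ascent with
  Wolfe–Atwood away steps (numba-compiled, Sherman–Morrison updates,
  periodic re-sync, tolerance 1e−7); the plain barycentric update converges
  only as O(d/ε) and is unusable at that tolerance. The returned squared
  radius is the maximum quadratic form over the wrapped subset, so
  enclosure is exact regardless of tolerance. Boundary points count as
  inside (≤), which keeps coverage counts deterministic.

Overlap is J = |A ∩ B| / |A ∪ B| counted over the union of both periods'
background clouds (no deduplication). The null distribution fits 1000
pairs of ellipsoids to random background samples of the occurrence sample
sizes (without replacement within a replicate, independent across
replicates); degenerate replicates are resampled with a retry count, and a
warning is attached if more than 10% needed retries. The p-value is the
plain proportion of null J at or below the observed J (an optional
(r+1)/(n+1) correction is available), and the test is one-sided in the
low-overlap tail: rejection means the observed overlap is at or below the
empirical α-quantile of the null. The null-hypothesis phrasing "observed
ellipsoids overlap at least as much as background ellipsoids" is
operationalised by exactly this rejection rule.

Because the MVE discounts outlying occurrences it yields systematically
tighter envelopes, hence lower observed J, than the CVAE on the same data;
the two methods can disagree on significance, and the pipeline always
reports both.

## Geographic products

Median suitability grids are binarised at the percentile-5 threshold of
occurrence-cell scores (linear interpolation between order statistics;
a discrete order-statistic variant is available). Cells strictly below the
threshold become non-suitable, so occurrence cells sitting exactly at the
threshold remain suitable, and by construction the thresholding
occurrences' omission never exceeds 5% + 1/n. Pairs of aligned binary maps
yield stable-suitable / lost / gained / stable-unsuitable categories (codes
3/1/2/0) with counts that partition the valid cells; comparisons require
identical affine transforms and masks — no silent resampling. For the
transferred grid the period-A occurrences provide the threshold: sites are
geographic and persist across the transition, matching the territorial
reading of the record.

MOP similarity of a transfer cell is 1 − (mean Euclidean distance, in
calibration-standardized variable space, to the nearest
⌈reference_percent·m⌉ calibration points), normalised by the maximum such
distance over the transfer region; the default reference fraction is 0.1.
Strict extrapolation is flagged wherever any variable leaves the
calibration min–max range. Note that similarity reaches exactly 1 only
where the mean reference distance is 0, i.e. at duplicated conditions when
the reference fraction selects a single neighbour.

## Synthetic scenarios

The generator emulates downscaled climate-simulation outputs: per-variable
white noise smoothed by an isotropic Gaussian kernel (correlation length 3
cells by default), empirically re-standardized, mixed through an
eigenvalue-clipped factor of the requested correlation matrix, then scaled
and shifted to the requested moments. Defaults are an interglacial West
European state — coldest-month temperature 1 ± 4 °C, warmest-month 17 ± 3
°C, precipitation 800 ± 250 mm/yr, NPP 550 ± 180 gC/m²/yr, biomass
9000 ± 3500 g/m² with positive temperature–productivity correlations — on
a 100×100 lattice at 0.16°-like spacing with an ~85% accessible-area mask
carved from an independent smooth field. The glacial state subtracts
(8 °C, 5 °C, 300 mm, 250 gC/m², 4500 g/m²) and adds fresh smooth noise at
0.3 sd so the pair shares spatial structure without being deterministically
related. Physical constraints are enforced by construction: non-negative
variables truncate at 0 and t_warm clips to ≥ t_cold, so moment checks use
post-truncation targets.

Occurrences are sampled uniformly among distinct valid cells inside a known
ellipsoidal true niche (centroid at +0.3 sd of the variable means, diagonal
shape of (0.8 sd)², χ²₀.₉₅ radius) — uniform rather than density-weighted
sampling keeps the parameter-recovery target well defined. The default
sample size is 30 per period, the order of magnitude of per-interval
archaeological site counts. Two occupancy modes control the second period:
`territorial` (default) keeps the period-A in-niche cells as the period-B
site pool — populations hold their territories while conditions change
under them, which produces a genuine environmental niche shift — while
`niche_tracking` re-samples cells that are in-niche under period-B
conditions, emulating conservatism.

What the generator does **not** emulate: process-based climate or
vegetation dynamics, coastline change, spatial sampling bias in site
discovery, dating uncertainty in period attribution, and
suitability-weighted site placement. Passing tests therefore demonstrate
the correctness and statistical calibration of the machinery on fields with
realistic smoothness and correlation structure, not the faithfulness of
any particular paleoclimate reconstruction.

## Numerical choices and reproducibility

* Stage seeds derive from one master seed as `sha256(f"{seed}:{stage}")
  mod 2^31`, so any stage can be replayed in isolation and two runs with
  the same configuration are byte-identical (no timestamps are written;
  JSON keys are sorted; rasters are written at 12 significant digits,
  giving round-trip error below 1e−6 even for biomass-scale values).
* Partial ROC thresholds are the 201 evenly spaced quantiles of the grid
  scores; per-iteration curves integrate by the trapezoid rule.
* The concentration search runs 500 starts with at most 30 concentration
  steps and wraps the 10 best subsets by default; both knobs are exposed
  (`mve_n_starts`, `mve_n_candidates`) and the null resampling uses the
  same method and coverage as the observed fit.
* Degenerate geometry (collinear points, singular covariance, h < k+1)
  raises typed errors rather than producing silent results.
* Default problem sizes (100×100 lattice, 10,000-cell background cap,
  n_null = 1000, 500 pROC iterations) are the standard study conditions;
  the test suite exercises reduced lattices and replicate counts chosen to
  keep the full suite in the low minutes while preserving every contract.

## Known limitations

* The suitability surrogate implements l/q/p features only — no hinge or
  threshold features, no clamping semantics, and no feature-specific
  regularization tables; an adapter can ingest externally produced
  suitability rasters via the standard ASCII-grid reader if the original
  engine is required.
* The bootstrap partial-ROC p is anticonservative at small test sizes (see
  above); interpret stage-1 survivors accordingly.
* Ellipsoid fitting is done in PC space by default; raw-space ellipsoids
  are possible through the same API but untested against the pipeline.
* Areas are reported in cells, not km²; the synthetic lattice carries no
  equal-area projection.
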
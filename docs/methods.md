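# Methods

This note documents the models and procedures implemented in `hubdisrupt`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical decisions a user auditing the
pipeline would want to know.

## Pipeline overview

1. **Regional signals.**  Regional mean time series are extracted from a
   4-D functional image by averaging voxel values within each labelled
   parcel, weighted by the voxel's gray-matter probability (no hard GM
   cutoff: a zero-probability voxel simply contributes nothing).  Nuisance
   variance is removed by OLS regression on `[intercept | confounds |
   spike indicators]`, one indicator column per outlier-flagged volume.
   Spike regression is used instead of volume deletion so the sampling
   grid stays regular — the wavelet transform assumes uniformly sampled
   series.  A scan fails motion QC when more than 12 % of its volumes are
   flagged (the comparison is `fraction ≤ threshold` passes).
2. **Wavelet correlation.**  Each regional series is decomposed with the
   maximal overlap discrete wavelet transform (MODWT), an undecimated
   transform whose scale-j coefficients keep the original series length
   and cover the dyadic band `(f_N/2^j, f_N/2^(j−1))` with
   `f_N = 1/(2·TR)`.  The analysis scale is the smallest j whose whole
   band lies at or below 0.1 Hz — scale 4 for TR = 0.72 s
   (0.043–0.087 Hz), scale 3 for TR = 2.0 s (0.03125–0.0625 Hz; the exact
   dyadic values are reported rather than rounded variants).
   Inter-regional correlation at the chosen scale is the Pearson
   correlation of the detail coefficients after discarding the
   `L_j − 1 = (2^j − 1)(L − 1)` coefficients affected by the circular
   boundary (`L = 8` taps).
3. **Graph construction.**  The absolute correlation matrix is reduced to
   an unweighted, undirected, connected graph at a fixed *cost* (fraction
   of realized edges among the `N(N−1)/2` pairs): the maximum-|r| spanning
   tree (Prim) guarantees connectivity, then the strongest non-tree pairs
   are added until `M = round(cost · N(N−1)/2)` edges are reached.
   Intra-hemispheric analyses take the hemisphere's principal submatrix
   (44 nodes per side in the default template; midline structures such as
   the cerebellar vermis are excluded).
4. **Nodal metrics.**  Degree `D_i`; nodal global efficiency
   `Eg_i = (1/(N−1)) Σ_j 1/L_ij` (hop distances, `1/∞ = 0`); betweenness
   `B_i = Σ_{j<k} ρ_jk(i)/ρ_jk` over unordered pairs excluding the
   endpoints, unnormalized; local efficiency `El_i` = global efficiency of
   the subgraph induced by i's neighbours (distances computed inside the
   subgraph); clustering `C_i = 2t_i/(D_i(D_i−1))`.  `El` and `C` are
   defined as 0 for degree < 2.  Clustering and betweenness are nodal
   quantities throughout; node-averaged versions are produced separately
   by `global_summary`.
5. **κ.**  For a metric vector, κ is the OLS slope of
   `(subject − reference)` on `reference` with a free intercept.  The
   reference is the nodewise mean of the reference-group profiles; for
   bilateral analyses each subject contributes the mean of left and right
   homologous nodes.  κ is undefined (raises) for a constant reference.
6. **Reliability.**  ICC(1,1) under a one-way random-effects model:
   `ICC = (MSB − MSW) / (MSB + (k−1)·MSW)` with MSB/MSW the between- and
   within-subject *mean squares* (the raw-variance reading of the same
   formula would not reproduce the standard one-way estimator).  Negative
   values are returned as computed and should be read as "not reliable";
   an all-constant matrix returns 1 with a warning.
7. **Group comparison.**  Two-sided Wilcoxon rank-sum with tie-corrected
   normal-approximation z (exact enumeration when the combined sample is
   ≤ 12 without ties).  Nodal difference maps flag nodes at `p < 1/N`
   (0.023 for N = 44).  Stars: `*` < 0.05, `**` < 0.01, `***` < 0.001.

## Sequential permutation p-values

Permutation significance for the ICC reassigns the `n·k` observations to
subject slots (cell-level scheme; a column-wise scheme that permutes each
session column across subjects is available behind `scheme="columns"`) and
recomputes the ICC; `p = P(ICC_null ≥ ICC_obs)`.  Rather than a fixed
budget, a sequential procedure draws permutations in batches and stops as
soon as a confidence sequence for p excludes the decision threshold
(default α = 0.05): at the k-th check an `ε/(k(k+1))`-level
Clopper–Pearson interval is computed, so the total spent risk is bounded
by the resampling risk ε (default 10⁻³) — the probability that the
accept/reject decision differs from the infinite-permutation one.
Defaults: minimum 1 000 permutations before the first check, batches of
200, cap 100 000; hitting the cap returns the current `(b+1)/(n+1)`
estimate flagged unresolved.  A fixed-budget mode (`fixed_budget=B`,
`p = (b+1)/(B+1)`) serves as the reference implementation in tests.

## Synthetic cohorts

The generator emulates a two-group, two-session, two-hemisphere
resting-state study entirely from an explicit spatial model, so the ground
truth (which nodes are hubs, how strongly they were degraded) is known
exactly.

**Spatial model.**  Correlations follow a single-factor structure
`corr_ij = l_i·l_j`.  Hub nodes (fraction `hub_fraction` = 0.2, i.e. 9 of
44) load at `sqrt(hub_corr)` (default `hub_corr` = 0.6) and periphery
nodes at `sqrt(base_corr)` (default 0.2), each modulated by a
deterministic linear ramp of relative width `loading_spread` = 0.22 so
that degrees vary continuously instead of in flat blocks.  The factor
form is positive semi-definite by construction, so the nearest-PSD repair
that guards the constructors is a validated no-op rather than a
distortion; hub–periphery pairs sit at the geometric mean of the two
levels, the natural consequence of hubs being defined by a shared
connectivity factor.

**Subject trait.**  Each subject carries a hub-strength trait
`a_s ~ N(0, subject_sd)` (default 0.1) that scales their hub-loading
elevation identically in both hemispheres and both sessions.  Without
such stable individual differences the between-subject variance of κ
would be pure sampling noise and every reliability analysis would be
vacuous; with the default, control κ_D reaches ICC ≈ 0.6 ("good") at 512
timepoints.

**Disruption.**  Hub-targeted disruption replaces the subject's matrix by
the convex combination `(1 − γ)·C + γ·B` with the all-periphery model B
(hub loadings flattened to `sqrt(base_corr)`): only pairs involving a hub
move, PSD is preserved, γ = 0 is the identity and γ = 1 makes former hub
columns statistically indistinguishable from the base level.  Patients
receive the disruption in the hemisphere contralateral to their recorded
lesion side (default 11 left-lesioned, 9 right-lesioned of 20).

**Temporal model.**  Series are stationary Gaussian AR(1) processes
(lag-1 autocorrelation `temporal_ar1` = 0.3, innovations drawn from the
spatial covariance and scaled by `sqrt(1 − φ²)` so the stationary spatial
correlation equals the target exactly), plus white observation noise of
SD `noise_sd` = 0.2.  Default sizes — 20 + 20 subjects, 44 nodes per
hemisphere, 512 timepoints at TR = 2.0 s (selecting wavelet scale 3), two
sessions — mirror a realistic clinical arm while keeping a full-cohort
pipeline pass near a second of CPU time.

**What the generator does not emulate** — and hence what passing tests do
not certify about real fMRI: spatially autocorrelated parcels and
lesion geometry, physiological (cardiac/respiratory) noise and
motion artefacts, non-stationarity and non-Gaussianity of BOLD,
inter-hemispheric coupling (hemispheres are generated independently),
scanner/site effects, and eyes-open/closed state differences.  Results on
synthetic cohorts demonstrate the statistical machinery, not properties
of any clinical population.

## Reference designs, attenuation bias and calibration

κ regresses against an *estimated* reference, and this has consequences
that the package makes explicit:

* **In-group vs out-of-group.**  Members of the reference group evaluated
  against their own mean have κ that sums to exactly zero by construction.
  An out-of-group subject instead inherits a negative bias of roughly
  `−var(reference noise)/var(reference profile)` — small for degree, large
  for metrics whose nodal profile is nearly flat (local efficiency,
  clustering).  This is the operational face of the known limitation that
  κ ignores reference-group variance; it is also visible in the bootstrap
  robustness null (mean z ≈ −0.2 under the clinical design).
* **Clinical design.**  The default `pooled_kappa_table` follows the
  clinical convention: controls (in-group, left/right-averaged) vs
  patients (out-of-group, single contralesional hemisphere).  It is the
  right design for detecting disruption, where the effect dwarfs the
  bias, but it is *not* exchangeable under the null.
* **Calibration design.**  For null-calibration experiments the package
  provides `reference="everyone"` (the grand mean of all subjects' pooled
  left/right profiles — label-agnostic, hence exactly exchangeable when
  the groups come from one population) and `patient_profile =
  "left-right-mean"`.  Under this design the rank-sum comparison of κ
  rejects at the nominal rate (measured ≈ 5–8 % across metric × cost
  cells over 60 independent null cohorts, z ≈ N(0, 1)).  A leave-one-out
  option exists but is only approximately exchangeable: LOO references
  induce negative cross-correlation among in-group κs and positive
  correlation among out-of-group κs, which inflates the rank-sum test
  once trait variance dominates reference noise.

## Numerical choices

* Edge-count rounding: round-half-to-even on `cost·N(N−1)/2`.
* Tie-breaking (MST and thresholding): lexicographic on (min node index,
  max node index); this makes graphs deterministic and edge sets nested
  across costs.
* Realized threshold `R` = smallest included non-tree |r| (NaN when the
  graph is the bare tree).
* Wavelet filter: Daubechies least-asymmetric 8-tap (`sym8`),
  configurable; periodic (circular) filtering with boundary-coefficient
  exclusion; the MODWT uses DWT filters divided by √2, making the energy
  identity exact.
* PSD repair: eigenvalue clipping at 10⁻⁸ followed by rescaling to unit
  diagonal; constructors reject matrices the repair cannot fix.
* Degenerate inputs: constant reference profiles, zero-variance detail
  series, empty regions, rank-deficient nuisance designs, costs below the
  spanning-tree floor and oversized subgroup draws all raise informative
  errors rather than returning NaN.
* All stochastic procedures take explicit seeds; cohorts, bootstrap
  tables and pipeline runs are bit-reproducible from (spec, seed), and
  time-series TSVs round-trip floats exactly (`%.17g` out,
  `round_trip` parsing in).

## Problem sizes used by the test suite and acceptance script

Synthetic experiments run at the default study conditions (20 + 20
subjects, 44 nodes, 512 timepoints).  Detection power is assessed over 20
seeded replicates at γ = 0.6 and a γ-ladder {0, 0.25, 0.5, 0.75, 1};
null calibration over 60 independent γ = 0 cohorts (metrics D and Eg at
20 % and 30 % cost); bootstrap robustness over 1 000 resamplings of a
60-subject healthy cohort (20 reference vs 9 + 11 test hemispheres, as in
the clinical arm).  Graph-metric correctness is established exactly
against brute-force oracles on ≥ 100 random connected graphs with
N ≤ 12 rather than statistically.

## Known limitations

* κ treats the reference profile as noise-free (see attenuation bias
  above); no correction for reference-group variance is attempted.
* Only ICC(1,1) is implemented (no two-way variants, no F-based
  confidence intervals — significance is by permutation).
* Graphs are binary and undirected; negative correlations enter only
  through their absolute value.
* `select_scale` requires the full dyadic band below the ceiling; it will
  not pick a partially admissible band.
* The CLI covers the common paths; exotic designs (per-side bootstrap
  robustness, custom pooling) are library-level.
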
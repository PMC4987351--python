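"""Synthetic cohorts with known hub structure and hub-targeted disruption.

The generator builds regional BOLD-like time series from an explicit
spatial correlation matrix with a single-factor structure
``corr_ij = l_i * l_j``: a designated subset of nodes (the "hubs") carries
elevated factor loadings (``sqrt(hub_corr)``, so hub-hub pairs correlate at
``hub_corr``), the rest sit near ``sqrt(base_corr)``.  Loadings are graded
by a deterministic ramp so degrees vary continuously rather than in flat
blocks, and the factor form guarantees positive semi-definiteness without
any repair distorting the targets.  Hub-targeted disruption interpolates
the matrix toward the all-periphery model by a factor gamma in [0, 1]
(a convex combination of two valid correlation matrices, hence still PSD),
optionally raising peripheral correlations.  This reproduces the
qualitative signature a lesion leaves on the contralesional network:
former high-degree regions lose rank while peripheral regions gain.
Because the construction is explicit, the ground truth (which nodes are
hubs, how strongly they were degraded) is known exactly, so every pipeline
stage can be validated end to end.

Temporal structure is AR(1) with innovations drawn from the spatial
covariance, so the stationary spatial correlation equals the target;
white observation noise attenuates all correlations uniformly.

Default condition: 20 controls and 20 patients (11 left-lesioned, 9
right-lesioned), two sessions, two hemispheres of 44 nodes, 512 timepoints
at TR = 2.0 s (wavelet scale 3 is then selected automatically).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .regions import RegionDefinition
from .signals import TimeSeriesMatrix, write_timeseries_tsv, read_timeseries_tsv

MIN_TIMEPOINTS = 64  # wavelet scale-3 support with margin


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition parameters of a synthetic cohort."""

    n_controls: int = 20
    n_patients: int = 20
    n_patients_left_lesion: int = 11
    n_nodes: int = 44  # per hemisphere
    n_timepoints: int = 512
    tr: float = 2.0
    n_sessions: int = 2
    hub_fraction: float = 0.2
    base_corr: float = 0.2
    hub_corr: float = 0.6
    loading_spread: float = 0.22
    disruption_gamma: float = 0.6
    periphery_boost: float = 0.0
    subject_sd: float = 0.1
    noise_sd: float = 0.2
    temporal_ar1: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("hub_fraction", "disruption_gamma"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not -1 < self.temporal_ar1 < 1:
            raise ValueError("temporal_ar1 must lie in (-1, 1)")
        if self.n_patients_left_lesion > self.n_patients:
            raise ValueError("more left-lesioned patients than patients")

    @property
    def n_patients_right_lesion(self) -> int:
        return self.n_patients - self.n_patients_left_lesion

    @property
    def n_hubs(self) -> int:
        return int(round(self.hub_fraction * self.n_nodes))


def hub_indices(spec: CohortSpec) -> np.ndarray:
    """Designated hub nodes (a deterministic leading block)."""
    return np.arange(spec.n_hubs)


def nearest_psd_correlation(c: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Clip negative eigenvalues and rescale back to unit diagonal."""
    c = (c + c.T) / 2.0
    vals, vecs = np.linalg.eigh(c)
    if vals.min() >= -1e-10:
        return c
    vals = np.clip(vals, floor, None)
    repaired = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return (repaired + repaired.T) / 2.0


def factor_loadings(spec: CohortSpec, disrupted_to_base: bool = False
                    ) -> np.ndarray:
    """Per-node factor loadings: graded hubs plus graded periphery.

    Hub nodes load at ``sqrt(hub_corr)`` and periphery nodes at
    ``sqrt(base_corr)``, each modulated by a deterministic linear ramp of
    relative width ``loading_spread`` so correlations (and hence degrees)
    vary continuously within each class.  ``disrupted_to_base=True`` maps
    hub loadings to the periphery base level (the gamma = 1 endpoint).
    """
    n, k = spec.n_nodes, spec.n_hubs
    s = spec.loading_spread
    l = np.empty(n)
    if n > k:
        ramp_p = np.linspace(1 - s, 1 + s, n - k)
        l[k:] = np.sqrt(spec.base_corr) * ramp_p
    if k:
        if disrupted_to_base:
            l[:k] = np.sqrt(spec.base_corr)
        else:
            ramp_h = np.linspace(1 - s, 1 + s, k)
            l[:k] = np.sqrt(spec.hub_corr) * ramp_h
    return np.clip(l, 0.02, 0.97)


def _factor_correlation(l: np.ndarray) -> np.ndarray:
    c = np.outer(l, l)
    np.fill_diagonal(c, 1.0)
    return c


def make_hub_covariance(spec: CohortSpec) -> np.ndarray:
    """Unit-diagonal correlation with elevated, graded hub loadings.

    Hub-hub pairs correlate near ``hub_corr``, periphery pairs near
    ``base_corr`` and hub-periphery pairs at the geometric mean — the
    single-factor structure keeps the matrix PSD by construction, so the
    nearest-PSD repair is a validated no-op rather than a distortion.
    """
    c = nearest_psd_correlation(_factor_correlation(factor_loadings(spec)))
    if np.linalg.eigvalsh(c).min() < -1e-8:
        raise ValueError("correlation targets infeasible: repair failed")
    return c


def base_covariance(spec: CohortSpec) -> np.ndarray:
    """The all-periphery model: hub loadings flattened to the base level."""
    return _factor_correlation(factor_loadings(spec, disrupted_to_base=True))


def apply_hub_disruption(
    cov: np.ndarray,
    spec: CohortSpec,
    gamma: Optional[float] = None,
    periphery_boost: Optional[float] = None,
) -> np.ndarray:
    """Attenuate hub correlations toward the base level by factor (1-gamma).

    The disrupted matrix is the convex combination
    ``(1 - gamma) * cov + gamma * base`` with the all-periphery base model,
    which only moves pairs involving a hub (periphery pairs agree between
    the two endpoints) and stays PSD.  ``gamma=0`` is the identity;
    ``gamma=1`` makes hub columns statistically indistinguishable from the
    base level.  ``periphery_boost`` (added to non-hub pairs) emulates
    peripheral overconnection; the nearest-correlation repair then restores
    PSD if needed.
    """
    gamma = spec.disruption_gamma if gamma is None else gamma
    boost = spec.periphery_boost if periphery_boost is None else periphery_boost
    if not 0 <= gamma <= 1:
        raise ValueError("gamma must lie in [0, 1]")
    c = np.array(cov, dtype=float, copy=True)
    base = base_covariance(spec)
    c = (1 - gamma) * c + gamma * base
    if boost:
        n = c.shape[0]
        is_hub = np.zeros(n, dtype=bool)
        is_hub[hub_indices(spec)] = True
        periph_pair = ~(is_hub[:, None] | is_hub[None, :])
        c[periph_pair] = np.clip(c[periph_pair] + boost, -0.99, 0.99)
    np.fill_diagonal(c, 1.0)
    return nearest_psd_correlation(c)


def simulate_subject(
    cov: np.ndarray,
    n_timepoints: int,
    tr: float,
    ar1: float = 0.0,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    regions: Optional[Sequence[RegionDefinition]] = None,
    subject_id: str = "",
    session_id: str = "",
    rng: Optional[np.random.Generator] = None,
) -> TimeSeriesMatrix:
    """Zero-mean Gaussian series with given spatial covariance and AR(1).

    The AR(1) recursion uses innovations scaled by sqrt(1 - ar1^2), so the
    stationary spatial covariance equals ``cov`` exactly; white observation
    noise of SD ``noise_sd`` is added afterwards.
    """
    if n_timepoints < MIN_TIMEPOINTS:
        raise ValueError(
            f"n_timepoints must be >= {MIN_TIMEPOINTS} for wavelet support"
        )
    rng = rng if rng is not None else np.random.default_rng(seed)
    cov = np.asarray(cov, dtype=float)
    n = cov.shape[0]
    chol = np.linalg.cholesky(cov + 1e-10 * np.eye(n))
    innov = chol @ rng.standard_normal((n, n_timepoints))
    x = np.empty((n, n_timepoints))
    x[:, 0] = innov[:, 0]
    scale = np.sqrt(1 - ar1**2)
    for t in range(1, n_timepoints):
        x[:, t] = ar1 * x[:, t - 1] + scale * innov[:, t]
    if noise_sd:
        x += noise_sd * rng.standard_normal(x.shape)
    if regions is None:
        regions = [
            RegionDefinition(i + 1, f"node_{i + 1:02d}", "midline")
            for i in range(n)
        ]
    return TimeSeriesMatrix(x, tr, list(regions), subject_id, session_id)


def _hemi_regions(n_nodes: int, side: str) -> list[RegionDefinition]:
    offset = 0 if side == "left" else n_nodes
    other = n_nodes if side == "left" else 0
    return [
        RegionDefinition(offset + i + 1, f"{side[0].upper()}_{i + 1:02d}",
                         side, homologue_id=other + i + 1)
        for i in range(n_nodes)
    ]


@dataclass
class SyntheticCohort:
    """Simulated controls and patients with ground-truth manifest.

    ``timeseries`` maps (subject_id, session, hemisphere) to a
    :class:`TimeSeriesMatrix`.  The manifest records the spec, hub node
    indices, disruption strength and each patient's lesioned side.
    """

    spec: CohortSpec
    timeseries: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    @property
    def control_ids(self) -> list[str]:
        return self.manifest["controls"]

    @property
    def patient_ids(self) -> list[str]:
        return list(self.manifest["lesion_side"].keys())

    def contralesional_side(self, patient_id: str) -> str:
        lesion = self.manifest["lesion_side"][patient_id]
        return "right" if lesion == "left" else "left"

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = dict(self.manifest, spec=asdict(self.spec))
        (directory / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True)
        )
        for (sid, sess, hemi), ts in self.timeseries.items():
            write_timeseries_tsv(
                ts, directory / f"{sid}_ses-{sess}_{hemi}.tsv"
            )

    @classmethod
    def load(cls, directory) -> "SyntheticCohort":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        spec = CohortSpec(**manifest.pop("spec"))
        cohort = cls(spec, manifest=manifest)
        sides = {"left", "right"}
        for path in sorted(directory.glob("*_ses-*_*.tsv")):
            stem = path.stem
            sid, sess_part, hemi = stem.rsplit("_", 2)
            if hemi not in sides:
                continue
            sess = int(sess_part.replace("ses-", ""))
            regions = _hemi_regions(spec.n_nodes, hemi)
            ts = read_timeseries_tsv(path, spec.tr, regions,
                                     subject_id=sid, session_id=str(sess))
            cohort.timeseries[(sid, sess, hemi)] = ts
        return cohort


def _subject_loadings(spec: CohortSpec, trait: float,
                      gamma: float) -> np.ndarray:
    """Loadings for one subject: trait-scaled hub elevation, then disruption.

    ``trait`` multiplies the subject's hub elevation (a stable individual
    hub-strength difference, identical across sessions and hemispheres, so
    test-retest analyses have genuine between-subject variance to detect);
    ``gamma`` then attenuates the elevation toward the base level.
    """
    l_intact = factor_loadings(spec)
    l_base = factor_loadings(spec, disrupted_to_base=True)
    l = l_base + (1 - gamma) * (1 + trait) * (l_intact - l_base)
    return np.clip(l, 0.02, 0.97)


def simulate_cohort(spec: CohortSpec = CohortSpec()) -> SyntheticCohort:
    """Simulate controls (intact) and patients (contralesional disruption).

    Each subject carries a hub-strength trait drawn with SD ``subject_sd``;
    controls use their trait-modulated intact model in both hemispheres,
    while each patient's contralesional hemisphere is additionally
    disrupted by ``disruption_gamma``.  All sessions share the subject's
    correlation structure and differ only by the random draw, so
    within-subject (session) variability is pure sampling noise.
    """
    rng = np.random.default_rng(spec.seed)
    cohort = SyntheticCohort(spec)
    controls = [f"ctrl{c:03d}" for c in range(spec.n_controls)]
    patients = [f"pat{p:03d}" for p in range(spec.n_patients)]
    lesion_side = {
        pid: ("left" if p < spec.n_patients_left_lesion else "right")
        for p, pid in enumerate(patients)
    }
    traits = {
        sid: float(rng.normal(0.0, spec.subject_sd))
        for sid in controls + patients
    }

    def draw(sid, sess, hemi, gamma):
        cov = _factor_correlation(_subject_loadings(spec, traits[sid], gamma))
        regions = _hemi_regions(spec.n_nodes, hemi)
        cohort.timeseries[(sid, sess, hemi)] = simulate_subject(
            cov, spec.n_timepoints, spec.tr, spec.temporal_ar1,
            spec.noise_sd, regions=regions, subject_id=sid,
            session_id=str(sess), rng=rng,
        )

    for sid in controls:
        for sess in range(1, spec.n_sessions + 1):
            for hemi in ("left", "right"):
                draw(sid, sess, hemi, gamma=0.0)
    for pid in patients:
        contra = "right" if lesion_side[pid] == "left" else "left"
        for sess in range(1, spec.n_sessions + 1):
            for hemi in ("left", "right"):
                gamma = spec.disruption_gamma if hemi == contra else 0.0
                draw(pid, sess, hemi, gamma)

    cohort.manifest = {
        "controls": controls,
        "lesion_side": lesion_side,
        "hub_indices": hub_indices(spec).tolist(),
        "disruption_gamma": spec.disruption_gamma,
        "subject_traits": traits,
        "seed": spec.seed,
    }
    return cohort


def make_profile_with_slope(
    ref,
    a: float,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Profile with known hub-disruption slope: ref + a*ref + noise.

    Feeding the result to the kappa fit recovers ``a`` exactly when
    ``noise_sd`` is zero, and unbiasedly otherwise.
    """
    values = ref.values if hasattr(ref, "values") else np.asarray(ref, float)
    if np.ptp(values) == 0:
        raise ValueError("reference profile must not be constant")
    rng = rng if rng is not None else np.random.default_rng(seed)
    eps = rng.normal(0.0, noise_sd, size=values.shape) if noise_sd else 0.0
    return values + a * values + eps
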
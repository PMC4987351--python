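"""Regional time-series extraction, nuisance regression and motion QC.

Regional series are formed by gray-matter-probability-weighted averaging of
voxel time courses within each labelled parcel; the weighting suppresses
contamination from white matter and CSF without imposing a hard tissue
threshold.  Motion-related variance is removed by least-squares regression
of nuisance regressors plus one indicator (spike) column per flagged
volume — spike regression rather than volume deletion keeps the sampling
grid regular, which the wavelet transform downstream requires.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .regions import RegionDefinition, validate_regions

#: Subjects with more than this fraction of flagged volumes fail QC.
DEFAULT_QC_THRESHOLD = 0.12


@dataclass
class TimeSeriesMatrix:
    """Regions x timepoints signal block with acquisition metadata."""

    data: np.ndarray  # (n_regions, n_timepoints)
    tr: float
    regions: Sequence[RegionDefinition]
    subject_id: str = ""
    session_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (regions x timepoints)")
        if len(self.regions) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.regions)} regions declared but data has "
                f"{self.data.shape[0]} rows"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series contain non-finite values")
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    @property
    def region_ids(self) -> list[int]:
        return [r.region_id for r in self.regions]


@dataclass(frozen=True)
class QCReport:
    """Motion quality-control outcome for one scan."""

    n_volumes: int
    n_outliers: int
    fraction_rejected: float
    passed: bool
    threshold: float = DEFAULT_QC_THRESHOLD

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


def _as_array(img) -> np.ndarray:
    """Accept a numpy array or anything with get_fdata (a nibabel image)."""
    if hasattr(img, "get_fdata"):
        return np.asarray(img.get_fdata())
    return np.asarray(img)


def extract_regional_series(
    fmri,
    labels,
    gm_prob,
    regions: Sequence[RegionDefinition],
    tr: float,
    subject_id: str = "",
    session_id: str = "",
) -> TimeSeriesMatrix:
    """GM-probability-weighted regional mean time series.

    For region ``r`` at time ``t`` the value is
    ``sum_v w_v x_v(t) / sum_v w_v`` over voxels ``v`` with label ``r``,
    where ``w_v`` is the gray-matter probability of voxel ``v``.

    Parameters
    ----------
    fmri
        4-D array or NIfTI image (x, y, z, t).
    labels
        3-D integer label image on the same grid.
    gm_prob
        3-D gray-matter probability image on the same grid, values in [0, 1].
    regions
        Declared parcellation; every region must contain at least one voxel
        with positive weight.
    """
    validate_regions(regions)
    fmri = _as_array(fmri)
    labels = np.rint(_as_array(labels)).astype(int)
    gm = _as_array(gm_prob).astype(float)
    if fmri.ndim != 4:
        raise ValueError("fmri must be 4-D")
    if labels.shape != fmri.shape[:3] or gm.shape != fmri.shape[:3]:
        raise ValueError(
            f"grid mismatch: fmri {fmri.shape[:3]}, labels {labels.shape}, "
            f"gm {gm.shape}"
        )
    if gm.min() < 0 or gm.max() > 1:
        raise ValueError("gm_prob values must lie in [0, 1]")

    n_t = fmri.shape[3]
    out = np.empty((len(regions), n_t))
    flat_fmri = fmri.reshape(-1, n_t)
    flat_labels = labels.ravel()
    flat_gm = gm.ravel()
    for i, region in enumerate(regions):
        mask = flat_labels == region.region_id
        w = flat_gm[mask]
        total = w.sum()
        if total <= 0:
            raise ValueError(
                f"region {region.region_id} ({region.name}) has zero total "
                "GM weight"
            )
        out[i] = w @ flat_fmri[mask] / total
    return TimeSeriesMatrix(out, tr, list(regions), subject_id, session_id)


def _spike_columns(flags: np.ndarray) -> np.ndarray:
    """One indicator column per flagged timepoint."""
    idx = np.flatnonzero(flags)
    cols = np.zeros((flags.size, idx.size))
    cols[idx, np.arange(idx.size)] = 1.0
    return cols


def regress_nuisance(
    ts: TimeSeriesMatrix,
    confounds: Optional[np.ndarray] = None,
    outlier_flags: Optional[np.ndarray] = None,
) -> TimeSeriesMatrix:
    """Replace each regional series by its residual against the nuisance design.

    The design is ``[intercept | confounds | spike indicators]``.  Residuals
    are orthogonal to every design column.  A rank-deficient design raises,
    naming the collinear columns.
    """
    n_t = ts.n_timepoints
    cols = [np.ones((n_t, 1))]
    names = ["intercept"]
    if confounds is not None:
        confounds = np.atleast_2d(np.asarray(confounds, dtype=float))
        if confounds.shape[0] != n_t:
            if confounds.shape[1] == n_t:
                confounds = confounds.T
            else:
                raise ValueError(
                    f"confounds have {confounds.shape[0]} rows, expected {n_t}"
                )
        cols.append(confounds)
        names += [f"confound_{j}" for j in range(confounds.shape[1])]
    if outlier_flags is not None:
        flags = np.asarray(outlier_flags, dtype=bool)
        if flags.size != n_t:
            raise ValueError("outlier_flags length must match timepoints")
        spikes = _spike_columns(flags)
        if spikes.shape[1]:
            cols.append(spikes)
            names += [f"spike_t{t}" for t in np.flatnonzero(flags)]
    design = np.hstack(cols)

    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify offending columns by greedy QR-style elimination
        bad = []
        kept: list[int] = []
        for j in range(design.shape[1]):
            trial = design[:, kept + [j]]
            if np.linalg.matrix_rank(trial) == len(kept) + 1:
                kept.append(j)
            else:
                bad.append(names[j])
        raise ValueError(f"rank-deficient nuisance design; collinear: {bad}")

    beta, *_ = np.linalg.lstsq(design, ts.data.T, rcond=None)
    resid = ts.data.T - design @ beta
    return replace(ts, data=resid.T)


def motion_qc(
    n_volumes: int,
    outlier_flags,
    threshold: float = DEFAULT_QC_THRESHOLD,
) -> QCReport:
    """Pass/fail motion check: more than ``threshold`` rejected volumes fails.

    ``outlier_flags`` may be a boolean vector or an integer outlier count.
    """
    if n_volumes < 1:
        raise ValueError("n_volumes must be >= 1")
    if np.isscalar(outlier_flags):
        n_out = int(outlier_flags)
    else:
        n_out = int(np.count_nonzero(np.asarray(outlier_flags, dtype=bool)))
    frac = n_out / n_volumes
    return QCReport(n_volumes, n_out, frac, passed=frac <= threshold,
                    threshold=threshold)


# ---------------------------------------------------------------------------
# TSV round-trip: first column region_id, one column per timepoint.

def write_timeseries_tsv(ts: TimeSeriesMatrix, path) -> None:
    df = pd.DataFrame(ts.data, copy=True)
    df.columns = [f"t{j:05d}" for j in range(ts.n_timepoints)]
    df.insert(0, "region_id", ts.region_ids)
    # %.17g guarantees bit-exact float round-trips through text
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_timeseries_tsv(
    path,
    tr: float,
    regions: Optional[Sequence[RegionDefinition]] = None,
    subject_id: str = "",
    session_id: str = "",
) -> TimeSeriesMatrix:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    ids = df["region_id"].astype(int).tolist()
    data = df.drop(columns="region_id").to_numpy(dtype=float)
    if regions is None:
        regions = [RegionDefinition(i, f"region_{i}", "midline") for i in ids]
    else:
        by_id = {r.region_id: r for r in regions}
        missing = [i for i in ids if i not in by_id]
        if missing:
            raise ValueError(f"region ids {missing} not in the parcellation")
        regions = [by_id[i] for i in ids]
    return TimeSeriesMatrix(data, tr, regions, subject_id, session_id)
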
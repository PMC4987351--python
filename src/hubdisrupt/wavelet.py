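"""MODWT decomposition and scale-specific inter-regional correlation.

The maximal overlap discrete wavelet transform (MODWT) is an undecimated
wavelet decomposition: every scale yields a coefficient series of the
original length, so correlations can be estimated scale by scale on equally
many samples.  Scale ``j`` captures the dyadic frequency band
``(f_N / 2^j, f_N / 2^(j-1))`` where ``f_N = 1/(2 TR)`` is the Nyquist
frequency of the acquisition.  For resting-state fMRI the band of interest
sits below 0.1 Hz, which selects scale 4 at TR = 0.72 s and scale 3 at
TR = 2.0 s.

The transform uses the pyramid algorithm with circular (periodic) filtering
and MODWT-rescaled filters (the DWT filters divided by sqrt(2)), so the
energy identity ``||x||^2 = sum_j ||W_j||^2 + ||V_J||^2`` holds exactly.
Coefficients affected by the circular wrap-around (the first ``L_j - 1``
of each scale, with ``L_j = (2^j - 1)(L - 1) + 1``) are excluded from
correlation estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pywt

from .regions import RegionDefinition
from .signals import TimeSeriesMatrix

DEFAULT_FILTER = "sym8"  # Daubechies least-asymmetric 8-tap (LA8)
DEFAULT_F_CEILING = 0.1  # Hz; resting-state band of interest


@dataclass(frozen=True)
class WaveletSpec:
    """Provenance of one wavelet scale: TR, scale index and frequency band."""

    tr: float
    scale: int
    band: tuple[float, float]
    filter_name: str = DEFAULT_FILTER
    boundary_rule: str = "periodic-exclude"

    def __post_init__(self) -> None:
        low, high = self.band
        if not low < high:
            raise ValueError("band must satisfy f_low < f_high")


@dataclass
class CorrelationMatrix:
    """Symmetric inter-regional correlation matrix with provenance."""

    values: np.ndarray
    regions: Sequence[RegionDefinition]
    spec: Optional[WaveletSpec] = None
    subject_id: str = ""
    session_id: str = ""
    hemisphere_scope: str = "all"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("correlation matrix must be square")
        if v.shape[0] != len(self.regions):
            raise ValueError("region list does not match matrix size")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if np.nanmax(np.abs(v)) > 1 + 1e-8:
            raise ValueError("correlation entries must lie in [-1, 1]")
        v = np.clip((v + v.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(v, 1.0)
        self.values = v

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def region_ids(self) -> list[int]:
        return [r.region_id for r in self.regions]


def nyquist_frequency(tr: float) -> float:
    """Maximum resolvable frequency 1/(2 TR) in Hz."""
    if tr <= 0:
        raise ValueError("tr must be positive")
    return 1.0 / (2.0 * tr)


def scale_band(tr: float, scale: int) -> tuple[float, float]:
    """Dyadic frequency band (f_low, f_high) of wavelet scale ``scale``."""
    if scale < 1:
        raise ValueError("scale must be >= 1")
    f_n = nyquist_frequency(tr)
    return f_n / 2.0**scale, f_n / 2.0 ** (scale - 1)


def select_scale(
    tr: float,
    f_ceiling: float = DEFAULT_F_CEILING,
    n_timepoints: Optional[int] = None,
    filter_name: str = DEFAULT_FILTER,
) -> int:
    """Smallest scale whose entire band lies at or below ``f_ceiling``.

    If ``n_timepoints`` is given, the selected scale must still have at
    least two non-boundary MODWT coefficients; otherwise an error is raised
    rather than guessing a coarser or finer band.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    j = 1
    while scale_band(tr, j)[1] > f_ceiling:
        j += 1
    if n_timepoints is not None:
        l_j = _boundary_width(j, filter_name) + 1
        if n_timepoints - (l_j - 1) < 2:
            raise ValueError(
                f"scale {j} needs more than {l_j} timepoints, got {n_timepoints}"
            )
    return j


def _modwt_filters(filter_name: str) -> tuple[np.ndarray, np.ndarray]:
    w = pywt.Wavelet(filter_name)
    g = np.asarray(w.dec_lo) / np.sqrt(2.0)
    h = np.asarray(w.dec_hi) / np.sqrt(2.0)
    return g, h


def _boundary_width(scale: int, filter_name: str = DEFAULT_FILTER) -> int:
    """Number of wrap-around-affected coefficients L_j - 1 at ``scale``."""
    length = pywt.Wavelet(filter_name).dec_len
    l_j = (2**scale - 1) * (length - 1) + 1
    return l_j - 1


@dataclass
class ModwtResult:
    """Per-scale detail coefficients plus the final smooth."""

    details: list[np.ndarray]  # each (..., n_timepoints)
    smooth: np.ndarray
    filter_name: str
    boundary_counts: list[int] = field(default_factory=list)


def modwt_details(
    series: np.ndarray,
    max_scale: int,
    filter_name: str = DEFAULT_FILTER,
    boundary_rule: str = "periodic",
) -> ModwtResult:
    """MODWT pyramid to ``max_scale`` levels with circular filtering.

    ``series`` may be a single series or a (regions x timepoints) matrix;
    filtering is applied along the last axis.  The transform is linear and,
    with the rescaled filters used here, exactly energy preserving.
    """
    if boundary_rule != "periodic":
        raise ValueError("only periodic boundary handling is implemented")
    x = np.asarray(series, dtype=float)
    n = x.shape[-1]
    g, h = _modwt_filters(filter_name)
    length = g.size
    details: list[np.ndarray] = []
    counts: list[int] = []
    v = x
    for j in range(1, max_scale + 1):
        step = 2 ** (j - 1)
        l_j = (2**j - 1) * (length - 1) + 1
        if l_j > n:
            raise ValueError(
                f"series of length {n} too short for scale {j}: needs at "
                f"least {l_j} timepoints; use fewer scales"
            )
        w_j = np.zeros_like(v)
        v_j = np.zeros_like(v)
        for l in range(length):
            shifted = np.roll(v, step * l, axis=-1)
            w_j += h[l] * shifted
            v_j += g[l] * shifted
        details.append(w_j)
        counts.append(l_j - 1)
        v = v_j
    return ModwtResult(details, v, filter_name, counts)


def wavelet_correlation_matrix(
    ts: TimeSeriesMatrix,
    scale: Optional[int] = None,
    filter_name: str = DEFAULT_FILTER,
    f_ceiling: float = DEFAULT_F_CEILING,
) -> CorrelationMatrix:
    """Pearson correlation of scale-``scale`` MODWT detail coefficients.

    ``scale=None`` selects the scale automatically from the TR.  Boundary
    coefficients are excluded before correlating.  A region whose detail
    sequence has zero variance raises an error naming the region.
    """
    if scale is None:
        scale = select_scale(ts.tr, f_ceiling, ts.n_timepoints, filter_name)
    res = modwt_details(ts.data, scale, filter_name)
    coeffs = res.details[scale - 1][:, res.boundary_counts[scale - 1]:]
    if coeffs.shape[1] < 2:
        raise ValueError(
            f"only {coeffs.shape[1]} non-boundary coefficients at scale "
            f"{scale}; series too short"
        )
    sd = coeffs.std(axis=1)
    if np.any(sd == 0):
        bad = [ts.regions[i].name for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance detail coefficients for regions {bad}")
    corr = np.corrcoef(coeffs)
    spec = WaveletSpec(ts.tr, scale, scale_band(ts.tr, scale), filter_name)
    return CorrelationMatrix(
        corr, list(ts.regions), spec, ts.subject_id, ts.session_id
    )
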
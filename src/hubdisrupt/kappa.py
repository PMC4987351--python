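"""The hub disruption index (kappa).

For a chosen nodal metric, kappa of a subject is the slope of the ordinary
least-squares regression of the nodewise difference (subject - reference)
on the reference group's mean nodal value.  A subject whose topology
matches the reference scatters around a horizontal line (kappa ~ 0);
a subject whose high-value nodes (hubs) lost value while peripheral nodes
gained scatters around a negative slope (kappa < 0).  The index condenses a
whole nodal reorganization pattern into a single number per subject, which
makes it amenable to standard group statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import NodalMetricProfile


@dataclass
class ReferenceProfile:
    """Nodewise mean metric values of a reference (control) group."""

    values: np.ndarray
    metric: str
    node_ids: list[int]
    n_reference: int
    pooling: str = "single-hemisphere"  # or "left-right-mean"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.n_reference < 1:
            raise ValueError("reference group must contain at least 1 profile")


@dataclass(frozen=True)
class KappaResult:
    """Fitted hub disruption index for one subject."""

    kappa: float
    intercept: float
    r_squared: float
    metric: str
    subject_id: str = ""
    session_id: str = ""


def _metric_values(p, metric: str) -> np.ndarray:
    if isinstance(p, NodalMetricProfile):
        return p.get(metric)
    return np.asarray(p, dtype=float)


def reference_profile(
    profiles: Sequence,
    metric: str,
    pooling: str = "single-hemisphere",
    profiles_right: Optional[Sequence] = None,
) -> ReferenceProfile:
    """Nodewise mean over reference subjects.

    With ``pooling="left-right-mean"`` each subject contributes the mean of
    their left and right homologous nodal values (``profiles`` holds the
    left-hemisphere profiles, ``profiles_right`` the right, in homologous
    node order); the reference is then the across-subject mean.
    """
    if len(profiles) < 1:
        raise ValueError("need at least one profile")
    arrays = [_metric_values(p, metric) for p in profiles]
    node_ids = (
        list(profiles[0].node_ids)
        if isinstance(profiles[0], NodalMetricProfile)
        else list(range(arrays[0].size))
    )
    for p in profiles[1:]:
        if isinstance(p, NodalMetricProfile) and list(p.node_ids) != node_ids:
            raise ValueError("profiles have mismatching node order")
    stack = np.vstack(arrays)
    if pooling == "left-right-mean":
        if profiles_right is None:
            raise ValueError("left-right-mean pooling requires profiles_right")
        right = np.vstack([_metric_values(p, metric) for p in profiles_right])
        if right.shape != stack.shape:
            raise ValueError("left and right profile stacks differ in shape")
        stack = (stack + right) / 2.0
    elif pooling != "single-hemisphere":
        raise ValueError(f"unknown pooling {pooling!r}")
    return ReferenceProfile(stack.mean(axis=0), metric, node_ids,
                            n_reference=stack.shape[0], pooling=pooling)


def kappa(
    subject,
    ref: ReferenceProfile,
    metric: Optional[str] = None,
    subject_id: str = "",
    session_id: str = "",
) -> KappaResult:
    """OLS slope of (subject - reference) on reference, with intercept."""
    metric = metric or ref.metric
    y_subj = _metric_values(subject, metric)
    x = ref.values
    if y_subj.shape != x.shape:
        raise ValueError("subject and reference profiles differ in length")
    if np.ptp(x) == 0:
        raise ValueError("reference profile is constant; slope undefined")
    diff = y_subj - x
    fit = stats.linregress(x, diff)
    if isinstance(subject, NodalMetricProfile):
        subject_id = subject_id or str(subject.provenance.get("subject_id", ""))
        session_id = session_id or str(subject.provenance.get("session_id", ""))
    return KappaResult(
        kappa=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        metric=metric,
        subject_id=subject_id,
        session_id=session_id,
    )


def cohort_kappa(
    profiles: Iterable,
    ref: ReferenceProfile,
    metric: Optional[str] = None,
    ids: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Long-format kappa table, one row per subject profile."""
    rows = []
    for k, p in enumerate(profiles):
        sid = ids[k] if ids is not None else ""
        res = kappa(p, ref, metric, subject_id=sid)
        rows.append(
            {
                "subject_id": res.subject_id or str(k),
                "session_id": res.session_id,
                "metric": res.metric,
                "kappa": res.kappa,
                "intercept": res.intercept,
                "r2": res.r_squared,
            }
        )
    return pd.DataFrame(rows)
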
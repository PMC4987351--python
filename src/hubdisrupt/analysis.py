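"""High-level cohort analysis: time series -> profiles -> kappa -> tests.

These helpers tie the pipeline stages together for a whole cohort
(synthetic or loaded from disk): wavelet correlation per hemisphere,
cost-thresholded graphs, nodal metric profiles, kappa against a control
reference, and the standard group comparisons.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .comparison import ComparisonTable, compare_kappa_across_costs
from .graphs import threshold_to_cost
from .kappa import ReferenceProfile, kappa as kappa_fit
from .metrics import METRIC_NAMES, compute_metric
from .synthetic import SyntheticCohort
from .wavelet import wavelet_correlation_matrix


def cohort_profiles(
    cohort: SyntheticCohort,
    costs: Sequence[float],
    scale: Optional[int] = None,
    sessions: Optional[Sequence[int]] = None,
    metrics: Sequence[str] = METRIC_NAMES,
) -> pd.DataFrame:
    """Nodal metric profiles for every subject/session/hemisphere/cost.

    Returns a long DataFrame with columns subject, group, session,
    hemisphere, cost, metric, node_index, value.  The wavelet scale is
    selected from the TR when not given; each hemisphere's correlation
    matrix is computed once and reused across costs.
    """
    records = []
    controls = set(cohort.control_ids)
    for (sid, sess, hemi), ts in cohort.timeseries.items():
        if sessions is not None and sess not in sessions:
            continue
        corr = wavelet_correlation_matrix(ts, scale)
        for cost in costs:
            graph = threshold_to_cost(corr, cost)
            group = "control" if sid in controls else "patient"
            for metric in metrics:
                vals = compute_metric(graph, metric)
                for node, v in enumerate(vals):
                    records.append(
                        (sid, group, sess, hemi, cost, metric, node, v)
                    )
    return pd.DataFrame(
        records,
        columns=["subject", "group", "session", "hemisphere", "cost",
                 "metric", "node_index", "value"],
    )


def _nodal_array(df: pd.DataFrame, subjects: Sequence[str]) -> np.ndarray:
    """(n_subjects x n_nodes) array in the given subject order."""
    wide = df.pivot_table(index="subject", columns="node_index",
                          values="value", sort=False)
    return wide.loc[list(subjects)].to_numpy()


def pooled_kappa_table(
    profiles: pd.DataFrame,
    cohort: SyntheticCohort,
    metrics: Sequence[str] = METRIC_NAMES,
    costs: Optional[Sequence[float]] = None,
    session: int = 1,
    patient_profile: str = "contralesional",
    leave_one_out: bool = False,
    reference: str = "controls",
) -> pd.DataFrame:
    """Kappa of every subject against the pooled control reference.

    The reference is the control-group mean of each control's left/right
    averaged profile.  Controls contribute their own left/right average;
    patients contribute their contralesional hemisphere (the clinical
    design).  ``patient_profile="left-right-mean"`` makes patients
    contribute their left/right average instead, so both groups receive
    identical treatment — the exchangeable design null-calibration tests
    require (noisier single-hemisphere profiles suffer more attenuation of
    nonlinear metrics like clustering, which would bias an asymmetric
    comparison even without disruption).  Long format: subject, group,
    metric, cost, kappa.

    ``leave_one_out=True`` evaluates each control against the mean of the
    *other* controls (and each patient against a size-matched reference
    with one control dropped cyclically).  With the plain group mean (the
    clinical convention), in-group kappas average exactly zero by
    construction while out-of-group subjects inherit a small negative
    attenuation bias from reference-group noise; leave-one-out puts both
    groups on the out-of-group footing.

    ``reference="everyone"`` builds the reference from the pooled profiles
    of *all* subjects, controls and patients alike.  Because that
    reference is blind to group labels, the comparison is exactly
    exchangeable when the groups are drawn from one population — the
    design null-calibration experiments need.
    """
    if patient_profile not in ("contralesional", "left-right-mean"):
        raise ValueError(f"unknown patient_profile {patient_profile!r}")
    if reference not in ("controls", "everyone"):
        raise ValueError(f"unknown reference {reference!r}")
    if costs is None:
        costs = sorted(profiles["cost"].unique())
    controls = cohort.control_ids
    patients = cohort.patient_ids
    sess_df = profiles[profiles["session"] == session]
    rows = []
    for metric in metrics:
        mdf = sess_df[sess_df["metric"] == metric]
        for cost in costs:
            cdf = mdf[mdf["cost"] == cost]
            left = _nodal_array(
                cdf[cdf["hemisphere"] == "left"], controls + patients
            )
            right = _nodal_array(
                cdf[cdf["hemisphere"] == "right"], controls + patients
            )
            n_ctrl = len(controls)
            ctrl_pooled = (left[:n_ctrl] + right[:n_ctrl]) / 2.0
            if reference == "everyone":
                ref_stack = (left + right) / 2.0
            else:
                ref_stack = ctrl_pooled
            n_ref = ref_stack.shape[0]
            n_nodes = ref_stack.shape[1]

            def _ref(drop=None):
                if drop is None:
                    vals = ref_stack.mean(axis=0)
                    n = n_ref
                else:
                    vals = (ref_stack.sum(axis=0) - ref_stack[drop]) \
                        / (n_ref - 1)
                    n = n_ref - 1
                return ReferenceProfile(vals, metric, list(range(n_nodes)),
                                        n_reference=n,
                                        pooling="left-right-mean")

            ref = _ref()
            for i, sid in enumerate(controls):
                ref_i = _ref(drop=i) if leave_one_out else ref
                rows.append((sid, "control", metric, cost,
                             kappa_fit(ctrl_pooled[i], ref_i).kappa))
            for j, pid in enumerate(patients):
                if patient_profile == "left-right-mean":
                    vals = (left[n_ctrl + j] + right[n_ctrl + j]) / 2.0
                else:
                    side = cohort.contralesional_side(pid)
                    arr = left if side == "left" else right
                    vals = arr[n_ctrl + j]
                if leave_one_out:
                    # drop own row when part of the reference, else one
                    # reference row cyclically (equal reference noise)
                    drop = n_ctrl + j if reference == "everyone" \
                        else j % n_ctrl
                    ref_j = _ref(drop=drop)
                else:
                    ref_j = ref
                rows.append((pid, "patient", metric, cost,
                             kappa_fit(vals, ref_j).kappa))
    return pd.DataFrame(
        rows, columns=["subject", "group", "metric", "cost", "kappa"]
    )


def pooled_group_comparison(
    kappa_table: pd.DataFrame,
    metrics: Sequence[str] = METRIC_NAMES,
    costs: Optional[Sequence[float]] = None,
) -> ComparisonTable:
    """Patients-vs-controls rank-sum comparison per metric per cost."""
    if costs is None:
        costs = sorted(kappa_table["cost"].unique())
    ctrl = kappa_table[kappa_table["group"] == "control"]
    pat = kappa_table[kappa_table["group"] == "patient"]
    return compare_kappa_across_costs(ctrl, pat, metrics, costs)


def nodal_arrays_by_group(
    profiles: pd.DataFrame,
    cohort: SyntheticCohort,
    metric: str,
    cost: float,
    hemisphere: str,
    session: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """(controls, patients) nodal arrays for one hemisphere/metric/cost.

    Patients are restricted to those whose contralesional side matches
    ``hemisphere``.
    """
    sel = profiles[
        (profiles["session"] == session)
        & (profiles["metric"] == metric)
        & (profiles["cost"] == cost)
        & (profiles["hemisphere"] == hemisphere)
    ]
    pats = [p for p in cohort.patient_ids
            if cohort.contralesional_side(p) == hemisphere]
    ctrl = _nodal_array(sel, cohort.control_ids)
    pat = _nodal_array(sel, pats)
    return ctrl, pat


def session_nodal_tensor(
    profiles: pd.DataFrame,
    subjects: Sequence[str],
    metric: str,
    cost: float,
    hemisphere: str,
    sessions: Sequence[int] = (1, 2),
) -> np.ndarray:
    """(n_subjects, n_sessions, n_nodes) tensor for reliability analyses."""
    per_session = []
    for sess in sessions:
        sel = profiles[
            (profiles["session"] == sess)
            & (profiles["metric"] == metric)
            & (profiles["cost"] == cost)
            & (profiles["hemisphere"] == hemisphere)
        ]
        per_session.append(_nodal_array(sel, subjects))
    return np.stack(per_session, axis=1)
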
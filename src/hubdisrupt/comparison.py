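"""Group comparison of kappa and metrics; nodal maps; bootstrap robustness.

Group differences use the two-sided Wilcoxon rank-sum test (exact
enumeration for small samples, tie-corrected normal approximation
otherwise).  Nodal difference maps apply the 1/N false-positive correction:
with N regions per hemisphere a node is flagged only when p < 1/N.
Robustness of small-sample group differences is checked by bootstrap:
healthy subjects are repeatedly cast as pseudo-reference and pseudo-patient
groups, the kappa group-comparison z recomputed each time, and the observed
z located within that null distribution by lower-tail counting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .kappa import ReferenceProfile, kappa as kappa_fit

#: significance stars as used in the comparison figures
STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    for level, stars in STAR_LEVELS:
        if p < level:
            return stars
    return ""


def wilcoxon_rank_sum(x, y, exact_max_n: int = 12) -> tuple[float, float]:
    """Two-sided rank-sum test returning (z, p).

    z is the tie-corrected normal-approximation statistic (positive when x
    tends to exceed y).  For combined sample sizes up to ``exact_max_n``
    with no ties the p-value comes from exact enumeration.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    combined = np.concatenate([x, y])
    if np.ptp(combined) == 0:
        return 0.0, 1.0
    n1, n2 = x.size, y.size
    ranks = stats.rankdata(combined)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    # tie-corrected variance of U
    _, counts = np.unique(combined, return_counts=True)
    n = n1 + n2
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    z = 0.0 if sigma2 == 0 else (u1 - mu) / np.sqrt(sigma2)
    has_ties = np.any(counts > 1)
    if n <= exact_max_n and not has_ties:
        p = float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                     method="exact").pvalue)
    else:
        p = float(2 * stats.norm.sf(abs(z)))
    return float(z), min(p, 1.0)


@dataclass
class ComparisonTable:
    """Wilcoxon comparisons per metric per cost."""

    table: pd.DataFrame

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["p"] < alpha]


def compare_kappa_across_costs(
    controls: pd.DataFrame,
    patients: pd.DataFrame,
    metrics: Sequence[str],
    costs: Sequence[float],
    value_col: str = "kappa",
) -> ComparisonTable:
    """One rank-sum comparison (patients vs controls) per metric per cost.

    Both inputs are long tables with columns ``metric``, ``cost`` and
    ``value_col``.  z > 0 means patients tend higher than controls.
    """
    rows = []
    for metric in metrics:
        for cost in costs:
            xc = controls.query("metric == @metric and cost == @cost")[value_col]
            xp = patients.query("metric == @metric and cost == @cost")[value_col]
            if xc.empty or xp.empty:
                raise ValueError(
                    f"missing values for metric={metric} cost={cost}"
                )
            z, p = wilcoxon_rank_sum(xp.to_numpy(), xc.to_numpy())
            rows.append(
                {
                    "metric": metric,
                    "cost": cost,
                    "n_controls": xc.size,
                    "n_patients": xp.size,
                    "z": z,
                    "p": p,
                    "stars": significance_stars(p),
                }
            )
    return ComparisonTable(pd.DataFrame(rows))


@dataclass
class NodalDifferenceMap:
    """Per-node group difference with the 1/N false-positive correction."""

    node_ids: list[int]
    mean_diff: np.ndarray  # patients - controls
    p: np.ndarray
    threshold: float
    metric: str = ""

    @property
    def significant(self) -> np.ndarray:
        return self.p < self.threshold

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node_id": self.node_ids,
                "mean_diff": self.mean_diff,
                "p": self.p,
                "significant": self.significant,
            }
        )


def nodal_group_difference(
    control_values: np.ndarray,
    patient_values: np.ndarray,
    node_ids: Optional[Sequence[int]] = None,
    metric: str = "",
) -> NodalDifferenceMap:
    """Nodewise Wilcoxon comparison with significance at p < 1/N.

    Inputs are (n_subjects x n_nodes) arrays of nodal metric values.
    """
    ctrl = np.atleast_2d(np.asarray(control_values, dtype=float))
    pat = np.atleast_2d(np.asarray(patient_values, dtype=float))
    if ctrl.shape[1] != pat.shape[1]:
        raise ValueError("groups have different node counts")
    n_nodes = ctrl.shape[1]
    diff = pat.mean(axis=0) - ctrl.mean(axis=0)
    pvals = np.empty(n_nodes)
    for i in range(n_nodes):
        _, pvals[i] = wilcoxon_rank_sum(pat[:, i], ctrl[:, i])
    ids = list(node_ids) if node_ids is not None else list(range(n_nodes))
    return NodalDifferenceMap(ids, diff, pvals, threshold=1.0 / n_nodes,
                              metric=metric)


@dataclass
class RobustnessResult:
    """Bootstrap null distribution of group-comparison z-values."""

    null_z: np.ndarray
    observed_z: Optional[float]
    p_raw: Optional[float]
    p_plus_one: Optional[float]
    n_iter: int
    seed: Optional[int]
    design: str


def _kappa_values(arrays: np.ndarray, ref: ReferenceProfile) -> np.ndarray:
    return np.array([kappa_fit(a, ref).kappa for a in arrays])


def bootstrap_robustness(
    left: np.ndarray,
    right: np.ndarray,
    n_iter: int = 1000,
    design: str = "pooled",
    side: Optional[str] = None,
    n_ref: int = 20,
    n_test_left: int = 9,
    n_test_right: int = 11,
    observed_z: Optional[float] = None,
    seed: Optional[int] = None,
) -> RobustnessResult:
    """Null distribution of kappa group-comparison z under healthy resampling.

    ``left``/``right`` are (n_subjects x n_nodes) nodal metric arrays for a
    healthy cohort (homologous node order).  Per iteration, disjoint
    reference and test groups are drawn without replacement.

    design="pooled": the reference is the group mean of each reference
    subject's left/right average; the test group pools ``n_test_left`` left
    and ``n_test_right`` right hemispheres (mirroring a patient group with
    lesions on both sides).  design="per-side" with ``side``: the reference
    is built from that hemisphere only and the test group has
    ``n_test_left`` (side="left") or ``n_test_right`` (side="right")
    members.

    p (if ``observed_z`` is given) is the lower-tail raw count
    ``mean(null_z <= observed_z)``; the (b+1)/(n+1) convention is reported
    alongside.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape:
        raise ValueError("left and right arrays must have the same shape")
    n_subjects = left.shape[0]
    if design == "pooled":
        n_test = n_test_left + n_test_right
    elif design == "per-side":
        if side not in ("left", "right"):
            raise ValueError("per-side design requires side='left'|'right'")
        n_test = n_test_left if side == "left" else n_test_right
    else:
        raise ValueError(f"unknown design {design!r}")
    if n_ref + n_test > n_subjects:
        raise ValueError(
            f"cohort of {n_subjects} too small for {n_ref} reference + "
            f"{n_test} test subjects"
        )
    rng = np.random.default_rng(seed)
    null_z = np.empty(n_iter)
    for it in range(n_iter):
        picks = rng.choice(n_subjects, size=n_ref + n_test, replace=False)
        ref_idx, test_idx = picks[:n_ref], picks[n_ref:]
        if design == "pooled":
            ref_arrays = (left[ref_idx] + right[ref_idx]) / 2.0
            test_arrays = np.vstack(
                [left[test_idx[:n_test_left]], right[test_idx[n_test_left:]]]
            )
        else:
            hemi = left if side == "left" else right
            ref_arrays = hemi[ref_idx]
            test_arrays = hemi[test_idx]
        ref = ReferenceProfile(
            ref_arrays.mean(axis=0), "metric",
            list(range(ref_arrays.shape[1])), n_reference=n_ref,
        )
        k_ref = _kappa_values(ref_arrays, ref)
        k_test = _kappa_values(test_arrays, ref)
        null_z[it], _ = wilcoxon_rank_sum(k_test, k_ref)
    p_raw = p_plus = None
    if observed_z is not None:
        b = int(np.sum(null_z <= observed_z))
        p_raw = b / n_iter
        p_plus = (b + 1) / (n_iter + 1)
    return RobustnessResult(null_z, observed_z, p_raw, p_plus, n_iter, seed,
                            design if side is None else f"{design}:{side}")
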
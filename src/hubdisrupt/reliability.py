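"""Test-retest reliability: one-way ICC, permutation p-values, bootstrap.

The intraclass correlation coefficient under a one-way random-effects model,
ICC(1,1), compares between-subject to within-subject (session) variability:

    ICC = (MSB - MSW) / (MSB + (k - 1) MSW)

where MSB and MSW are the between- and within-subject mean squares of the
one-way ANOVA decomposition and k is the number of sessions per subject.
Values near 1 indicate high reliability; negative values can occur when
within-subject variance exceeds between-subject variance and should be read
as "not reliable".

Significance is assessed by permutation: observations are reassigned across
subjects, destroying subject identity, and the ICC recomputed.  The
sequential Monte-Carlo procedure stops as soon as a confidence sequence for
the permutation p-value excludes the decision threshold, bounding the
resampling risk (the probability of deciding differently from the ideal
infinite-permutation p-value) by a user-set constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ICCResult:
    """One-way ICC with its variance components."""

    icc: float
    s_b: float  # between-subject mean square (MSB)
    s_w: float  # within-subject mean square (MSW)
    k: int
    n: int
    p_value: Optional[float] = None
    n_permutations_used: int = 0
    p_resolved: bool = True


def icc_one_way(values: np.ndarray) -> ICCResult:
    """ICC(1,1) from a subjects x sessions matrix with no missing cells."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 2:
        raise ValueError("values must be a 2-D subjects x sessions matrix")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 sessions")
    if not np.all(np.isfinite(x)):
        raise ValueError("missing or non-finite cells are not allowed")
    grand = x.mean()
    subj_means = x.mean(axis=1)
    ssb = k * np.sum((subj_means - grand) ** 2)
    ssw = np.sum((x - subj_means[:, None]) ** 2)
    msb = ssb / (n - 1)
    msw = ssw / (n * (k - 1))
    if msb == 0 and msw == 0:
        warnings.warn("all values identical; ICC defined as 1", stacklevel=2)
        return ICCResult(1.0, 0.0, 0.0, k, n)
    icc = (msb - msw) / (msb + (k - 1) * msw)
    return ICCResult(float(icc), float(msb), float(msw), k, n)


def _permute_matrix(x: np.ndarray, rng: np.random.Generator,
                    scheme: str) -> np.ndarray:
    n, k = x.shape
    if scheme == "cells":
        # reassign all n*k observations to subject slots
        flat = rng.permutation(x.ravel())
        return flat.reshape(n, k)
    if scheme == "columns":
        # shuffle each session column across subjects independently
        out = np.empty_like(x)
        for j in range(k):
            out[:, j] = x[rng.permutation(n), j]
        return out
    raise ValueError(f"unknown permutation scheme {scheme!r}")


@dataclass
class PermutationPValue:
    p: float
    steps_used: int
    resolved: bool


def permutation_pvalue(
    values: np.ndarray,
    resampling_risk: float = 1e-3,
    max_steps: int = 100_000,
    seed: Optional[int] = None,
    alpha: float = 0.05,
    min_steps: int = 1_000,
    batch: int = 200,
    fixed_budget: Optional[int] = None,
    scheme: str = "cells",
) -> PermutationPValue:
    """One-sided permutation p for ICC: P(ICC_null >= ICC_obs).

    With ``fixed_budget=B`` a plain Monte-Carlo estimate ``(b + 1)/(B + 1)``
    is returned (the reference oracle).  Otherwise a sequential procedure
    draws permutations until an alpha-spent Clopper-Pearson confidence
    sequence for p lies entirely on one side of ``alpha`` (decision
    certain up to ``resampling_risk``), or ``max_steps`` is exhausted, in
    which case the current estimate is returned flagged unresolved.
    """
    x = np.asarray(values, dtype=float)
    obs = icc_one_way(x).icc
    rng = np.random.default_rng(seed)

    if fixed_budget is not None:
        exceed = sum(
            icc_one_way(_permute_matrix(x, rng, scheme)).icc >= obs
            for _ in range(fixed_budget)
        )
        return PermutationPValue((exceed + 1) / (fixed_budget + 1),
                                 fixed_budget, True)

    exceed = 0
    n_done = 0
    check = 0
    while n_done < max_steps:
        m = min(batch, max_steps - n_done)
        for _ in range(m):
            if icc_one_way(_permute_matrix(x, rng, scheme)).icc >= obs:
                exceed += 1
        n_done += m
        if n_done < min_steps:
            continue
        check += 1
        # alpha-spending over checks: sum_k eps/(k(k+1)) = eps
        eps_k = resampling_risk / (check * (check + 1))
        lo = stats.beta.ppf(eps_k / 2, exceed, n_done - exceed + 1) \
            if exceed > 0 else 0.0
        hi = stats.beta.ppf(1 - eps_k / 2, exceed + 1, n_done - exceed) \
            if exceed < n_done else 1.0
        if hi < alpha or lo > alpha:
            return PermutationPValue((exceed + 1) / (n_done + 1), n_done, True)
    return PermutationPValue((exceed + 1) / (n_done + 1), n_done, False)


def icc_with_pvalue(values: np.ndarray, **kwargs) -> ICCResult:
    """Convenience: ICC(1,1) plus its sequential permutation p-value."""
    res = icc_one_way(values)
    perm = permutation_pvalue(values, **kwargs)
    res.p_value = perm.p
    res.n_permutations_used = perm.steps_used
    res.p_resolved = perm.resolved
    return res


def _subgroup_kappa_matrix(nodal: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """kappa per subject per session, reference = subgroup per-session mean.

    ``nodal``: (n_subjects, n_sessions, n_nodes) metric values.
    Returns a (len(idx), n_sessions) kappa matrix.
    """
    from .kappa import ReferenceProfile, kappa as kappa_fit

    sub = nodal[idx]
    n_s, n_sess, _ = sub.shape
    out = np.empty((n_s, n_sess))
    for s in range(n_sess):
        ref_vals = sub[:, s, :].mean(axis=0)
        ref = ReferenceProfile(ref_vals, "metric",
                               list(range(ref_vals.size)), n_reference=n_s)
        for i in range(n_s):
            out[i, s] = kappa_fit(sub[i, s, :], ref).kappa
    return out


def bootstrap_subgroup_reliability(
    nodal_by_cost: dict,
    sizes,
    n_boot: int = 100,
    seed: Optional[int] = None,
    with_pvalues: bool = False,
    **perm_kwargs,
) -> pd.DataFrame:
    """ICC of kappa for bootstrap subgroups of several sizes, per cost.

    ``nodal_by_cost`` maps cost -> (n_subjects, n_sessions, n_nodes) nodal
    metric arrays.  For each draw a subgroup is sampled without replacement,
    kappa recomputed per subject/session against that subgroup's per-session
    mean, and the ICC across sessions taken.  When the requested size equals
    the full cohort the single deterministic ICC is reported.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for cost, nodal in nodal_by_cost.items():
        nodal = np.asarray(nodal, dtype=float)
        n_subjects = nodal.shape[0]
        for size in sizes:
            if size > n_subjects:
                raise ValueError(
                    f"subgroup size {size} exceeds cohort size {n_subjects}"
                )
            draws = 1 if size == n_subjects else n_boot
            for d in range(draws):
                idx = (
                    np.arange(n_subjects)
                    if size == n_subjects
                    else rng.choice(n_subjects, size=size, replace=False)
                )
                km = _subgroup_kappa_matrix(nodal, idx)
                res = icc_one_way(km)
                row = {
                    "cost": cost,
                    "size": size,
                    "draw": d,
                    "icc": res.icc,
                    "s_b": res.s_b,
                    "s_w": res.s_w,
                }
                if with_pvalues:
                    perm = permutation_pvalue(
                        km, seed=int(rng.integers(2**31)), **perm_kwargs
                    )
                    row["p"] = perm.p
                    row["p_resolved"] = perm.resolved
                rows.append(row)
    return pd.DataFrame(rows)


def hemispheric_symmetry_test(
    left: np.ndarray,
    right: np.ndarray,
    paired: bool = True,
) -> tuple[float, float]:
    """Wilcoxon test of left vs right kappa (or metric) values.

    Paired data use the signed-rank test (identical samples give p = 1);
    unpaired data use the rank-sum test.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if paired:
        if left.shape != right.shape:
            raise ValueError("paired test needs equal-length samples")
        d = left - right
        if np.all(d == 0):
            return 0.0, 1.0
        res = stats.wilcoxon(left, right)
        return float(res.statistic), float(res.pvalue)
    from .comparison import wilcoxon_rank_sum

    return wilcoxon_rank_sum(left, right)
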
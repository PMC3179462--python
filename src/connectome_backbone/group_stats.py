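"""Group comparisons: permutation tests, hemispheric symmetry, and
backbone-level metric contrasts between cohort groups.

Because a backbone metric (e.g. the global efficiency of a group's
network) has exactly one value per group, the resampling unit is the
subject: every permutation relabels scans between the two groups,
rebuilds each group's backbone at the stated cost, and recomputes the
metric difference.  The two-sided p-value is the literal proportion of
permutations whose absolute difference reaches the observed one (no +1
correction); p = 0 is reported with a warning since it only means "rarer
than 1/n_perm".
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import RegionAtlas
from .backbone import compute_snr, length_summary, threshold_to_cost
from .cohort import FiberCountCohort
from .metrics import global_efficiency, local_efficiency


def _mean_diff(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.mean(a) - np.mean(b))


@dataclass
class PermutationResult:
    observed: float
    p_two_sided: float
    n_perm: int
    exhaustive: bool
    seed: int | None


def permutation_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    n_perm: int = 1000,
    seed: int = 0,
    statistic: Callable[[np.ndarray, np.ndarray], float] = _mean_diff,
    exhaustive: bool = False,
) -> PermutationResult:
    """Two-sample permutation test on pooled relabelings.

    The statistic defaults to the difference of group means.  With
    ``exhaustive=True`` every distinct split of the pooled sample into
    the original group sizes is enumerated (the identity split included),
    giving the exact permutation p-value; otherwise ``n_perm`` random
    relabelings are sampled.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed = statistic(a, b)
    pooled = np.concatenate([a, b])
    n_a = a.size

    if exhaustive:
        hits = 0
        total = 0
        idx_all = frozenset(range(pooled.size))
        for comb in itertools.combinations(range(pooled.size), n_a):
            rest = sorted(idx_all - set(comb))
            d = statistic(pooled[list(comb)], pooled[rest])
            hits += abs(d) >= abs(observed) - 1e-12
            total += 1
        p = hits / total
        return PermutationResult(observed, p, total, True, None)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled.size)
        d = statistic(pooled[perm[:n_a]], pooled[perm[n_a:]])
        hits += abs(d) >= abs(observed) - 1e-12
    p = hits / n_perm
    if p == 0:
        warnings.warn(
            "permutation p = 0: the observed difference exceeded all "
            f"{n_perm} sampled permutations (p < 1/{n_perm})",
            stacklevel=2,
        )
    return PermutationResult(observed, p, n_perm, False, seed)


@dataclass
class SymmetryFit:
    """OLS of right-hemisphere on left-hemisphere node values.

    A slope of 1 with r = 1 is perfect hemispheric symmetry; slope < 1
    indicates values concentrated in the left partner (and vice versa).
    """

    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    stderr_slope: float
    n_pairs: int
    left: np.ndarray
    right: np.ndarray

    def ci_band(self, x: np.ndarray, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
        """Normal-theory confidence band for the mean regression line."""
        x = np.asarray(x, dtype=float)
        n = self.n_pairs
        resid = self.right - (self.slope * self.left + self.intercept)
        s = np.sqrt((resid @ resid) / (n - 2))
        xbar = self.left.mean()
        sxx = ((self.left - xbar) ** 2).sum()
        se = s * np.sqrt(1 / n + (x - xbar) ** 2 / sxx)
        t = stats.t.ppf(0.5 + level / 2, n - 2)
        yhat = self.slope * x + self.intercept
        return yhat - t * se, yhat + t * se


def hemisphere_symmetry(values: Sequence[float], atlas: RegionAtlas) -> SymmetryFit:
    """Regress right-hemisphere node values on their left partners.

    Nodes are paired by label stem (``PreCG-L`` with ``PreCG-R``); an
    unpaired node is an error listing the offending labels.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (atlas.n_regions,):
        raise ValueError("one value per atlas region required")
    pairs = atlas.hemisphere_pairs()
    left = np.array([values[i] for i, _ in pairs])
    right = np.array([values[j] for _, j in pairs])
    if np.ptp(left) == 0:  # zero-variance regressor: slope undefined
        return SymmetryFit(
            slope=np.nan, intercept=np.nan, pearson_r=np.nan, p_value=np.nan,
            stderr_slope=np.nan, n_pairs=len(pairs), left=left, right=right,
        )
    res = stats.linregress(left, right)
    return SymmetryFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        p_value=float(res.pvalue),
        stderr_slope=float(res.stderr),
        n_pairs=len(pairs),
        left=left,
        right=right,
    )


_METRICS = ("global_efficiency", "local_efficiency", "mean_fiber_length")


def _metric_of_scans(
    cohort: FiberCountCohort, idx: np.ndarray, metric: str, cost: float
) -> float:
    snr = compute_snr(cohort, scan_indices=idx)
    g = threshold_to_cost(snr, cost)
    if metric == "global_efficiency":
        return global_efficiency(g)
    if metric == "local_efficiency":
        return local_efficiency(g)[0]
    if metric == "mean_fiber_length":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return length_summary(cohort, g, scan_indices=idx).mean_mm
    raise ValueError(f"unknown metric {metric!r}; choose from {_METRICS}")


@dataclass
class GroupComparison:
    metric: str
    cost: float
    group_values: pd.Series
    p_values: pd.DataFrame
    n_perm: int
    seed: int


def compare_groups(
    cohort: FiberCountCohort,
    grouping: str = "age_group",
    metric: str = "local_efficiency",
    cost: float = 0.21,
    n_perm: int = 1000,
    seed: int = 0,
) -> GroupComparison:
    """Per-group backbone metric with all pairwise permutation p-values.

    For each group a backbone is built at ``cost`` from that group's
    scans and the metric evaluated on it; each pairwise test permutes
    scans between the two groups and rebuilds both backbones per
    relabeling (the subject is the resampling unit).  Groups with a
    single scan are rejected (SNR needs >= 2 subjects).
    """
    groups = cohort.groups(grouping)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups to compare")
    idx_of = {g: cohort.scan_indices(grouping, g) for g in groups}
    for g, idx in idx_of.items():
        if idx.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 scans")

    values = pd.Series(
        {g: _metric_of_scans(cohort, idx_of[g], metric, cost) for g in groups},
        name=metric,
    )
    pmat = pd.DataFrame(np.nan, index=groups, columns=groups)
    rng = np.random.default_rng(seed)
    for ga, gb in itertools.combinations(groups, 2):
        ia, ib = idx_of[ga], idx_of[gb]
        observed = values[ga] - values[gb]
        pooled = np.concatenate([ia, ib])
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            d = _metric_of_scans(cohort, perm[: ia.size], metric, cost) - \
                _metric_of_scans(cohort, perm[ia.size:], metric, cost)
            hits += abs(d) >= abs(observed) - 1e-12
        pmat.loc[ga, gb] = pmat.loc[gb, ga] = hits / n_perm
    return GroupComparison(
        metric=metric,
        cost=cost,
        group_values=values,
        p_values=pmat,
        n_perm=n_perm,
        seed=seed,
    )
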
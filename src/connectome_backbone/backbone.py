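"""Consistency backbone construction.

A connection is "consistent" when its fiber count is stable across the
subjects of a group.  Per region pair we compute the reciprocal of the
coefficient of variation of the fiber count — mean/SD across subjects,
called the connectivity SNR — and keep the top pairs by SNR until the
network reaches a target cost (fraction of the N(N-1)/2 possible edges).
The statistic is scale-invariant (SNR(c*x) = SNR(x) for c > 0), so it does
not depend on how many fibers tractography reconstructs overall.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cohort import FiberCountCohort
from .graph import BackboneGraph, largest_component_size


@dataclass
class SNRMatrix:
    """Per-pair count mean, sample SD (n-1 denominator) and SNR = mean/SD.

    Sentinels: SNR = +inf when SD = 0 with mean > 0 (a perfectly
    consistent connection); SNR = 0 when mean = 0 (absent).
    """

    mean: np.ndarray
    sd: np.ndarray
    snr: np.ndarray
    n_subjects: int

    @property
    def n_regions(self) -> int:
        return self.mean.shape[0]


def compute_snr(
    cohort: FiberCountCohort,
    group: str | None = None,
    group_by: str = "age_group",
    scan_indices: np.ndarray | None = None,
) -> SNRMatrix:
    """Connectivity SNR over the scans of one group (or explicit scan rows).

    Subjects without the connection contribute zeros to the pair's mean
    and SD — absence of a tract is signal, not missingness.
    """
    if scan_indices is None:
        if group is None:
            scan_indices = np.arange(cohort.n_scans)
        else:
            scan_indices = cohort.scan_indices(group_by, group)
    scan_indices = np.asarray(scan_indices)
    if scan_indices.size < 2:
        raise ValueError("SNR needs at least 2 subjects (SD undefined)")
    x = cohort.counts[scan_indices].astype(float)
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(mean > 0, np.where(sd > 0, mean / sd, np.inf), 0.0)
    np.fill_diagonal(snr, 0.0)
    return SNRMatrix(mean=mean, sd=sd, snr=snr, n_subjects=scan_indices.size)


def _ranked_pairs(snr: SNRMatrix) -> list[tuple[int, int]]:
    """All region pairs ranked for thresholding.

    Descending SNR; ties (including the +inf zero-variance sentinel tier)
    broken by higher mean, then by lexicographic pair index — fully
    deterministic and independent of input order.
    """
    n = snr.n_regions
    iu, ju = np.triu_indices(n, k=1)
    order = sorted(
        range(iu.size),
        key=lambda k: (-snr.snr[iu[k], ju[k]], -snr.mean[iu[k], ju[k]], iu[k], ju[k]),
    )
    return [(int(iu[k]), int(ju[k])) for k in order]


def threshold_to_cost(snr: SNRMatrix, target_cost: float) -> BackboneGraph:
    """Backbone at a target cost: keep the top round(cost*K) pairs by SNR.

    K = N(N-1)/2; rounding is half-up.  The realized cost |E|/K differs
    from the target by at most 1/(2K).
    """
    if not 0 < target_cost <= 1:
        raise ValueError("target_cost must be in (0, 1]")
    k_max = snr.n_regions * (snr.n_regions - 1) // 2
    n_edges = int(np.floor(target_cost * k_max + 0.5))  # half-up
    if n_edges == 0:
        raise ValueError(f"target_cost {target_cost} keeps zero edges")
    return BackboneGraph(snr.n_regions, frozenset(_ranked_pairs(snr)[:n_edges]))


def cost_sweep(
    snr: SNRMatrix, costs: list[float]
) -> list[dict[str, object]]:
    """Backbones over a cost grid, with largest-component sizes.

    Component size is nondecreasing in cost (edge sets are nested under
    the fixed tie-breaking), reaching N once no node is isolated.
    """
    out = []
    for c in costs:
        g = threshold_to_cost(snr, c)
        out.append(
            {
                "target_cost": c,
                "realized_cost": g.n_edges / g.max_edges,
                "graph": g,
                "largest_component": largest_component_size(g),
            }
        )
    return out


@dataclass
class LengthSummary:
    """Pooled fiber-length distribution of a group's backbone edges.

    ``edge_lengths`` are per-pair mean lengths (mm) over the subjects in
    which the connection is present; ``mean_mm`` is their pooled mean and
    ``q90_mm`` the 0.90 point of the empirical CDF (most fibers are
    short; the long tail is small).
    """

    edge_lengths: np.ndarray
    mean_mm: float
    q90_mm: float

    def cdf(self, x: np.ndarray | float) -> np.ndarray:
        """Empirical CDF of the pooled edge lengths, evaluated at x."""
        xs = np.sort(self.edge_lengths)
        return np.searchsorted(xs, np.asarray(x, dtype=float), side="right") / xs.size


def length_summary(
    cohort: FiberCountCohort,
    backbone: BackboneGraph,
    group: str | None = None,
    group_by: str = "age_group",
    scan_indices: np.ndarray | None = None,
) -> LengthSummary:
    """Mean fiber lengths of the backbone edges for one group.

    A pair's length is averaged over the group's scans where the
    connection is present (length > 0); backbone edges with no length
    data in any scan are excluded with a warning.
    """
    if cohort.lengths is None:
        raise ValueError("cohort has no fiber-length data")
    if scan_indices is not None:
        idx = np.asarray(scan_indices)
    elif group is None:
        idx = np.arange(cohort.n_scans)
    else:
        idx = cohort.scan_indices(group_by, group)
    lens = cohort.lengths[idx]
    vals = []
    missing = []
    for i, j in sorted(backbone.edges):
        present = lens[:, i, j] > 0
        if present.any():
            vals.append(lens[present, i, j].mean())
        else:
            missing.append((i, j))
    if missing:
        warnings.warn(
            f"{len(missing)} backbone edge(s) without length data excluded",
            stacklevel=2,
        )
    if not vals:
        raise ValueError("no backbone edge has length data")
    arr = np.asarray(vals)
    return LengthSummary(
        edge_lengths=arr,
        mean_mm=float(arr.mean()),
        q90_mm=float(np.quantile(arr, 0.90)),
    )
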
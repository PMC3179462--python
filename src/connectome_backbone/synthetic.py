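"""Synthetic fiber-count cohort generator.

Emulates the statistical structure the backbone analysis assumes, at the
fiber-count level (no images, tensors or streamlines): a cohort of 39
subjects scanned at three timepoints shares one planted modular backbone;
each scan draws overdispersed (negative-binomial) counts on the true
edges, sprinkles low-count spurious connections elsewhere, and records
lognormal mean fiber lengths whose location shifts upward with age.

The planted backbone is a stochastic block model with hemisphere-aware
modules (left/right module pairs plus one bilateral medial-style module by
default), with within/between edge probabilities chosen so the expected
backbone size matches the analysis cost of 0.21 (631 of 3003 region pairs
on the 78-node atlas).

No distributional form for fiber counts is published for this kind of
data; negative-binomial counts are this package's modeling choice —
overdispersion is what makes a mean/SD consistency statistic
discriminative between consistent and spurious connections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import RegionAtlas, synthetic_atlas
from .graph import BackboneGraph
from .cohort import FiberCountCohort


@dataclass(frozen=True)
class GroupSpec:
    """One cohort group (here: a longitudinal timepoint / age group).

    ``length_mean_mm`` is the expected inter-region fiber length for the
    group; ``count_scale`` multiplies the consistent-edge count mean.
    """

    label: str
    length_mean_mm: float
    count_scale: float = 1.0


#: Default age groups with mean connection fiber lengths (mm) matching the
#: developmental pattern: short predominantly proximal fibers at 2 weeks,
#: maturation of long-range fibers during the first two years.
DEFAULT_GROUPS: tuple[GroupSpec, ...] = (
    GroupSpec("2wk", 40.22),
    GroupSpec("1yr", 66.16),
    GroupSpec("2yr", 62.45),
)


def default_modules(n_regions: int) -> list[list[int]]:
    """Hemisphere-aware planted partition for a paired atlas.

    Stems are split into three blocks in ~16:14:9 proportion; the first
    two blocks form left/right module pairs, the last a bilateral module
    (five modules total on the 78-region atlas: 16+16, 14+14, 18 nodes).
    Assumes the interleaved ordering of :func:`~.atlas.synthetic_atlas` /
    :func:`~.atlas.default_atlas` (stem k -> nodes 2k, 2k+1).
    """
    if n_regions % 2:
        raise ValueError("paired module layout needs an even region count")
    stems = n_regions // 2
    g1 = max(1, round(stems * 16 / 39))
    g2 = max(1, round(stems * 14 / 39))
    g1 = min(g1, stems - 2)
    g2 = min(g2, stems - g1 - 1)
    blocks = [range(0, g1), range(g1, g1 + g2), range(g1 + g2, stems)]
    modules: list[list[int]] = []
    for b, block in enumerate(blocks):
        if b < 2:  # hemisphere-paired modules
            modules.append([2 * k for k in block])
            modules.append([2 * k + 1 for k in block])
        else:      # bilateral module
            modules.append([2 * k + o for k in block for o in (0, 1)])
    return modules


@dataclass
class CohortConfig:
    """Generator parameters; defaults describe the emulated study design."""

    n_regions: int = 78
    n_subjects: int = 39
    n_males: int | None = None  # default: the 18-of-39 study proportion
    groups: tuple[GroupSpec, ...] = DEFAULT_GROUPS
    modules_truth: list[list[int]] | None = None
    p_in: float = 0.70
    p_out: float = 0.094
    count_mean_consistent: float = 50.0
    count_dispersion: float = 5.0
    noise_edge_rate: float = 0.10
    noise_count_mean: float = 2.0
    noise_dispersion: float = 0.5
    subject_sigma: float = 0.20   # lognormal SD of per-scan count scaling
    length_sigma_pair: float = 0.40  # lognormal SD of per-pair base length
    length_sigma_scan: float = 0.10  # lognormal SD of per-scan length jitter
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p_out < self.p_in <= 1):
            raise ValueError("require 0 <= p_out < p_in <= 1")
        if self.count_dispersion <= 0 or self.noise_dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if not self.groups:
            raise ValueError("at least one group required")
        if not (0 <= self.noise_edge_rate <= 1):
            raise ValueError("noise_edge_rate must be in [0, 1]")
        if self.n_males is None:
            self.n_males = round(self.n_subjects * 18 / 39)
        if not 0 <= self.n_males <= self.n_subjects:
            raise ValueError("n_males must be within the subject count")
        if self.modules_truth is not None:
            flat = sorted(i for m in self.modules_truth for i in m)
            if flat != list(range(self.n_regions)):
                raise ValueError("modules_truth must partition all regions")

    def resolved_modules(self) -> list[list[int]]:
        if self.modules_truth is not None:
            return self.modules_truth
        return default_modules(self.n_regions)

    def module_labels(self) -> np.ndarray:
        lab = np.empty(self.n_regions, dtype=np.int64)
        for m, members in enumerate(self.resolved_modules()):
            lab[list(members)] = m
        return lab


def plant_backbone(
    config: CohortConfig, rng: np.random.Generator | None = None
) -> tuple[BackboneGraph, np.ndarray]:
    """Sample the ground-truth backbone: an SBM over the planted partition.

    Returns the graph and the per-node module labels.  Warns (does not
    fail) when ``p_in`` is so small that modules are expected to fragment.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    labels = config.module_labels()
    sizes = np.bincount(labels)
    if np.any(config.p_in * (sizes - 1) < 1):
        warnings.warn(
            "expected within-module degree < 1: planted modules may be "
            "internally disconnected",
            stacklevel=2,
        )
    n = config.n_regions
    same = labels[:, None] == labels[None, :]
    prob = np.where(same, config.p_in, config.p_out)
    iu = np.triu_indices(n, k=1)
    draw = rng.random(iu[0].size) < prob[iu]
    edges = frozenset(zip(iu[0][draw].tolist(), iu[1][draw].tolist()))
    return BackboneGraph(n, edges), labels


def _neg_binom(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """NB(mean, dispersion) with Var = mean + mean^2/dispersion."""
    mean = np.asarray(mean, dtype=float)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def sample_cohort(
    config: CohortConfig | None = None,
    atlas: RegionAtlas | None = None,
) -> tuple[FiberCountCohort, BackboneGraph, np.ndarray]:
    """Generate a full cohort; returns (cohort, true backbone, true modules).

    Every scan of every group shares the one planted backbone (the design
    is longitudinal: the same subjects are rescanned), with independent
    count noise per scan.  Fiber lengths live in a common stereotaxic
    space: a per-pair base length is shared across all scans, scaled by
    the group's mean length and a small per-scan jitter, so older groups
    have stochastically longer fibers.  Fully reproducible from
    ``config.seed``.
    """
    if config is None:
        config = CohortConfig()
    if atlas is None:
        atlas = synthetic_atlas(config.n_regions)
    if atlas.n_regions != config.n_regions:
        raise ValueError("atlas size does not match config.n_regions")

    rng = np.random.default_rng(config.seed)
    backbone, labels = plant_backbone(config, rng)

    n = config.n_regions
    iu = np.triu_indices(n, k=1)
    n_pairs = iu[0].size
    edge_mask = np.zeros(n_pairs, dtype=bool)
    edge_index = {e: k for k, e in enumerate(zip(iu[0].tolist(), iu[1].tolist()))}
    for e in backbone.edges:
        edge_mask[edge_index[e]] = True

    # per-pair base length, unit mean (lognormal with mu = -sigma^2/2)
    sp = config.length_sigma_pair
    pair_base = np.exp(rng.normal(-0.5 * sp * sp, sp, size=n_pairs))

    sexes = np.array(["M"] * config.n_males + ["F"] * (config.n_subjects - config.n_males))
    rng.shuffle(sexes)

    n_scans = config.n_subjects * len(config.groups)
    counts = np.zeros((n_scans, n, n), dtype=np.int64)
    lengths = np.zeros((n_scans, n, n), dtype=float)
    rows = []
    ss = config.length_sigma_scan
    row = 0
    for grp in config.groups:
        for s in range(config.n_subjects):
            subj_factor = np.exp(rng.normal(0.0, config.subject_sigma))
            vec = np.zeros(n_pairs, dtype=np.int64)
            true_mean = config.count_mean_consistent * grp.count_scale * subj_factor
            vec[edge_mask] = _neg_binom(
                rng, np.full(edge_mask.sum(), true_mean), config.count_dispersion
            )
            if config.noise_edge_rate > 0:
                noise_on = (~edge_mask) & (rng.random(n_pairs) < config.noise_edge_rate)
                if noise_on.any():
                    base = max(config.noise_count_mean - 1.0, 0.0)
                    vec[noise_on] = 1 + _neg_binom(
                        rng, np.full(noise_on.sum(), base), config.noise_dispersion
                    )
            jitter = np.exp(rng.normal(-0.5 * ss * ss, ss, size=n_pairs))
            lvec = np.where(vec > 0, grp.length_mean_mm * pair_base * jitter, 0.0)

            counts[row][iu] = vec
            counts[row] += counts[row].T
            lengths[row][iu] = lvec
            lengths[row] += lengths[row].T
            rows.append(
                {
                    "scan_id": f"S{s + 1:02d}_{grp.label}",
                    "subject_id": f"S{s + 1:02d}",
                    "age_group": grp.label,
                    "sex": sexes[s],
                }
            )
            row += 1

    cohort = FiberCountCohort(
        counts=counts, lengths=lengths, subjects=pd.DataFrame(rows), atlas=atlas
    )
    return cohort, backbone, labels
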
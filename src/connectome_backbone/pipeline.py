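"""End-to-end orchestration: simulate (or load) a cohort, build per-group
backbones at the analysis cost, and run every downstream analysis —
efficiency and centrality, small-world verdicts against rewired and
lattice nulls over a cost sweep, community detection and node roles,
broad-scale degree fits, hemispheric symmetry, and group comparisons.

Everything is reproducible from one master seed: stage k uses
``(master_seed * 100003 + k) mod 2^31``, a fixed splitting rule that
keeps stage-level reruns independent of one another.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from .backbone import compute_snr, length_summary, threshold_to_cost
from .cohort import FiberCountCohort, read_cohort_dir, write_cohort
from .community import detect_communities, node_roles, nonrandom_modularity_sweep
from .degree_dist import degree_fit
from .graph import largest_component_size, write_pajek
from .group_stats import compare_groups, hemisphere_symmetry
from .metrics import betweenness, efficiency_report, vulnerability
from .null_models import smallworld_sweep
from .synthetic import CohortConfig, sample_cohort


def stage_seed(master: int, stage: int) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    return (master * 100003 + stage) % (2**31)


@dataclass
class PipelineConfig:
    """Configuration of the full analysis run."""

    cohort: CohortConfig | None = None      # simulate when set
    input_dir: str | Path | None = None     # ... or load a written cohort
    cost: float = 0.21                      # analysis cost (fully connected point)
    cost_sweep: tuple[float, ...] = (0.10, 0.15, 0.21, 0.30)
    n_null: int = 100
    n_perm: int = 200
    seed: int = 0
    out_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if self.cohort is None and self.input_dir is None:
            self.cohort = CohortConfig(seed=stage_seed(self.seed, 0))


def _to_jsonable(x: Any) -> Any:
    if isinstance(x, dict):
        return {str(k): _to_jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_to_jsonable(v) for v in x]
    if isinstance(x, (np.floating, np.integer)):
        x = x.item()
    if isinstance(x, float) and not np.isfinite(x):
        return None  # strict-JSON representation of NaN/inf
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.bool_, bool)):
        return bool(x)
    return x


def run_all(config: PipelineConfig) -> dict[str, Any]:
    """Run the complete pipeline; returns (and optionally writes) the report."""
    report: dict[str, Any] = {"seed": config.seed, "cost": config.cost}

    if config.input_dir is not None:
        cohort = read_cohort_dir(config.input_dir)
    else:
        cohort, true_backbone, true_modules = sample_cohort(config.cohort)
        report["simulated"] = {
            "n_regions": config.cohort.n_regions,
            "n_scans": cohort.n_scans,
            "true_backbone_edges": true_backbone.n_edges,
            "true_n_modules": int(true_modules.max()) + 1,
        }
    groups = cohort.groups("age_group")
    report["groups"] = groups

    per_group: dict[str, Any] = {}
    for g in groups:
        snr = compute_snr(cohort, g)
        bb = threshold_to_cost(snr, config.cost)
        entry: dict[str, Any] = {
            "n_edges": bb.n_edges,
            "realized_cost": bb.n_edges / bb.max_edges,
            "largest_component": largest_component_size(bb),
        }
        eff = efficiency_report(bb)
        entry["metrics"] = {
            "e_glob": eff.e_glob,
            "e_loc": eff.e_loc,
            "cost": eff.cost,
        }
        btw = betweenness(bb)
        vul = vulnerability(bb)
        entry["betweenness_vulnerability_r"] = float(np.corrcoef(btw, vul)[0, 1])
        sym = hemisphere_symmetry(btw, cohort.atlas)
        entry["symmetry"] = {
            "slope": sym.slope,
            "pearson_r": sym.pearson_r,
            "p_value": sym.p_value,
        }
        if cohort.lengths is not None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ls = length_summary(cohort, bb, g)
            entry["fiber_length"] = {"mean_mm": ls.mean_mm, "q90_mm": ls.q90_mm}

        sw = smallworld_sweep(
            snr, list(config.cost_sweep), n_null=config.n_null,
            seed=stage_seed(config.seed, 1),
        )
        entry["small_world_sweep"] = sw
        entry["small_world_all_costs"] = all(r["small_world"] for r in sw)

        qsweep = nonrandom_modularity_sweep(
            snr, [config.cost], n_null=config.n_null,
            seed=stage_seed(config.seed, 2),
        )[0]
        part = detect_communities(bb)
        roles = node_roles(bb, part, labels=list(cohort.atlas.labels))
        entry["modularity"] = {
            "q": part.q,
            "n_modules": part.n_modules,
            "q_random_mean": qsweep["q_random_mean"],
            "q_random_sd": qsweep["q_random_sd"],
        }
        entry["communities"] = {
            str(m): [cohort.atlas.labels[i] for i in part.members(m)]
            for m in range(part.n_modules)
        }
        entry["roles"] = roles["role"].value_counts().to_dict()
        entry["role_table"] = {
            lab: {"z": float(z), "p": float(p), "role": r}
            for lab, z, p, r in zip(roles.index, roles["z"], roles["p"], roles["role"])
        }

        try:
            fit = degree_fit(bb)
            entry["degree_fit"] = {
                "alpha": fit.alpha,
                "k_cutoff": fit.k_cutoff,
                "r2_truncated": fit.r2_truncated,
                "r2_loglog": fit.r2_loglog,
                "gradient_magnitude": fit.loglog.gradient_magnitude,
            }
        except ValueError as err:  # e.g. near-regular degree sequence
            entry["degree_fit"] = {"error": str(err)}
        per_group[g] = entry

        if config.out_dir is not None:
            out = Path(config.out_dir)
            out.mkdir(parents=True, exist_ok=True)
            write_pajek(
                bb, list(cohort.atlas.labels), out / f"backbone_{g}.net",
                partition=part.assignment.tolist(),
            )
    report["per_group"] = per_group

    comparisons: dict[str, Any] = {}
    for grouping in ("age_group", "sex"):
        if len(cohort.groups(grouping)) < 2:
            continue
        comparisons[grouping] = {}
        for metric in ("global_efficiency", "local_efficiency", "mean_fiber_length"):
            if metric == "mean_fiber_length" and cohort.lengths is None:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cmp_res = compare_groups(
                    cohort, grouping=grouping, metric=metric, cost=config.cost,
                    n_perm=config.n_perm, seed=stage_seed(config.seed, 3),
                )
            comparisons[grouping][metric] = {
                "values": cmp_res.group_values.to_dict(),
                "p_values": {
                    f"{a}|{b}": float(cmp_res.p_values.loc[a, b])
                    for a in cmp_res.p_values.index
                    for b in cmp_res.p_values.columns
                    if a < b
                },
            }
    report["comparisons"] = comparisons

    report = _to_jsonable(report)
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        if config.input_dir is None:
            write_cohort(cohort, out / "cohort")
    return report
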
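"""End-to-end comparison of source localization methods.

Ties the forward simulator, the per-fold inverse fitting, the cluster-based
plausibility metric (on averaged training data and on single trials) and the
classification pipeline together into one seeded, reproducible report.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .forward import HeadModel, LeadField, compute_lead_field, load_montage, make_standard_montage
from .inverse import InverseOperator, apply_inverse
from .metric import (
    BaselineFit,
    cluster_sources,
    compare_methods,
    max_distance,
    nearest_cluster_distance,
    normalized_distance,
    random_baseline,
    select_top_sources,
)
from .pipeline import MOVEMENT, Recording, crossvalidate_by_run, segment_recording
from .simulate import SimulationConfig, simulate_trials
from .source_space import (
    ReferenceRegion,
    SourceSpace,
    adjacency_quantiles,
    build_graph,
    build_reference_region,
    load_mesh,
    make_sphere_source_space,
)

__all__ = ["ComparisonReport", "StudyContext", "build_study", "run_compare", "validate_config", "METHODS"]

logger = logging.getLogger(__name__)

METHODS = ("wmne", "dspm", "sloreta")

_KNOWN_KEYS = {
    "": {"seed", "methods", "source_space", "head_model", "montage", "simulate",
         "reference_region", "baseline", "metric", "classify"},
    "source_space": {"n_subdiv", "radius", "path", "hemisphere_rule"},
    "head_model": {"radii", "conductivities", "series_order"},
    "montage": {"n_channels", "path", "scalp_radius"},
    "simulate": {
        "active_vertices", "moments", "mrcp_peak", "mrcp_onset_lead",
        "background_count", "background_amplitude", "sensor_noise_sd",
        "trials_per_run", "runs", "rate", "rest_duration", "post_duration", "seed",
    },
    "reference_region": {"seed_vertices", "mni_coords"},
    "baseline": {"max_Nc", "n_samples"},
    "metric": {"fraction"},
    "classify": {"lambda_grid", "epsilon", "fraction"},
}


def validate_config(config: dict) -> None:
    """Reject unknown keys, reporting the offending key path."""
    for key in config:
        if key not in _KNOWN_KEYS[""]:
            raise ValueError(f"invalid config key: {key}")
        sub = config[key]
        if key in _KNOWN_KEYS and isinstance(sub, dict):
            for k2 in sub:
                if k2 not in _KNOWN_KEYS.get(key, set()):
                    raise ValueError(f"invalid config key: {key}.{k2}")


@dataclass
class StudyContext:
    space: SourceSpace
    lead_field: LeadField
    region: ReferenceRegion
    eps: float
    min_points: int
    recordings: list[Recording]
    baseline: BaselineFit
    ground_truth: list


@dataclass
class ComparisonReport:
    ba: dict[str, dict]
    distances: pd.DataFrame
    tests: dict
    baseline: dict
    params: dict
    version: str = field(default="")

    def to_json(self) -> str:
        summary = {
            "version": self.version,
            "balanced_accuracy": self.ba,
            "distance_means": {
                f"{m}/{s}/{v}": float(x)
                for (m, s, v), x in self.distances.groupby(["method", "scale", "variant"])[
                    "d_n"
                ]
                .mean()
                .items()
            },
            "excluded_no_cluster": int(self.distances["d_n"].isna().sum()),
            "tests": self.tests,
            "baseline_fit": self.baseline,
            "params": self.params,
        }
        return json.dumps(summary, indent=1, default=float)


def build_study(config: dict, seed: int | None = None) -> StudyContext:
    """Construct space, lead field, region, baseline and recordings from config."""
    validate_config(config)
    seed = int(config.get("seed", 0) if seed is None else seed)
    ss_cfg = dict(config.get("source_space", {}))
    if "path" in ss_cfg:
        space = load_mesh(ss_cfg["path"], ss_cfg.get("hemisphere_rule", "x-sign"))
    else:
        space = make_sphere_source_space(
            int(ss_cfg.get("n_subdiv", 3)), float(ss_cfg.get("radius", 70.0))
        )
    graph = build_graph(space)
    eps, min_points = adjacency_quantiles(graph)
    hm_cfg = dict(config.get("head_model", {}))
    default_head = HeadModel()
    head = HeadModel(
        tuple(hm_cfg.get("radii", default_head.radii)),
        tuple(hm_cfg.get("conductivities", default_head.conductivities)),
        int(hm_cfg.get("series_order", default_head.series_order)),
    )
    mo_cfg = dict(config.get("montage", {}))
    if "path" in mo_cfg:
        montage = load_montage(mo_cfg["path"], mo_cfg.get("scalp_radius", head.scalp_radius))
    else:
        montage = make_standard_montage(int(mo_cfg.get("n_channels", 128)), head.scalp_radius)
    t0 = time.perf_counter()
    lead_field = compute_lead_field(head, montage, space)
    logger.info("lead field %s x %s in %.2f s", lead_field.n_electrodes,
                3 * lead_field.n_sources, time.perf_counter() - t0)
    sim_cfg = dict(config.get("simulate", {}))
    sim_cfg.setdefault("seed", seed)
    sim = SimulationConfig(**{**sim_cfg, "active_vertices": tuple(sim_cfg.get("active_vertices", (0,)))})
    synth = simulate_trials(sim, lead_field)
    rr_cfg = dict(config.get("reference_region", {}))
    if "mni_coords" in rr_cfg:
        seeds = np.asarray(rr_cfg["mni_coords"], dtype=float)
    else:
        ids = rr_cfg.get("seed_vertices", list(sim.active_vertices))
        seeds = space.vertices[np.asarray(ids, dtype=int)]
    region = build_reference_region(space, graph, seeds)
    bl_cfg = dict(config.get("baseline", {}))
    baseline = random_baseline(
        space,
        region,
        max_Nc=int(bl_cfg.get("max_Nc", 15)),
        n_samples=int(bl_cfg.get("n_samples", 20_000)),
        seed=seed + 1,
    )
    return StudyContext(
        space, lead_field, region, eps, min_points,
        [s.recording for s in synth], baseline, synth,
    )


def _distance_rows(
    operator: InverseOperator,
    ctx: StudyContext,
    train_recs: list[Recording],
    method: str,
    fold: str,
    fraction: float,
) -> list[dict]:
    """Cluster-distance rows for one fold: averaged ERP and single trials."""
    movement = [
        s for r in train_recs for s in segment_recording(r) if s.label == MOVEMENT
    ]
    rows = []
    datasets = [("averaged", -1, np.mean([s.data for s in movement], axis=0))]
    datasets += [("single_trial", s.trial_id, s.data) for s in movement]
    for scale, trial, d in datasets:
        norms = apply_inverse(operator, d).norms[:, -1]  # at -0.05 s
        sel = select_top_sources(norms, fraction)
        clusters = cluster_sources(sel, ctx.space, ctx.eps, ctx.min_points)
        if clusters.n_clusters == 0:
            rows.append(dict(method=method, fold=fold, scale=scale, trial=trial,
                             variant="cluster", raw_mm=np.nan, n_clusters=0, d_n=np.nan))
        else:
            res = nearest_cluster_distance(clusters, ctx.region, ctx.space)
            rows.append(dict(
                method=method, fold=fold, scale=scale, trial=trial, variant="cluster",
                raw_mm=res.raw_distance, n_clusters=res.n_clusters,
                d_n=normalized_distance(res.raw_distance, res.n_clusters, ctx.baseline),
            ))
        mres = max_distance(norms, ctx.region, ctx.space, ctx.baseline.one_cluster_mean)
        rows.append(dict(method=method, fold=fold, scale=scale, trial=trial,
                         variant="maximum", raw_mm=mres.raw_distance,
                         n_clusters=mres.n_clusters, d_n=mres.normalized))
    return rows


def run_compare(config: dict, seed: int | None = None) -> ComparisonReport:
    """Execute the full three-method comparison on one (simulated) dataset."""
    ctx = build_study(config, seed)
    seed = int(config.get("seed", 0) if seed is None else seed)
    methods = list(config.get("methods", METHODS))
    cls_cfg = dict(config.get("classify", {}))
    fraction = float(config.get("metric", {}).get("fraction", 0.05))
    ba: dict[str, dict] = {}
    rows: list[dict] = []
    for method in methods:
        logger.info("evaluating %s", method)
        result, models = crossvalidate_by_run(
            ctx.recordings,
            ctx.lead_field,
            method=method,
            fraction=float(cls_cfg.get("fraction", fraction)),
            epsilon=float(cls_cfg.get("epsilon", 0.1)),
            seed=seed,
        )
        ba[method] = {
            "per_fold": result.per_fold_ba.tolist(),
            "mean": result.mean_ba,
            "sem": result.sem,
        }
        for model in models:
            train_recs = [r for r in ctx.recordings if r.run_id != model.test_run]
            rows += _distance_rows(
                model.solver.operator_, ctx, train_recs, method, model.test_run, fraction
            )
    distances = pd.DataFrame(rows)
    single = distances.query("scale == 'single_trial' and variant == 'cluster'")
    paired = {
        m: single.query("method == @m").sort_values(["fold", "trial"])["d_n"].to_numpy()
        for m in methods
    }
    ok = ~np.any([np.isnan(v) for v in paired.values()], axis=0)
    tests = compare_methods({m: v[ok] for m, v in paired.items()}) if ok.sum() >= 5 else {
        "pairs": [], "p_raw": [], "p_holm": [], "degenerate": [],
        "note": "fewer than 5 complete paired trials",
    }
    report = ComparisonReport(
        ba=ba,
        distances=distances,
        tests=tests,
        baseline={
            "coeff_a_mm": ctx.baseline.coeff_a,
            "exponent_b": ctx.baseline.exponent_b,
            "one_cluster_mean_mm": ctx.baseline.one_cluster_mean,
            "n_samples": ctx.baseline.n_samples,
            "seed": ctx.baseline.seed,
        },
        params={"seed": seed, "methods": methods, "config": config,
                "eps_mm": ctx.eps, "min_points": ctx.min_points,
                "region_vertices": int(len(ctx.region))},
        version=__version__,
    )
    return report


def write_report(report: ComparisonReport, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report.to_json())
    report.distances.to_csv(out / "distances.csv", index=False)
    pd.DataFrame(
        [
            {"method": m, "fold": i, "balanced_accuracy": v}
            for m, d in report.ba.items()
            for i, v in enumerate(d["per_fold"])
        ]
    ).to_csv(out / "balanced_accuracy.csv", index=False)
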
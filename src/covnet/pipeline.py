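"""End-to-end group analysis: residuals -> networks -> metrics -> inference.

``run_full_analysis`` reproduces the full layout of the group comparison:
minimum-full-connectivity analysis (global metrics, nodal metrics, hubs),
a density-sweep permutation comparison of the global measures, and the
overall correlation-strength t-test.  All artifacts are plain text and the
report records config, seeds, and version, so a rerun with the same config is
byte-identical (timings go to a separate log file).
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .inference import (
    NODAL_MEASURES,
    compare_strength,
    nodal_comparison,
    permutation_sweep,
)
from .io import read_volume_table, write_association_matrix, write_graph, write_volume_table
from .metrics import (
    betweenness_and_degree,
    generate_random_ensemble,
    small_worldness,
)
from .netbuild import (
    DensityGrid,
    build_association_matrix,
    min_full_connectivity_density,
    threshold_at_density,
)
from .preprocess import regress_confounds, regress_confounds_pooled

__all__ = ["run_full_analysis"]

_FLOAT_FORMAT = "%.12g"


def _results_frame(results) -> pd.DataFrame:
    rows = [
        {
            "measure": r.measure,
            "density": r.density,
            "roi": r.roi if r.roi is not None else "global",
            "observed_diff": r.observed_diff,
            "p": r.p_two_tailed,
            "ci_low": r.ci95_low,
            "ci_high": r.ci95_high,
            "null_mean": float(np.nanmean(r.null_diffs)) if len(r.null_diffs) else float("nan"),
            "significant": r.significant,
            "undefined": r.undefined,
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def run_full_analysis(config: RunConfig) -> dict:
    config.validate_paths()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    t_start = time.perf_counter()

    def log(stage: str) -> None:
        log_lines.append(f"{stage}: {time.perf_counter() - t_start:.2f}s elapsed")

    def stage(name):
        class _Stage:
            def __enter__(self):
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    log_lines.append(f"{name}: FAILED ({exc})")
                    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
                    raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
                log(name)
                return False

        return _Stage()

    with stage("read"):
        table_a = read_volume_table(config.group_a, config.covariates)
        table_b = read_volume_table(config.group_b, config.covariates)
        if table_a.roi_labels != table_b.roi_labels:
            raise ValueError("group tables have mismatched ROI labels")

    with stage("preprocess"):
        if config.pooled_confound_fit:
            resid_a, resid_b = regress_confounds_pooled(
                table_a, table_b, config.covariates
            )
        else:
            resid_a = regress_confounds(table_a, config.covariates)
            resid_b = regress_confounds(table_b, config.covariates)
        write_volume_table(resid_a, out_dir / "residuals_a.csv")
        write_volume_table(resid_b, out_dir / "residuals_b.csv")

    with stage("association"):
        assoc_a = build_association_matrix(resid_a)
        assoc_b = build_association_matrix(resid_b)
        write_association_matrix(assoc_a, out_dir / "assoc_a.csv")
        write_association_matrix(assoc_b, out_dir / "assoc_b.csv")
        strength = compare_strength(assoc_a, assoc_b)

    with stage("min_density"):
        min_density = min_full_connectivity_density([assoc_a, assoc_b])
        graph_a = threshold_at_density(assoc_a, min_density)
        graph_b = threshold_at_density(assoc_b, min_density)
        write_graph(graph_a, out_dir / "adjacency_a.csv", out_dir / "edges_a.tsv")
        write_graph(graph_b, out_dir / "adjacency_b.csv", out_dir / "edges_b.tsv")

    with stage("global_metrics"):
        global_metrics = {}
        for name, graph, offset in (("A", graph_a, 1), ("B", graph_b, 2)):
            ensemble = generate_random_ensemble(
                graph,
                config.ensemble_size,
                iterations_per_edge=config.iterations_per_edge,
                seed=config.seed + offset,
            )
            gm = small_worldness(graph, ensemble, path_length_mode=config.path_length_mode)
            global_metrics[name] = {
                "density": graph.density,
                "clustering": gm.clustering,
                "path_length": gm.path_length,
                "normalized_clustering": gm.gamma,
                "normalized_path_length": gm.lam,
                "small_worldness": gm.sigma,
                "ensemble_size": gm.ensemble_size,
            }

    with stage("density_sweep"):
        grid = DensityGrid.from_range(
            config.density_min, config.density_max, config.density_step
        )
        sweep_results = permutation_sweep(
            resid_a,
            resid_b,
            config.sweep_measures,
            grid,
            repetitions=config.repetitions,
            seed=config.seed,
            ensemble_size=config.ensemble_size,
            iterations_per_edge=config.iterations_per_edge,
            path_length_mode=config.path_length_mode,
        )
        sweep_frame = _results_frame(sweep_results)
        sweep_frame.to_csv(
            out_dir / "sweep_results.csv", index=False, float_format=_FLOAT_FORMAT
        )

    with stage("nodal"):
        nodal_results = nodal_comparison(
            resid_a,
            resid_b,
            min_density,
            repetitions=config.repetitions,
            seed=config.seed,
            path_length_mode=config.path_length_mode,
        )
        nodal_frame = _results_frame(
            [r for measure in NODAL_MEASURES for r in nodal_results[measure]]
        )
        # Rewired-ensemble nodal means: the alternative "random graph" null.
        rand_rows = []
        for name, graph, offset in (("A", graph_a, 3), ("B", graph_b, 4)):
            ensemble = generate_random_ensemble(
                graph,
                config.ensemble_size,
                iterations_per_edge=config.iterations_per_edge,
                seed=config.seed + offset,
            )
            bc = np.mean(
                [betweenness_and_degree(m).betweenness for m in ensemble.members], axis=0
            )
            for roi, value in zip(graph.roi_labels, bc):
                rand_rows.append(
                    {"group": name, "roi": roi, "rand_mean_betweenness": value}
                )
        nodal_frame.to_csv(
            out_dir / "nodal_results.csv", index=False, float_format=_FLOAT_FORMAT
        )
        pd.DataFrame(rand_rows).to_csv(
            out_dir / "nodal_random_null.csv", index=False, float_format=_FLOAT_FORMAT
        )

    with stage("hubs"):
        hub_rows = []
        nodal_obs = {}
        for name, graph in (("A", graph_a), ("B", graph_b)):
            nodal = betweenness_and_degree(graph)
            nodal_obs[name] = nodal
            for roi, degree, bc, hub in zip(
                nodal.roi_labels, nodal.degree, nodal.betweenness, nodal.is_hub
            ):
                hub_rows.append(
                    {
                        "group": name,
                        "roi": roi,
                        "degree": int(degree),
                        "betweenness": bc,
                        "is_hub": bool(hub),
                    }
                )
        pd.DataFrame(hub_rows).to_csv(
            out_dir / "nodal_metrics.csv", index=False, float_format=_FLOAT_FORMAT
        )

    report = {
        "version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "n_subjects": {"A": table_a.n_subjects, "B": table_b.n_subjects},
        "n_rois": table_a.n_rois,
        "min_full_connectivity_density": min_density,
        "strength_comparison": {
            "t": strength.t_statistic,
            "p": strength.p_value,
            "mean_z_a": strength.mean_z_a,
            "mean_z_b": strength.mean_z_b,
            "n_values": strength.n_values,
        },
        "global_metrics_at_min_density": global_metrics,
        "hubs": {
            name: sorted(nodal_obs[name].hub_labels()) for name in ("A", "B")
        },
        "artifacts": sorted(
            p.name for p in out_dir.iterdir() if p.suffix in {".csv", ".tsv"}
        ),
    }
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log("report")
    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
    return report
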
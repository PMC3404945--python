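"""Between-group inference on covariance networks.

Two pathways:

* overall correlation strength — Fisher r-to-z transform of all inter-regional
  correlations followed by a pooled two-sample t-test;
* network measures — nonparametric label permutation: subjects' residual rows
  are repeatedly reassigned to two groups of the original sizes, the whole
  association -> threshold -> measure pipeline is rerun, and the observed
  difference is located in the resulting null distribution (two-tailed,
  add-one corrected, never exactly zero).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .metrics import (
    betweenness_and_degree,
    characteristic_path_length,
    clustering_coefficient,
    generate_random_ensemble,
    small_worldness,
)
from .netbuild import AssociationMatrix, BinaryGraph, association_summary, build_association_matrix, threshold_at_density
from .preprocess import ResidualTable

__all__ = [
    "GLOBAL_MEASURES",
    "NODAL_MEASURES",
    "PermutationResult",
    "StrengthComparison",
    "fisher_r_to_z",
    "compare_strength",
    "permutation_sweep",
    "permutation_test",
    "nodal_comparison",
]

GLOBAL_MEASURES = ("clustering", "path_length", "gamma", "lambda", "sigma")
NODAL_MEASURES = ("betweenness", "degree")
_ENSEMBLE_MEASURES = frozenset({"gamma", "lambda", "sigma"})

MIN_REPETITIONS = 100


@dataclass
class PermutationResult:
    """Observed group difference for one measure at one density, with its null.

    ``observed_diff`` is group A minus group B.  ``roi`` is None for global
    measures.  ``undefined`` flags densities where the measure could not be
    evaluated on the observed networks (e.g. an empty graph); such results are
    emitted, not dropped.
    """

    measure: str
    density: float
    roi: str | None
    observed_diff: float
    null_diffs: np.ndarray
    p_two_tailed: float
    ci95_low: float
    ci95_high: float
    repetitions: int
    seed: int
    undefined: bool = False
    n_undefined_null: int = 0

    @property
    def significant(self) -> bool:
        """Observed difference falls outside the central 95% of the null."""
        if self.undefined:
            return False
        return not self.ci95_low <= self.observed_diff <= self.ci95_high


@dataclass(frozen=True)
class StrengthComparison:
    """Pooled t-test on Fisher-z correlations; t > 0 means A > B."""

    t_statistic: float
    p_value: float
    mean_z_a: float
    mean_z_b: float
    n_values: int

    @property
    def degrees_of_freedom(self) -> int:
        return 2 * self.n_values - 2


def fisher_r_to_z(r):
    """Variance-stabilizing z = arctanh(r); rejects |r| >= 1."""
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) >= 1.0):
        raise ValueError("Fisher r-to-z is undefined for |r| >= 1")
    z = np.arctanh(arr)
    return float(z) if np.isscalar(r) or arr.ndim == 0 else z


def compare_strength(
    assoc_a: AssociationMatrix, assoc_b: AssociationMatrix
) -> StrengthComparison:
    """Two-sample pooled-variance t-test on z-transformed correlations."""
    if assoc_a.n_rois != assoc_b.n_rois:
        raise ValueError("association matrices differ in size")
    zs = []
    for assoc in (assoc_a, assoc_b):
        r = association_summary(assoc)
        bad = np.flatnonzero(np.abs(r) >= 1.0)
        if bad.size:
            iu, ju = np.triu_indices(assoc.n_rois, 1)
            i, j = iu[bad[0]], ju[bad[0]]
            raise ValueError(
                "Fisher r-to-z undefined for |r| = 1 between "
                f"{assoc.roi_labels[i]} and {assoc.roi_labels[j]}"
            )
        zs.append(fisher_r_to_z(r))
    z_a, z_b = zs
    t_stat, p_val = stats.ttest_ind(z_a, z_b, equal_var=True)
    return StrengthComparison(
        t_statistic=float(t_stat),
        p_value=float(p_val),
        mean_z_a=float(z_a.mean()),
        mean_z_b=float(z_b.mean()),
        n_values=z_a.size,
    )


def _volume_matrix(table: ResidualTable) -> np.ndarray:
    return np.asarray(table.volumes, dtype=float)


def _assoc_from_rows(rows: np.ndarray, roi_labels: list[str]) -> AssociationMatrix:
    corr = np.corrcoef(rows, rowvar=False)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 0.0)
    return AssociationMatrix(roi_labels=roi_labels, values=corr, n_subjects=rows.shape[0])


def _graph_measures(
    graph: BinaryGraph,
    measures: Sequence[str],
    *,
    ensemble_size: int,
    iterations_per_edge: int,
    path_length_mode: str,
    rng: np.random.Generator,
) -> dict[str, float | np.ndarray]:
    out: dict[str, float | np.ndarray] = {}
    need = set(measures)
    if "clustering" in need:
        out["clustering"] = clustering_coefficient(graph)[1]
    if "path_length" in need:
        out["path_length"] = characteristic_path_length(graph, mode=path_length_mode)
    if need & _ENSEMBLE_MEASURES:
        ensemble = generate_random_ensemble(
            graph,
            ensemble_size,
            iterations_per_edge=iterations_per_edge,
            seed=int(rng.integers(0, 2**32)),
        )
        gm = small_worldness(graph, ensemble, path_length_mode=path_length_mode)
        if "gamma" in need:
            out["gamma"] = gm.gamma
        if "lambda" in need:
            out["lambda"] = gm.lam
        if "sigma" in need:
            out["sigma"] = gm.sigma
    if "betweenness" in need:
        out["betweenness"] = betweenness_and_degree(graph).betweenness
    if "degree" in need:
        out["degree"] = graph.degrees.astype(float)
    return out


def _split_measures(
    rows_a: np.ndarray,
    rows_b: np.ndarray,
    roi_labels: list[str],
    densities: Sequence[float],
    measures: Sequence[str],
    *,
    ensemble_size: int,
    iterations_per_edge: int,
    path_length_mode: str,
    rng: np.random.Generator,
) -> dict[tuple[str, float], float | np.ndarray]:
    """Measure differences (A minus B) for one labelling, keyed by (measure, density)."""
    assoc_a = _assoc_from_rows(rows_a, roi_labels)
    assoc_b = _assoc_from_rows(rows_b, roi_labels)
    diffs: dict[tuple[str, float], float | np.ndarray] = {}
    for density in densities:
        try:
            graph_a = threshold_at_density(assoc_a, density)
            graph_b = threshold_at_density(assoc_b, density)
            vals_a = _graph_measures(
                graph_a,
                measures,
                ensemble_size=ensemble_size,
                iterations_per_edge=iterations_per_edge,
                path_length_mode=path_length_mode,
                rng=rng,
            )
            vals_b = _graph_measures(
                graph_b,
                measures,
                ensemble_size=ensemble_size,
                iterations_per_edge=iterations_per_edge,
                path_length_mode=path_length_mode,
                rng=rng,
            )
        except ValueError:
            for measure in measures:
                diffs[(measure, density)] = (
                    np.full(len(roi_labels), np.nan)
                    if measure in NODAL_MEASURES
                    else np.nan
                )
            continue
        for measure in measures:
            diffs[(measure, density)] = vals_a[measure] - vals_b[measure]
    return diffs


def _make_result(
    measure: str,
    density: float,
    roi: str | None,
    observed: float,
    nulls: np.ndarray,
    repetitions: int,
    seed: int,
) -> PermutationResult:
    nulls = np.asarray(nulls, dtype=float)
    valid = nulls[np.isfinite(nulls)]
    n_bad = nulls.size - valid.size
    if not np.isfinite(observed) or valid.size == 0:
        return PermutationResult(
            measure=measure,
            density=density,
            roi=roi,
            observed_diff=float(observed),
            null_diffs=nulls,
            p_two_tailed=float("nan"),
            ci95_low=float("nan"),
            ci95_high=float("nan"),
            repetitions=repetitions,
            seed=seed,
            undefined=True,
            n_undefined_null=n_bad,
        )
    p = (1.0 + np.count_nonzero(np.abs(valid) >= abs(observed))) / (valid.size + 1.0)
    lo, hi = np.percentile(valid, [2.5, 97.5])
    return PermutationResult(
        measure=measure,
        density=density,
        roi=roi,
        observed_diff=float(observed),
        null_diffs=nulls,
        p_two_tailed=float(p),
        ci95_low=float(lo),
        ci95_high=float(hi),
        repetitions=repetitions,
        seed=seed,
        n_undefined_null=n_bad,
    )


def permutation_sweep(
    residuals_a: ResidualTable,
    residuals_b: ResidualTable,
    measures: Sequence[str],
    densities: Iterable[float],
    repetitions: int = 1000,
    seed: int = 0,
    *,
    ensemble_size: int = 20,
    iterations_per_edge: int = 10,
    path_length_mode: str = "component",
) -> list[PermutationResult]:
    """Label-permutation null for several measures over a density grid.

    Residual rows of the two groups are pooled and reassigned ``repetitions``
    times, preserving group sizes; each repetition uses an independent RNG
    seeded ``seed + repetition`` so runs are reproducible and parallelizable.
    Ensemble-dependent measures draw a fresh rewired ensemble for every
    permutation network from that repetition's stream.
    """
    if residuals_a.roi_labels != residuals_b.roi_labels:
        raise ValueError("residual tables have mismatched ROI labels")
    if repetitions < MIN_REPETITIONS:
        raise ValueError(f"repetitions must be >= {MIN_REPETITIONS}")
    unknown = set(measures) - set(GLOBAL_MEASURES) - set(NODAL_MEASURES)
    if unknown:
        raise ValueError(f"unknown measures: {sorted(unknown)}")
    densities = [float(d) for d in densities]
    roi_labels = list(residuals_a.roi_labels)
    rows_a = _volume_matrix(residuals_a)
    rows_b = _volume_matrix(residuals_b)
    n_a = rows_a.shape[0]
    pooled = np.vstack([rows_a, rows_b])
    n_total = pooled.shape[0]

    kwargs = dict(
        ensemble_size=ensemble_size,
        iterations_per_edge=iterations_per_edge,
        path_length_mode=path_length_mode,
    )
    observed = _split_measures(
        rows_a, rows_b, roi_labels, densities, measures,
        rng=np.random.default_rng(seed), **kwargs,
    )
    nulls: dict[tuple[str, float], list] = {key: [] for key in observed}
    for rep in range(1, repetitions + 1):
        rng = np.random.default_rng(seed + rep)
        perm = rng.permutation(n_total)
        diffs = _split_measures(
            pooled[perm[:n_a]], pooled[perm[n_a:]], roi_labels, densities, measures,
            rng=rng, **kwargs,
        )
        for key, value in diffs.items():
            nulls[key].append(value)

    results: list[PermutationResult] = []
    for measure in measures:
        for density in densities:
            obs = observed[(measure, density)]
            null = np.asarray(nulls[(measure, density)], dtype=float)
            if measure in NODAL_MEASURES:
                obs = np.asarray(obs, dtype=float)
                for idx, roi in enumerate(roi_labels):
                    results.append(
                        _make_result(
                            measure, density, roi, obs[idx], null[:, idx],
                            repetitions, seed,
                        )
                    )
            else:
                results.append(
                    _make_result(
                        measure, density, None, float(obs), null, repetitions, seed
                    )
                )
    return results


def permutation_test(
    residuals_a: ResidualTable,
    residuals_b: ResidualTable,
    measure: str,
    densities: Iterable[float],
    repetitions: int = 1000,
    seed: int = 0,
    **kwargs,
) -> list[PermutationResult]:
    """Single-measure convenience wrapper around :func:`permutation_sweep`."""
    return permutation_sweep(
        residuals_a, residuals_b, [measure], densities, repetitions, seed, **kwargs
    )


def nodal_comparison(
    residuals_a: ResidualTable,
    residuals_b: ResidualTable,
    density: float,
    repetitions: int = 1000,
    seed: int = 0,
    measures: Sequence[str] = NODAL_MEASURES,
    **kwargs,
) -> dict[str, list[PermutationResult]]:
    """Per-ROI permutation comparison of betweenness and degree at one density.

    Requires that the observed graphs of both groups are connected at the
    requested density (the analysis density is meant to be the minimum
    full-connectivity density).
    """
    for table in (residuals_a, residuals_b):
        assoc = build_association_matrix(table)
        if not threshold_at_density(assoc, density).is_connected():
            raise ValueError(
                f"group {table.group_label} network is disconnected at density {density}"
            )
    results = permutation_sweep(
        residuals_a, residuals_b, list(measures), [density], repetitions, seed, **kwargs
    )
    by_measure: dict[str, list[PermutationResult]] = {m: [] for m in measures}
    for res in results:
        by_measure[res.measure].append(res)
    return by_measure
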
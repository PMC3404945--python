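# covnet

Group-level structural covariance network analysis.

Starting from two tables of subject-by-region gray-matter volumes (one per
group, with per-subject age and total-brain-volume covariates), `covnet`:

1. regresses the linear effects of the covariates out of every region
   (residuals replace raw volumes);
2. builds one inter-regional Pearson association matrix per group across
   subjects, and binarizes it by keeping the E largest correlations at a
   target density D = E / (N(N-1)/2);
3. finds the minimum density at which both group networks become fully
   connected;
4. computes clustering coefficient, characteristic path length, normalized
   clustering/path length and the small-world index against degree-matched
   random ensembles (Maslov–Sneppen double-edge-swap), nodal betweenness and
   degree, and betweenness hubs (mean + 2 SD rule);
5. compares groups: overall correlation strength via Fisher r-to-z plus a
   pooled two-sample t-test, and network measures via a label-permutation
   test (subjects' residual rows reassigned to groups, two-tailed add-one
   p-values and 95% null intervals) across a density sweep.

A synthetic-cohort generator with planted block-correlation structure and
linear confounds stands in for MRI data, so the whole pipeline is testable
end to end.

## CLI

```bash
# simulate a two-group cohort (CohortSpec fields in YAML)
covnet simulate --config cohort.yaml --out-dir data/ --seed 1

# remove age/TBV effects from every region
covnet preprocess --in data/group_a.csv --covariates age,tbv --out a_resid.csv

# association matrix + one thresholded graph
covnet build --in a_resid.csv --density 0.184 --out-prefix grpA

# density-sweep permutation comparison only
covnet compare --group-a a_resid.csv --group-b b_resid.csv --out-dir results/

# full analysis (min-density metrics, sweep, nodal comparison, hubs, strength)
covnet run --config run.yaml
```

Example `cohort.yaml`:

```yaml
n_subjects_per_group: 35
n_rois: 90
n_modules: 6
r_within_a: 0.5
r_within_b: 0.3
r_between: 0.1
beta_age: 0.5
beta_tbv: 0.01
seed: 1
```

Example `run.yaml` (all fields optional except the two input paths):

```yaml
group_a: data/group_a.csv
group_b: data/group_b.csv
out_dir: results/
covariates: [age, tbv]
density_min: 0.05
density_max: 0.50
density_step: 0.01
repetitions: 1000
ensemble_size: 20
iterations_per_edge: 10
path_length_mode: component   # or harmonic
pooled_confound_fit: false
seed: 0
```

`covnet run` writes residual tables, association matrices, adjacency
matrices and edge lists at the minimum full-connectivity density, tidy CSVs
of the sweep and nodal permutation results, nodal metrics with hub flags,
and `report.json` (config, seeds, version, global metrics, hubs, strength
test). Reruns with an identical config are byte-identical; timings go to
`run.log` only.

A packaged fixture of 90 bilateral region labels (45 regions x left/right)
is available via `covnet.io.load_aal90_labels()` or
`covnet simulate --aal-labels`.

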
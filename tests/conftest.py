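import numpy as np
import pandas as pd
import pytest

from covnet import CohortSpec, generate_cohort, regress_confounds
from covnet.netbuild import AssociationMatrix, BinaryGraph
from covnet.synthetic import SubjectVolumeTable


@pytest.fixture(scope="session")
def null_cohort():
    """Two groups drawn from one distribution, with confounds to remove."""
    spec = CohortSpec(
        n_subjects_per_group=40,
        n_rois=30,
        n_modules=3,
        r_within_a=0.4,
        r_within_b=0.4,
        r_between=0.1,
        beta_age=0.5,
        beta_tbv=0.01,
        seed=11,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def null_residuals(null_cohort):
    a, b = null_cohort
    return regress_confounds(a), regress_confounds(b)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_table(volumes, *, group="A", age=None, tbv=None, labels=None):
    """Small volume table with default covariates, for hand-built fixtures."""
    volumes = np.asarray(volumes, dtype=float)
    n, p = volumes.shape
    rng = np.random.default_rng(99)
    if age is None:
        age = rng.uniform(43, 67, n)
    if tbv is None:
        tbv = rng.normal(1400, 100, n)
    if labels is None:
        labels = [f"R{i}" for i in range(p)]
    return SubjectVolumeTable(
        group_label=group,
        subject_ids=[f"{group}{i}" for i in range(n)],
        roi_labels=list(labels),
        volumes=volumes,
        covariates=pd.DataFrame({"age": age, "tbv": tbv}),
    )


def assoc_from_matrix(values, n_subjects=10):
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    return AssociationMatrix(
        roi_labels=[f"R{i}" for i in range(n)], values=values, n_subjects=n_subjects
    )


def graph_from_edges(n, edges, labels=None):
    adjacency = np.zeros((n, n), dtype=int)
    for a, b in edges:
        adjacency[a, b] = adjacency[b, a] = 1
    if labels is None:
        labels = [f"N{i}" for i in range(n)]
    return BinaryGraph(roi_labels=list(labels), adjacency=adjacency)


def random_graph(n, rng, p=None):
    """Random undirected graph on n nodes (at least one edge)."""
    if p is None:
        p = rng.uniform(0.2, 0.9)
    while True:
        upper = rng.random((n, n)) < p
        adjacency = np.triu(upper, 1)
        adjacency = (adjacency | adjacency.T).astype(int)
        if adjacency.sum() > 0:
            return graph_from_edges(
                n, list(zip(*np.nonzero(np.triu(adjacency, 1))))
            )
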
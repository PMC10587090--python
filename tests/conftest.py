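import numpy as np
import pandas as pd
import pytest

from pam50stab.datatypes import SUBTYPES, ExpressionMatrix
from pam50stab.classify import ReferenceSetCollection, build_reference_sets
from pam50stab.io import load_default_centroids, load_default_partition
from pam50stab.simulate import SimulationConfig, simulate_cohort

BASELINE = 3.0  # log2 FPKM baseline used by prototype fixtures


@pytest.fixture(scope="session")
def centroids():
    return load_default_centroids()


@pytest.fixture(scope="session")
def partition():
    return load_default_partition()


def make_prototype_cohort(centroids, n_per_subtype=4, baseline=BASELINE):
    """Noise-free cohort: each sample is an exact copy of one centroid row,
    mapped to FPKM through the fixed baseline. Returns (expr, labels)."""
    cols, labels = {}, {}
    for st in SUBTYPES:
        prof = np.exp2(centroids.values.loc[st].to_numpy() + baseline) - 0.1
        for i in range(n_per_subtype):
            sid = f"{st}_{i}"
            cols[sid] = prof
            labels[sid] = st
    expr = ExpressionMatrix(pd.DataFrame(cols, index=centroids.genes))
    return expr, pd.Series(labels)


@pytest.fixture(scope="session")
def prototype_cohort(centroids):
    return make_prototype_cohort(centroids)


@pytest.fixture(scope="session")
def prototype_refsets(prototype_cohort):
    expr, labels = prototype_cohort
    return build_reference_sets(expr, labels, {s: 1 for s in SUBTYPES},
                                n_sets=10, seed=5)


@pytest.fixture(scope="session")
def small_cohort(centroids):
    return simulate_cohort(centroids, SimulationConfig(n_samples=150, seed=42))


@pytest.fixture(scope="session")
def small_refsets(small_cohort):
    truth = small_cohort.truth
    labels = pd.Series(truth["true_subtype"].to_numpy(),
                       index=truth["sample_id"].to_numpy())
    comp = {s: max(2, int(round((labels == s).mean() * 30))) for s in SUBTYPES}
    return build_reference_sets(small_cohort.expression, labels, comp,
                                n_sets=25, seed=7)


@pytest.fixture(scope="session")
def truth_labels(small_cohort):
    truth = small_cohort.truth
    return pd.Series(truth["true_subtype"].to_numpy(),
                     index=truth["sample_id"].to_numpy())


def identical_refsets(expr: ExpressionMatrix, n_sets: int) -> ReferenceSetCollection:
    """n_sets copies of the whole-cohort reference (median centering)."""
    centering = expr.log2().median(axis=1)
    mat = pd.DataFrame({f"ref{k+1:03d}": centering for k in range(n_sets)})
    return ReferenceSetCollection(sets=[expr.samples] * n_sets, centering=mat)
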
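import pytest

from lshclust import (
    FamilySpec,
    LSHClusterer,
    benchmark_spec,
    generate_families,
    nn_identity_oracle,
    optimize_family,
)
from lshclust.align import ClusterCriteria


@pytest.fixture(scope="session")
def covering_family():
    """Zero-false-negative family at the standard operating point."""
    return optimize_family(12, 3, 24, 2, seed=0)


@pytest.fixture(scope="session")
def small_set():
    """A small mixed set: 4 families of 5 plus 10 singletons."""
    return generate_families(
        FamilySpec(
            n_families=4, members_per_family=5, target_identity=0.95,
            n_singletons=10, length_min=60, length_max=120,
            length_mean=90, length_sd=20, seed=11,
        )
    )


@pytest.fixture(scope="session")
def bench_set():
    """The standard desk-scale benchmark set (seed 101)."""
    return generate_families(benchmark_spec(seed=101))


@pytest.fixture(scope="session")
def bench_fit90(bench_set):
    records, _ = bench_set
    return LSHClusterer(min_identity=0.9, seed=101).fit(records)


@pytest.fixture(scope="session")
def bench_fit30(bench_set):
    records, _ = bench_set
    return LSHClusterer(min_identity=0.3, seed=101).fit(records)


@pytest.fixture(scope="session")
def bench_nn(bench_set):
    """Exhaustive all-vs-all nearest-neighbor identity oracle (deep
    criteria, matching the 0.3 clustering)."""
    records, _ = bench_set
    nn, table = nn_identity_oracle(records, ClusterCriteria(0.3, 0.8))
    return nn, table
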
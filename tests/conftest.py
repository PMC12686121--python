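import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

from zgakit.genes import GeneModel
from zgakit.pipeline import run_epigenome_benchmark, run_sequence_benchmark

BENCH_SEEDS = list(range(1, 11))


@pytest.fixture(scope="session")
def toy_genome():
    """20 nt toy chromosome with hand-checkable coordinates."""
    return {"chrT": "ACGTACGTAAGGCCTTACGT"}


@pytest.fixture(scope="session")
def small_forest_data():
    """A small fitted random forest plus its training data."""
    from sklearn.ensemble import RandomForestClassifier

    rng = np.random.default_rng(0)
    X = rng.normal(size=(80, 6))
    y = (X[:, 0] + 0.7 * X[:, 2] + 0.4 * rng.normal(size=80) > 0).astype(int)
    rf = RandomForestClassifier(n_estimators=10, max_depth=4, random_state=0).fit(X, y)
    Xdf = pd.DataFrame(X, columns=[f"f{i}" for i in range(6)])
    return rf, Xdf, y


@pytest.fixture(scope="session")
def sequence_benchmarks():
    """Planted-6-mer parameter-recovery runs over ten seeds (shared)."""
    return [run_sequence_benchmark(seed=s) for s in BENCH_SEEDS]


@pytest.fixture(scope="session")
def epigenome_benchmarks():
    """Planted mark-bump recovery runs over ten seeds (shared)."""
    return [run_epigenome_benchmark(seed=s) for s in BENCH_SEEDS]


def make_gene(gid="g1", chrom="chrT", strand="+", tss=5, tes=15):
    if strand == "-" and tss < tes:
        tss, tes = tes, tss
    return GeneModel(id=gid, chrom=chrom, strand=strand, tss=tss, tes=tes)
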
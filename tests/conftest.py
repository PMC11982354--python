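import numpy as np
import pandas as pd
import pytest

from episcreen import synthetic
from episcreen.methylome import BetaMatrix
from episcreen.transcriptome import CountMatrix


@pytest.fixture(scope="session")
def small_cohort():
    """A compact planted cohort shared by the integration-style tests."""
    spec = synthetic.CohortSpec(n_genes=150, n_planted=10, seed=11)
    return spec, synthetic.gen_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def toy_beta():
    """Hand-sized beta matrix: 5 probes, 3 genes, 4+4 samples."""
    samples = [f"T{i}" for i in range(4)] + [f"N{i}" for i in range(4)]
    rng = np.random.default_rng(7)
    values = pd.DataFrame(
        rng.uniform(0.05, 0.95, size=(5, 8)),
        index=[f"cg{i}" for i in range(5)],
        columns=samples,
    )
    ann = pd.DataFrame(
        {
            "gene": ["GA", "GA", "GB", "GC", None],
            "chrom": ["chr1"] * 5,
            "pos": range(100, 105),
            "region": ["island", "shore_N", "island", "open_sea", "shelf_S"],
        },
        index=values.index,
    )
    groups = pd.Series(["tumor"] * 4 + ["normal"] * 4, index=samples)
    return BetaMatrix(values, ann, groups)


@pytest.fixture()
def toy_counts():
    samples = [f"T{i}" for i in range(3)] + [f"N{i}" for i in range(3)]
    counts = pd.DataFrame(
        [[10, 20, 30, 40, 50, 60], [5, 5, 5, 5, 5, 5], [100, 90, 80, 70, 60, 50]],
        index=["g1", "g2", "g3"],
        columns=samples,
    )
    lengths = pd.Series([1000, 2000, 1500], index=counts.index)
    groups = pd.Series(["tumor"] * 3 + ["normal"] * 3, index=samples)
    return CountMatrix(counts, lengths, groups)
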
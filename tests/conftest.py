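import numpy as np
import pandas as pd
import pytest

from steatoreg.affinity import PositionWeightModel
from steatoreg.synthetic import SyntheticConfig, generate_all


def random_pwm(rng, width=6, name="TF"):
    counts = rng.integers(1, 50, size=(4, width)).astype(float)
    return PositionWeightModel.from_counts(name, counts)


def random_sequence(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture(scope="session")
def small_cfg():
    return SyntheticConfig(
        seed=7, n_genes=60, n_tfs=6, n_active_tfs=2, n_clusters=4,
        genome_length=1_200_000, n_peaks=60, de_fraction=0.5,
        n_cpgs=60, n_aging_cpgs=10, n_diet_cpgs=10, n_opposite_cpgs=5,
        n_samples_per_group=4,
    )


@pytest.fixture(scope="session")
def small_data(small_cfg):
    return generate_all(small_cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def toy_genes():
    # two genes on chr1 (one per strand), one on chr2
    return pd.DataFrame({
        "gene_id": ["g1", "g2", "g3"],
        "chrom": ["chr1", "chr1", "chr2"],
        "start": [10_000, 50_000, 5_000],
        "end": [12_000, 55_000, 9_000],
        "strand": ["+", "-", "+"],
        "tss": [10_000, 54_999, 5_000],
    })
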
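import numpy as np
import pandas as pd
import pytest

from popimmune.genotypes import SITE_COLUMNS, GenotypeMatrix


def make_sites(n, gene=None, prefix="rs"):
    return pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(1, n + 1) * 10,
            "ref": "A",
            "alt": "G",
            "gene": gene if gene is not None else [f"GENE{i}" for i in range(n)],
            "consequence": "missense_variant",
        },
        index=pd.Index([f"{prefix}{i}" for i in range(n)], name="site_id"),
    )[SITE_COLUMNS]


def make_genotypes(dosages, populations=None):
    """GenotypeMatrix from a (samples x sites) array."""
    dosages = np.asarray(dosages)
    n_samples, n_sites = dosages.shape
    if populations is None:
        populations = ["pop0"] * n_samples
    return GenotypeMatrix(
        sample_ids=[f"S{i}" for i in range(n_samples)],
        population_labels=np.asarray(populations),
        sites=make_sites(n_sites),
        dosages=dosages,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
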
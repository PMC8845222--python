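import numpy as np
import pandas as pd
import pytest

from vgscmap.features import assemble_design, build_lagged_features
from vgscmap.pipeline import StackedEnsemble
from vgscmap.synth import (
    SynthConfig,
    generate_covariate_fields,
    generate_latent_frequencies,
    sample_allele_counts,
)


@pytest.fixture(scope="session")
def small_cfg():
    return SynthConfig(n_samples=160, n_sites=60, seed=7)


@pytest.fixture(scope="session")
def small_data(small_cfg):
    grid = generate_covariate_fields(small_cfg)
    truth = generate_latent_frequencies(small_cfg, grid)
    samples = sample_allele_counts(truth, small_cfg)
    return grid, truth, samples


@pytest.fixture(scope="session")
def small_design(small_data):
    grid, _, samples = small_data
    return assemble_design(samples, build_lagged_features(grid))


@pytest.fixture(scope="session")
def small_features(small_data):
    grid, _, _ = small_data
    return build_lagged_features(grid)


@pytest.fixture(scope="session")
def small_fit(small_design):
    """One fitted ensemble shared by read-only tests."""
    return StackedEnsemble(small_design, K=4, seed=11).fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_simplex(rng, n, j):
    g = rng.gamma(2.0, size=(n, j))
    return g / g.sum(axis=1, keepdims=True)


def random_counts(rng, p, depth=40):
    return np.vstack([rng.multinomial(depth, row) for row in p])


@pytest.fixture(scope="session")
def toy_allele_csv(tmp_path_factory):
    """Six samples with mosquito counts (4, 5, 6, 2, 10, 5)."""
    path = tmp_path_factory.mktemp("ingest") / "alleles.csv"
    mosq = [4, 5, 6, 2, 10, 5]
    rows = []
    for i, m in enumerate(mosq):
        n = 2 * m
        rows.append(
            {
                "sample_id": i,
                "longitude": 1.0 + i,
                "latitude": 2.0,
                "year": 2010,
                "species": "gambiae",
                "n_mosquitoes": m,
                "n_alleles": n,
                "count_995L": n - 2,
                "count_995F": 2,
                "count_995S": 0,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
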
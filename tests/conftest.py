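import numpy as np
import pandas as pd
import pytest

import aeropollen as ap


@pytest.fixture(scope="session")
def city_matrix() -> pd.DataFrame:
    """Packaged 11-city percentage composition matrix."""
    return ap.load_city_composition()


@pytest.fixture(scope="session")
def city_env() -> pd.DataFrame:
    """Packaged per-city land-cover and climate covariates."""
    return ap.load_city_environment()


@pytest.fixture(scope="session")
def city_ordination(city_matrix) -> ap.OrdinationResult:
    """2-D nMDS of the 11 cities (top-8 taxa, sqrt Bray–Curtis, 50 restarts)."""
    top = ap.select_top_taxa(city_matrix, k=8)
    dist = ap.dissimilarity_matrix(top, metric="braycurtis", transform="sqrt")
    return ap.nmds(dist, n_restarts=50, seed=1)


@pytest.fixture
def hirst10() -> ap.SamplerSpec:
    return ap.SamplerSpec(kind="hirst", flow_rate_l_min=10.0)


@pytest.fixture
def daily_series():
    """Factory: concentration series DataFrame from a list of (date, value)."""

    def _make(pairs):
        return pd.DataFrame(
            {
                "date": pd.to_datetime([p[0] for p in pairs]),
                "grains_per_m3": [float(p[1]) for p in pairs],
            }
        )

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
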
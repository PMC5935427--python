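import numpy as np
import pandas as pd
import pytest

import sha2011 as sh
from sha2011.accounts_engine import CUBE_COLUMNS, AccountsCube


@pytest.fixture(scope="session")
def rules():
    return sh.default_rules()


@pytest.fixture(scope="session")
def small_config():
    # two cities, 30 institutions, 3600 encounters: fast but fully structured
    return sh.GeneratorConfig(n_cities=2, encounters_per_institution=120, seed=42)


@pytest.fixture(scope="session")
def census(small_config):
    return sh.generate(small_config)


@pytest.fixture(scope="session")
def census_truth(census, rules):
    return sh.tabulate_truth(census, rules)


@pytest.fixture(scope="session")
def census_coefficients(census):
    tallies = sh.tally(census.encounters, census.institutions)
    return sh.estimate_coefficients(tallies, census.provincial, kappa=census.config.kappa)


@pytest.fixture(scope="session")
def census_cube(census, census_coefficients, rules):
    return sh.compute_che(census.provincial, census.institutions, census_coefficients, rules)


def make_cube(rows, **metadata) -> AccountsCube:
    """Cube from (provider, function, scheme, disease, age, source, amount) tuples."""
    return AccountsCube(pd.DataFrame(rows, columns=CUBE_COLUMNS), metadata)


def cube_diff(a: AccountsCube, b: AccountsCube) -> float:
    """Maximum cell-wise relative difference between two cubes."""
    key = CUBE_COLUMNS[:5]
    sa = a.aggregated().set_index(key)["amount_cny"]
    sb = b.aggregated().set_index(key)["amount_cny"]
    idx = sa.index.union(sb.index)
    sa, sb = sa.reindex(idx).fillna(0.0), sb.reindex(idx).fillna(0.0)
    scale = np.maximum(np.abs(sb.to_numpy()), 1e-9)
    return float((np.abs(sa.to_numpy() - sb.to_numpy()) / scale).max())
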
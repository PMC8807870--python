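import logging

import numpy as np
import pytest

from crhnet import abc as abc_mod
from crhnet import build_crhs, crh_metrics, generate_fixture
from crhnet.simulate import FixtureConfig

logging.getLogger("crhnet").setLevel(logging.ERROR)

# small single-chromosome configuration for fast unit tests
SMALL_HUBS = (((1, 1),) * 4 + ((1, 3),) * 2 + ((2, 4),) * 2 + ((3, 8),))


def small_config(seed: int) -> FixtureConfig:
    return FixtureConfig(
        seed=seed,
        n_chrom=1,
        chrom_length=10_000_000,
        n_genes=60,
        n_elements=250,
        planted_hubs=SMALL_HUBS,
    )


@pytest.fixture(scope="session")
def fixture_default():
    """Default-sized fixture, seed 1."""
    return generate_fixture(seed=1)


@pytest.fixture(scope="session")
def fixture_small():
    return generate_fixture(small_config(7))


@pytest.fixture(scope="session")
def pairs_default(fixture_default):
    pairs = abc_mod.compute_abc_scores(
        fixture_default.elements, fixture_default.promoters, fixture_default.matrices
    )
    return abc_mod.threshold_pairs(pairs)


@pytest.fixture(scope="session")
def crhs_default(fixture_default, pairs_default):
    crhs = build_crhs(pairs_default)
    el_iv = {e.interval.id: e.interval for e in fixture_default.elements}
    pr_iv = {p.gene_id: p.interval for p in fixture_default.promoters}
    for c in crhs:
        crh_metrics(c, el_iv, pr_iv)
    return crhs


@pytest.fixture(scope="session")
def coord_maps(fixture_default):
    el_iv = {e.interval.id: e.interval for e in fixture_default.elements}
    pr_iv = {p.gene_id: p.interval for p in fixture_default.promoters}
    return el_iv, pr_iv


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
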
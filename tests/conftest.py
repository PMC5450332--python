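import numpy as np
import pytest

import survrules as sr


def random_records(rng, n, censor_p=0.4, weights=False, max_time=15):
    """Small random survival records for property tests."""
    recs = []
    for _ in range(n):
        recs.append(
            sr.SurvivalRecord(
                covariates={},
                time=float(rng.integers(1, max_time)),
                status=int(rng.random() > censor_p),
                weight=float(rng.choice([0.5, 1.0, 2.0])) if weights else 1.0,
            )
        )
    return recs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def km_basic():
    return sr.make_fixture("km_basic")


@pytest.fixture
def logrank_pair():
    ds = sr.make_fixture("logrank_pair")
    covered = [r for r in ds.records if r.covariates["group"] == "c"]
    uncovered = [r for r in ds.records if r.covariates["group"] == "u"]
    return covered, uncovered


@pytest.fixture
def ibs_mixed():
    return sr.make_fixture("ibs_mixed")


@pytest.fixture
def merge_coverage():
    return sr.make_fixture("merge_coverage")
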
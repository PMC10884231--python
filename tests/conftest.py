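import pytest

from germforge.fixtures import (
    ighd_fixture,
    ighj_fixture,
    ighv_fixture,
    igkj_fixture,
    igkv_fixture,
    iglj_fixture,
    iglv_fixture,
)
from germforge.pipeline import run_curation


def _curate(fx):
    return run_curation(fx["candidates"], fx["exemplars"], fx["donors"], fx["overrides"])


@pytest.fixture(scope="session")
def ighv_bundle():
    fx = ighv_fixture(0)
    return fx, _curate(fx)


@pytest.fixture(scope="session")
def igkv_bundle():
    fx = igkv_fixture(1)
    return fx, _curate(fx)


@pytest.fixture(scope="session")
def iglv_bundle():
    fx = iglv_fixture(2)
    return fx, _curate(fx)


@pytest.fixture(scope="session")
def ighd_bundle():
    fx = ighd_fixture(6)
    return fx, _curate(fx)


@pytest.fixture(scope="session")
def ighj_bundle():
    fx = ighj_fixture(3)
    return fx, _curate(fx)


@pytest.fixture(scope="session")
def igkj_bundle():
    fx = igkj_fixture(4)
    return fx, _curate(fx)


@pytest.fixture(scope="session")
def iglj_bundle():
    fx = iglj_fixture(5)
    return fx, _curate(fx)
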
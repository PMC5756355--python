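import pytest

from attribkit import UncertaintySpec, load_china_crc_2012, run_study
from attribkit.data_model import fixture_path, read_reported_pafs


@pytest.fixture(scope="session")
def china():
    return load_china_crc_2012()


@pytest.fixture(scope="session")
def reported():
    return read_reported_pafs(fixture_path() / "reported_pafs.csv")


@pytest.fixture(scope="session")
def china_estimates(china):
    return run_study(china, UncertaintySpec(draws=3000, seed=0))


def estimate(estimates, factor, stratum):
    return next(e for e in estimates if e.factor == factor and e.stratum == stratum)
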
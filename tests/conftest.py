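import pytest

from crc3s.capture_histories import CaptureMarginals, table_from_marginals


@pytest.fixture
def national_marginals():
    return CaptureMarginals(
        n=(2465, 1314, 2211),
        pair_overlaps=(721, 422, 415),
        triple_overlap=210,
        stratum="national",
    )


@pytest.fixture
def national_table(national_marginals):
    return table_from_marginals(national_marginals)


@pytest.fixture
def eastern_table():
    m = CaptureMarginals(
        n=(558, 337, 126), pair_overlaps=(211, 50, 64), triple_overlap=36, stratum="Eastern"
    )
    return table_from_marginals(m)


@pytest.fixture
def western_marginals():
    # printed marginals are mutually inconsistent: services-only cell is -17
    return CaptureMarginals(
        n=(357, 164, 609), pair_overlaps=(126, 182, 155), triple_overlap=100, stratum="Western"
    )
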
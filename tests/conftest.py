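import pytest

from kporph import build_skeleton, make_scenario


@pytest.fixture(scope="session")
def graph():
    return build_skeleton()


@pytest.fixture(scope="session")
def paper_like_records():
    """One paper_like scenario shared across thermo/spectra/interface tests."""
    return make_scenario("paper_like", seed=1)


@pytest.fixture(scope="session")
def records_by_level(paper_like_records):
    return {r.level: r for r in paper_like_records}
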
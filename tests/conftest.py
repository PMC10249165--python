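import pytest

from glottic_cea import fixture_pair, run_psa, table1_fixture


@pytest.fixture(scope="session")
def hypofrt_public():
    return table1_fixture("HYPOFRT", "public")


@pytest.fixture(scope="session")
def cfrt_public():
    return table1_fixture("CFRT", "public")


@pytest.fixture(scope="session")
def public_pair():
    return fixture_pair("public")


@pytest.fixture(scope="session")
def private_pair():
    return fixture_pair("private")


@pytest.fixture(scope="session")
def small_psa(public_pair):
    ref, comp = public_pair
    return run_psa(ref, comp, n=120, seed=5, wtp_grid=(0.0, 2_000.0, 40_000.0))


@pytest.fixture(scope="session")
def all_fixtures():
    return [
        table1_fixture(s, p)
        for s in ("HYPOFRT", "CFRT")
        for p in ("public", "private")
    ]
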
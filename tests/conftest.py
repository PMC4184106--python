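import pytest

from varvault.synthdata import build_wdm_fixture


@pytest.fixture(scope="session")
def wdm(tmp_path_factory):
    """The worked-example store: two affected samples carrying the 13
    published candidate SNPs, 24 decoy-bearing filter-group samples."""
    workdir = tmp_path_factory.mktemp("wdm")
    return build_wdm_fixture(workdir)


@pytest.fixture()
def tmp_store():
    from varvault.datastore import init_store

    store = init_store(":memory:")
    yield store
    store.close()
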
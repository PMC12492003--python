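import numpy as np
import pytest

from aqpflux.seqio import SeqRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_nt(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(4, size=n))


@pytest.fixture
def random_nt_record(rng):
    def make(n, rec_id="r"):
        return SeqRecord(rec_id, random_nt(rng, n))
    return make


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    """One small fixture bundle shared by the slower integration tests."""
    from aqpflux.synthetic import make_fixture_suite

    out = tmp_path_factory.mktemp("fixtures")
    manifest = make_fixture_suite(seed=11, out_dir=out, n_oocytes=4)
    return out, manifest
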
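import numpy as np
import pytest

import wgdtriplets as w


@pytest.fixture(scope="session")
def two_event_fixture(tmp_path_factory):
    """A small simulated (3,2) dataset written in the canonical pair format."""
    out = tmp_path_factory.mktemp("fixture")
    config = w.default_config(schedule=(3, 2), rates=(0.3, 0.4),
                              root_count=4000, seed=11)
    paths = w.make_fixture(config, out)
    return config, paths


@pytest.fixture(scope="session")
def fitted_selector(two_event_fixture):
    """The pipeline fitted once on the shared (3,2) fixture."""
    _, paths = two_event_fixture
    pairs = w.read_pairs(paths["pairs"])
    return w.PloidyHistorySelector(n_events=2).fit(pairs)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
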
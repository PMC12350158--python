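import numpy as np
import pytest

from svatlas.mei import MeiResources
from svatlas.synth import make_consensus_db


@pytest.fixture(scope="session")
def consensus_db():
    return make_consensus_db()


@pytest.fixture(scope="session")
def consensus_resources(consensus_db):
    """Consensus-only MEI resources (no genome), shared across tests."""
    return MeiResources.build(
        consensus_db,
        retro={"LTR": consensus_db["LTR"], "ERVK_INT": consensus_db["ERVK_INT"]},
        mito=consensus_db["MT"],
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
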
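import numpy as np
import pytest

from gaitbci.protocol import Protocol
from gaitbci.synth import SynthConfig, gen_session

#: Short protocol for fixture sessions: long enough for two decoder refits
#: and a handful of gait cycles in every phase, short enough to keep the
#: suite fast.
SHORT_PROTOCOL = Protocol(stand_pre=5.0, walk=130.0, walk_bci=20.0,
                          stand_post=5.0)


@pytest.fixture(scope="session")
def short_session():
    """High-SNR synthetic trial on the short protocol, with ground truth."""
    from dataclasses import replace
    config = replace(SynthConfig.preset("high-snr", seed=1234),
                     protocol=SHORT_PROTOCOL)
    bundle, truth = gen_session(config)
    return bundle, truth


@pytest.fixture(scope="session")
def session_folder(short_session, tmp_path_factory):
    """The short session written out as a trial folder."""
    from gaitbci.formats import write_session

    bundle, _ = short_session
    parent = tmp_path_factory.mktemp("sessions")
    return write_session(bundle, parent)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
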
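import numpy as np
import pytest

import netstates as ns


@pytest.fixture(scope="session")
def small_event():
    """One paper-regime synthetic event on a small grid (fast fixture)."""
    pre_spec, sz_spec = ns.paper_regime_specs(11, rows=4, cols=4, duration_s=40.0)
    pre, sz = ns.make_event(pre_spec, sz_spec)
    return pre_spec, sz_spec, pre, sz


@pytest.fixture(scope="session")
def small_cfg_pair(small_event):
    """Configuration matrices of the small event's two epochs."""
    pre_spec, sz_spec, pre, sz = small_event
    cfgs = []
    for ep in (pre, sz):
        wep = ns.preprocess_epoch(ep)
        cfgs.append(ns.to_configuration_matrix(ns.build_dynamic_network(wep)))
    return cfgs[0], cfgs[1]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
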
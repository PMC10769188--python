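import numpy as np
import pytest

from pippack.fixtures import FixtureSpec, make_backbone, make_chain
from pippack.model import PIPPack, PIPPackConfig


@pytest.fixture
def helix_chain():
    """20-residue ideal helix with staggered rotamers, proline-free sequence."""
    spec = FixtureSpec(length=20, sequence="AELKVFDSTNQRIMLHWYEA",
                       motif="helix", chi_mode="staggered", seed=11)
    chain, chi = make_chain(spec)
    return chain, chi


@pytest.fixture
def coil_chain():
    spec = FixtureSpec(length=12, motif="coil", chi_mode="random", seed=7)
    chain, chi = make_chain(spec)
    return chain, chi


@pytest.fixture
def coil_backbone():
    return make_backbone(FixtureSpec(length=10, motif="coil", seed=3))


def tiny_config(layer_type="ipmp", **kw):
    defaults = dict(hidden_dim=16, edge_dim=16, n_layers=1,
                    layer_type=layer_type, n_points=2, k_neighbors=6,
                    ipa_heads=2, ipa_channels=4, ipa_query_points=2,
                    ipa_value_points=2)
    defaults.update(kw)
    return PIPPackConfig(**defaults)


@pytest.fixture
def tiny_model():
    return PIPPack(tiny_config(), np.random.default_rng(0))
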
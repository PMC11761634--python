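import numpy as np
import pytest

from foldcover.synth import TorsionSpec, build_backbone
from foldcover.structio import BackboneStructure
from foldcover._geom import random_rotation


@pytest.fixture(scope="session")
def helix20():
    return build_backbone(TorsionSpec.helix(20), id="helix20")


@pytest.fixture(scope="session")
def strand10():
    return build_backbone(TorsionSpec.strand(10), id="strand10")


@pytest.fixture(scope="session")
def mixed40():
    return build_backbone(TorsionSpec.helix_hairpin(helix_n=14, arm=8), id="mixed40")


def rigid_copy(s: BackboneStructure, seed: int) -> BackboneStructure:
    """A rotated + translated copy of a structure (same chirality)."""
    rng = np.random.default_rng(seed)
    rot = random_rotation(rng)
    trans = rng.normal(0.0, 20.0, size=3)
    return BackboneStructure(
        id=s.id + "_rt",
        coords=s.coords @ rot.T + trans,
        chain_breaks=list(s.chain_breaks),
    )
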
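import numpy as np
import pytest

from artscore.classes import full_scheme, merged_scheme
from artscore.synthgen import generate_well, scene_for_class


@pytest.fixture(scope="session")
def full13():
    return full_scheme()


@pytest.fixture(scope="session")
def merged5():
    return merged_scheme()


@pytest.fixture(scope="session")
def crystal_well(full13):
    """A 384-px protein-crystal well (score 23) with UV mate."""
    spec = scene_for_class(full13.by_score(23), 384, 384, seed=42)
    return generate_well(spec, scheme=full13, chop_size=128)


@pytest.fixture(scope="session")
def clear_well(full13):
    spec = scene_for_class(full13.by_score(1), 384, 384, seed=43)
    return generate_well(spec, scheme=full13, chop_size=128)


@pytest.fixture(scope="session")
def salt_well(full13):
    """Visible crystal, no UV fluorescence."""
    spec = scene_for_class(full13.by_score(23), 384, 384, seed=42, salt=True)
    return generate_well(spec, scheme=full13)


@pytest.fixture(scope="session")
def trained_segmenter():
    """A tiny U-Net fitted on 8 small synthetic wells (shared by tests
    that need a working but not necessarily accurate segmenter)."""
    from artscore.dropseg import DropletSegmenter

    sch = full_scheme()
    rng = np.random.default_rng(7)
    wells = [
        generate_well(
            scene_for_class(sch.by_score(1), 64, 64, seed=int(rng.integers(2**31)))
        )
        for _ in range(8)
    ]
    images = np.stack([w.visible for w in wells])
    masks = np.stack([w.droplet_mask.astype(float) for w in wells])
    return DropletSegmenter(
        depth=2, base_filters=4, epochs=10, lr=2e-3, seed=0
    ).fit(images, masks)
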
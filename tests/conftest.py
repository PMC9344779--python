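"""Shared fixtures: small synthetic scenes and window datasets.

All fixtures are generated programmatically and sized for CPU speed;
windows stay at the mandatory 96 px, scenes are small multiples of it.
"""

import numpy as np
import pytest

from cytodetect.synthetic import SceneConfig, SyntheticScene, NucleusInstance, generate_scene
from cytodetect.windowing import assemble_balanced_dataset, split_dataset


SMALL = dict(height=288, width=384)  # 3 x 4 windows of 96 px


@pytest.fixture(scope="session")
def small_scene():
    return generate_scene(SceneConfig(n_blue=5, n_red=3, seed=7, **SMALL))


@pytest.fixture(scope="session")
def scene_ensemble():
    """30 small scenes for dataset assembly."""
    return [generate_scene(SceneConfig(n_blue=6, n_red=3, seed=100 + k, **SMALL))
            for k in range(30)]


@pytest.fixture(scope="session")
def tiny_dataset(scene_ensemble):
    """60-per-class balanced dataset with a 3:1 split."""
    samples = assemble_balanced_dataset(scene_ensemble, 60, seed=1)
    return split_dataset(samples, 0.75, seed=2)


def make_scene_from_masks(masks, lineages, shape=(288, 384)):
    """Hand-built scene: explicit instance masks on a blank image."""
    image = np.full(shape + (3,), 240, dtype=np.uint8)
    instances = []
    for i, (mask, lineage) in enumerate(zip(masks, lineages)):
        rows, cols = np.nonzero(mask)
        instances.append(NucleusInstance(
            id=i + 1, lineage=lineage,
            center=(float(rows.mean()), float(cols.mean())),
            semi_axes=(1.0, 1.0), rotation=0.0, mask=mask))
    return SyntheticScene(image=image, instances=instances, debris_count=0,
                          seed=0, source_id="handmade")
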
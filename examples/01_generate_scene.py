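"""Generate one synthetic cytology field and export its ground truth.

Builds a Papanicolaou-like field with 5 blue-lineage (basal) and 3
red-lineage (superficial) cells, then writes the image (TIFF + PNG),
per-instance masks, a labeled mask and COCO-style annotations.
"""

from cytodetect import SceneConfig, generate_scene, export_ground_truth

config = SceneConfig(n_blue=5, n_red=3, height=512, width=640, seed=7)
scene = generate_scene(config)
print(f"scene {scene.source_id}: {scene.image.shape[1]}x{scene.image.shape[0]} px, "
      f"{len(scene.instances)} nuclei "
      f"({len(scene.blue_instances())} blue), {scene.debris_count} debris blobs")
for inst in scene.instances:
    print(f"  nucleus {inst.id}: {inst.lineage:5s} lineage, "
          f"area {inst.area} px, center ({inst.center[0]:.0f}, {inst.center[1]:.0f})")

manifest = export_ground_truth(scene, "scratch/example_scene")
print(f"wrote {len(manifest)} files to scratch/example_scene/")
# Blue nuclei are the detection targets downstream; the per-instance masks
# are the exact ground truth every later stage is scored against.
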
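"""Cut detections into labelled 255x255 crops and plan an augmented dataset.

Shows the dataset layout arithmetic: 1000 originals per stage with two
augmented copies each gives 3000 per stage, and a stratified 3:1 split
yields 2250 training / 750 test images per stage.
"""

from soyemerge import (SceneConfig, generate_scene, detect_seedlings,
                       build_dataset)
from soyemerge.crops import cut_crop

image, truth = generate_scene(SceneConfig(seed=7, stage_mix=(0.34, 0.33, 0.33)))
detections, count = detect_seedlings(image)
crops = [cut_crop(image, det) for det in detections[:5]]
print(f"cut {len(crops)} crops of shape {crops[0].pixels.shape} "
      f"from {count} detections")

manifest = build_dataset([0] * 1000 + [1] * 1000 + [2] * 1000,
                         augment_per_original=2, split_ratio=(3, 1), seed=1)
print("per-class totals:", manifest.per_class_counts())
print("train split:     ", manifest.per_class_counts("train"))
print("test split:      ", manifest.per_class_counts("test"))
# Each original spawns two augmented copies (brightness / horizontal flip /
# saturation / random crop / scale, cycled), so 1000 -> 3000 per stage; the
# 3:1 split then gives 2250/750 per stage.
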
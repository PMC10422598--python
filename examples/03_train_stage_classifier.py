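"""Train the improved AlexNet on synthetic seedling crops (a few minutes on CPU).

Builds truth-labelled crops from three synthetic scenes, trains the
reduced-channel preset for 6 epochs and reports the average-loss /
average-accuracy training metrics plus held-out accuracy.
"""

import numpy as np

from soyemerge import (NetConfig, SceneConfig, TrainConfig, build_dataset,
                       build_model, detect_seedlings, evaluate,
                       generate_scene, train)
from soyemerge.crops import cut_crop, manifest_arrays
from soyemerge.net import average_metrics

crops = []
for seed in (11, 12, 13):
    image, truth = generate_scene(SceneConfig(seed=seed, stage_mix=(0.34, 0.33, 0.33)))
    detections, _ = detect_seedlings(image)
    centers = np.array([[p.x, p.y] for p in truth.plants])
    stages = np.array([p.stage for p in truth.plants])
    for det in detections:
        x0, y0, w, h = det.rect
        j = int(np.argmin((centers[:, 0] - (x0 + w / 2)) ** 2
                          + (centers[:, 1] - (y0 + h / 2)) ** 2))
        crops.append(cut_crop(image, det, label=int(stages[j])))

manifest = build_dataset(crops, augment_per_original=1, seed=0)
Xtr, ytr = manifest_arrays(manifest, crops, "train")
Xte, yte = manifest_arrays(manifest, crops, "test")
print(f"dataset: {len(Xtr)} train / {len(Xte)} test crops")

model = build_model(NetConfig.desk_scale(), seed=0)
print(f"model: {model.describe()['total_params']:,} parameters "
      f"(5 conv / 3 pool / 3 FC layers)")

cfg = TrainConfig.desk_scale(seed=0)
cfg.epochs = 6
history = train(model, (Xtr, ytr), (Xte, yte), cfg, verbose=True)
al, aa = average_metrics(history)
res = evaluate(model, Xte, yte)
print(f"average loss AL={al:.4f}, average accuracy AA={aa:.2f}%")
print(f"final test accuracy A={res.accuracy:.4f} "
      f"({res.n_correct}/{res.n_total} crops correct)")
print("confusion matrix (rows = true stage VE/VC/V1):")
print(res.confusion)
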
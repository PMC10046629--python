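"""Train MSegNet on a small synthetic set and score it on held-out images.

A scaled-down run: 48-px phantoms, 45 training originals augmented to
300, a narrow (8-feature) MSegNet, 6 epochs. Prints the per-epoch
validation Dice and the held-out per-image accuracy/IoU/Dice.
"""

from dataclasses import replace

import numpy as np

from mwbrain.augmentation import AugmentationPolicy, expand_training_set
from mwbrain.evaluation import segmentation_metrics
from mwbrain.msegnet import MSegNet, MSegNetConfig, segment
from mwbrain.synthetic_data import PhantomSpec, generate_dataset
from mwbrain.training import TrainConfig, compute_stats, train_model, zscore_normalize

spec = PhantomSpec(image_size=48)
train = generate_dataset(15, seed=1, spec=spec)   # 45 originals
val = generate_dataset(4, seed=2, spec=spec)
test = generate_dataset(5, seed=3, spec=spec)

augmented = expand_training_set(train, AugmentationPolicy(target_total=300, seed=5))
stats = compute_stats(train)
norm = lambda ss: [replace(s, image=zscore_normalize(s.image, stats)) for s in ss]

net = MSegNet(MSegNetConfig(initial_features=8, input_size=48),
              rng=np.random.default_rng(9))
history = train_model(net, norm(augmented), norm(val),
                      TrainConfig.segmentation(max_epochs=6, seed=9),
                      task="segmentation")
for row in history.itertuples():
    print(f"epoch {row.epoch}: train loss {row.train_loss:.3f}, "
          f"val Dice {row.val_metric:.3f}")

preds = [segment(net, zscore_normalize(s.image, stats)).mask for s in test]
scores = segmentation_metrics(preds, [s.mask for s in test])
print(f"held-out ({len(test)} images): accuracy {scores.accuracy:.3f}, "
      f"IoU {scores.iou:.3f}, Dice {scores.dice:.3f}")
print("Dice is the per-image overlap with the true tumor disks, averaged over")
print("the test set; a non-tumor image scores 1 only if the prediction is empty.")
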
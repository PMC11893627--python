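"""Desk-scale training of the inception U-Net on phantom spine ROIs.

Builds 32 noiseless spine ROI crops with their vertebra masks, trains
a reduced network for 10 epochs (binary cross-entropy, Adam at the
canonical 5e-4, He-normal init, 85:15 split) and reports Dice on the
training and validation folds.  Runs in a couple of minutes on one
CPU; scale n/epochs up for better masks.
"""

import numpy as np

from spinemetrics import NetworkConfig, build_model, train_model, predict, binarize
from spinemetrics.phantom import random_subject, rasterize_masks, render_pair
from spinemetrics.pipeline import preprocess_views
from spinemetrics.preprocess import (
    DEFAULT_ROI_SIZES, crop_resize_mask, crop_resize_normalize,
)
from spinemetrics.segment import dice_score

hw = (64, 32)
rng = np.random.default_rng(7)
images, targets = [], []
while len(images) < 32:
    cfg, g = random_subject(rng, noise_sd=0.0)
    pair = render_pair(g, cfg)
    masks = rasterize_masks(g, cfg)
    view = "frontal" if len(images) % 2 == 0 else "lateral"
    windows, success = preprocess_views(
        pair, roi_sizes={**DEFAULT_ROI_SIZES, "spine": hw}
    )
    if not success[view]["spine"]:
        continue
    w = windows[view]["spine"]
    images.append(crop_resize_normalize(pair.image(view), w))
    targets.append(crop_resize_mask(masks.view(view)["vertebra"], w))

net = NetworkConfig(input_hw=hw, depth=3, base_width=8, epochs=10,
                    batch_size=8, learning_rate=5e-4, seed=0)
model = build_model(net)
print(f"network parameters: {model.n_parameters()}")
hist = train_model(model, np.array(images), np.array(targets), net)
for e, (tb, vd) in enumerate(zip(hist.train_bce, hist.val_dice)):
    print(f"epoch {e:2d}  train BCE {tb:.4f}  val Dice {vd:.3f}")
x = np.array(images)
train_dice = np.mean([dice_score(binarize(predict(model, xi)), yi)
                      for xi, yi in zip(x, np.array(targets))])
print(f"training Dice after {net.epochs} epochs: {train_dice:.3f}")
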
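# rcunet

Breast-ultrasound tumor segmentation with **RCU-Net** — a U-Net variant
whose shortcut connections are refined by Res Paths and which adds a dense
input-to-decoder connection — together with the full pipeline around it:
synthetic ultrasound-phantom generation, preprocessing (bicubic resize +
CLAHE), training, the five-metric evaluation suite, and a k-fold
cross-validation harness. It is aimed at medical-image-analysis researchers
who want a dependency-light, fully reproducible reference implementation of
the architecture family and its evaluation protocol.

## The model

Plain U-Net routes raw encoder features to the decoder over shortcut
connections, which leaves a semantic gap between the two sides and loses
fine detail to pooling. RCU-Net makes two changes:

* **Res Path shortcuts.** Each shortcut carries a chain of residual units

  $$x_l = H_l(x_{l-1}) + x_{l-1},$$

  with 3×3 convolutions inside $H_l$: 4, 3, 2, 1 units at encoder levels
  1–4, at 64, 128, 256, 512 channels.
* **Dense input connection.** A dense block (base width $F=64$, growth rate
  $k=16$, four concatenation stages, layer $l$ seeing $F + k(l-1)$ input
  channels) runs from the raw input, at full resolution, straight to the
  last decoder stage; its 128-channel output is added element-wise to the
  128-kernel last decoder stage before the sigmoid head.

Training uses pixel-sum binary cross-entropy averaged over the batch
($L = \frac1n \sum_i \sum_{px} -(y\,\log\hat y + (1-y)\log(1-\hat y))$),
Adam ($\alpha=10^{-4}$, $\beta_1=0.9$, $\beta_2=0.999$, batch 4) and
he_normal initialization. Evaluation reports TP, FP, Dice, Jaccard and
Hausdorff distance per image, with JS > 0.75 as the per-image success rule.
The neural-network engine (convolutions, batch norm, backprop, Adam) is
implemented directly in NumPy — no deep-learning framework is required.

Clinical breast-ultrasound datasets with expert masks are rarely shareable,
so the package includes a speckle-phantom generator (deformed-ellipse
hypoechoic lesions, multiplicative Gamma speckle, fuzzy boundaries,
posterior shadows) that makes every stage testable end-to-end. See
`docs/methods.md` for modeling details and the generator's limitations.

## Worked example

```python
import numpy as np
from rcunet import (BackboneConfig, TrainConfig, build_variant,
                    evaluate_set, generate_dataset, train)
from rcunet.phantom import desk_phantom_spec

data = generate_dataset(250, desk_phantom_spec(seed=42))
train_pairs, test_pairs = data[:200], data[200:]

cfg = BackboneConfig(input_extent=(64, 64),
                     encoder_filters=(16, 32, 64, 128, 256))
model = build_variant("rcunet", cfg)
result = train(model, train_pairs, TrainConfig(epochs=30, seed=7))
print("first epochs:", [round(h, 1) for h in result.history[:3]])

pairs = [(mask, model(np.asarray(img)[None, None])[0, 0] >= 0.5)
         for img, mask in test_pairs]
_, agg = evaluate_set(pairs)
print({k: round(agg[k], 3) for k in ("tp", "fp", "dc", "js", "hd")},
      "successes:", agg["success_count"], "/", agg["n"])
```

Output (about 15 minutes on one CPU):

```
first epochs: [1697.0, 411.6, 328.7]
{'tp': 0.933, 'fp': 0.075, 'dc': 0.937, 'js': 0.893, 'hd': 2.98} successes: 46 / 50
```

The falling per-epoch loss shows the quarter-width, 64×64 desk-scale
RCU-Net learning from scratch; on the 50 held-out phantoms it recovers the
lesions with mean Dice 0.937 and a mean boundary error (Hausdorff) of about
3 pixels, and 46 of 50 segmentations clear the JS > 0.75 success bar.

The same models scale to the published 256×256/64-filter configuration
(`BackboneConfig()` defaults); a scikit-learn-style facade is available as
`rcunet.UNetSegmenter(variant="rcunet").fit(X, y).predict(X)`, and every
stage is also exposed on the command line (`rcunet phantom | preprocess |
train | evaluate | crossval`).

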
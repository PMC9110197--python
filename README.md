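# apunet

Attention-gated parallel U-Net for segmenting lung lesions in co-registered
tri-modal image crops (CT, PET, and fused PET/CT), together with a synthetic
phantom generator so the whole pipeline runs, trains, and is tested without
any clinical data.

## The problem and the model

Small pulmonary lesions are hard to delineate from a single modality: CT
shows anatomy but little lesion contrast, while PET shows a bright metabolic
hot spot with poor spatial resolution. The package implements a dual
parallel U-Net over 50×50 crops that fuses the three channels:

- **UNet_A** has two encoders (fused PET/CT and PET, channel ladder
  16→32→64→128→256) whose bottleneck features are summed before a shared
  decoder; **UNet_B** is a single-encoder U-Net on CT (32→…→512).
  Downsampling is 2×2 max-pooling with floor semantics (50→25→12→6→3);
  upsampling is a 2×2 transpose convolution that exactly mirrors the ladder
  back (3→6→12→25→50).
- A **two-modal fusion gate** combines same-scale PET and PET/CT encoder
  features: for the concatenation `c = [χ₁, χ₂]` the block computes
  `c ⊙ σ(Conv₃ₓ₃(ReLU(Conv₁ₓ₁(c))))`.
- Skip connections carry **hybrid attention** over the concatenated
  three-path features `χ = [F_hybrid, F_CT]`: a channel gate
  `χ + χ ⊙ σ(MLP(avgpool χ) + MLP(maxpool χ))` (shared MLP, hidden width
  ⌊C/3⌋) followed by a spatial gate
  `x + x ⊙ σ(Conv₃ₓ₃([mean_c x, max_c x]))`.
- A **multiscale feature-aggregation (MFA) head** resamples all four decoder
  scales of both subnetworks to full resolution, compresses each to 16
  channels (F, 64 channels total) and combines
  `F_MFA = F·α·β + F·α + F` with a learned channel gate α and pixel gate β.

Six ablation variants (plain U-Net, multi-encoder U-Net, parallel U-Net,
and parallel U-Net plus each block in isolation) share the construction
path, so all emit identically shaped logits. Segmentation quality is scored
with DSC, Recall, VOE and RVD:

```
DSC = 2|P∩G|/(|P|+|G|)   Recall = TP/(TP+FN)
VOE = |1 − |P∩G|/|P∪G||  RVD = ||P|/|G| − 1|
```

The network layers themselves (autodiff tensors, convolutions, batch norm,
pooling, bilinear resampling, Adam) are implemented in-package on numpy
(`apunet.nn`) and are validated against finite-difference gradients in the
test suite.

## Worked example

```python
import numpy as np
from apunet import (PhantomConfig, generate_triplet, ModelSpec, build_model,
                    TrainConfig, train, predict_mask, dsc)

sample = generate_triplet(PhantomConfig(seed=0), np.random.default_rng(0), "s0")
spec = ModelSpec(variant="apu_net", base_channels_a=4, base_channels_b=8)
model = build_model(spec, seed=0)
log = train(model, [sample], TrainConfig(epochs=200, batch_size=1, seed=0))
pred = predict_mask(model, sample)
print(f"final loss {log.final_loss:.4f}  dice {dsc(pred, sample.mask):.3f}")
```

prints

```
final loss 0.0126  dice 1.000
```

i.e. after 200 optimization steps on a single 50×50 phantom the model has
memorized the lesion exactly (a quick end-to-end sanity check of the
forward/backward path, the loss, and the optimizer).

The same pipeline from the shell:

```bash
apunet generate --n-train 64 --n-test 16 --size 50 --seed 0 --out data/
apunet train --data data/ --model apu_net --out runs/apu/
apunet predict --data data/ --run runs/apu/ --out preds/
apunet evaluate --pred preds/ --gt data/images --out report.csv
```

`apunet train` writes a checkpoint, a YAML sidecar (config + seed, from
which the run is exactly reproducible on CPU), a per-epoch training log, and
a per-sample metric CSV with a footer row of means.

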
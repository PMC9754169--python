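# ctdense

Densely sliced CT reconstruction in the longitudinal direction.

Abdominal CT volumes are usually anisotropic: fine in-plane resolution
but a coarse slice increment (e.g. 2.5 mm), because denser longitudinal
sampling costs radiation dose. `ctdense` synthesizes the missing
intermediate slices: for a chosen half-gap parameter m it reconstructs
the 2m − 1 slices between each pair of adjacent slices, turning a
sparsely sliced volume into a densely sliced one with no dose increase.

It is aimed at medical-image-analysis researchers who want a fully
self-contained, CPU-trainable implementation of:

- the **parallel U-net architecture**: 2m − 1 independently
  parameterized encoder–decoder networks sharing one two-slice input,
  each predicting one target position S_{t−m+k} from (S_{t−m}, S_{t+m}),
  so reconstructed positions cannot influence one another;
- the **range-clip organ enhancement**: per-organ transform
  f(x) = clip(B(x − C)) with C = R_ll, B = 1/(R_lh − R_ll) that
  stretches an organ's narrow intensity band [R_ll, R_lh] onto [0, 1],
  trains a dedicated model on transformed data, and merges
  f⁻¹(organ output) into the base reconstruction inside organ masks;
- the **evaluation protocol**: per-position MAE in HU, per-slice
  min-max-normalized SSIM, improvement percentages, paired Wilcoxon
  significance, and the μ rule for choosing m;
- a **synthetic phantom generator** (labeled ellipsoid "organs" with
  narrow intensity bands and nonlinear through-plane drift) so the whole
  pipeline trains and evaluates without patient data.

Everything deep-learning is implemented in numpy (see
`docs/methods.md`); there is no GPU or framework dependency.

## Worked example

```python
import numpy as np
from ctdense import (PhantomConfig, generate_dataset, make_grouping,
                     split_volume, reconstruct_linear, UnetSpec, TrainConfig,
                     build_parallel, train_parallel, predict_slices, mae)
from ctdense.pipeline import assemble_training_arrays

train, test = generate_dataset(PhantomConfig(), n_volumes=30, master_seed=1)
grouping = make_grouping(25, targets_per_gap=3)       # m = 2: sparse slices 1,5,9,...
X, Y = assemble_training_arrays(train, grouping, mirror=True)

spec = UnetSpec(encoder_blocks=4, decoder_blocks=3, base_channels=8,
                dropout_rate=0.2, image_shape=(64, 64))
cfg = TrainConfig(learning_rate=5e-3, lr_schedule="cosine", epochs=15,
                  augment_flips=True, seed=1)
model = build_parallel(spec, targets_per_gap=3, seed=1)
train_parallel(model, X, Y, cfg)

vol, labels = test[0]
sparse, truth = split_volume(vol, grouping)
pred = np.stack([predict_slices(model, sparse[g], sparse[g + 1])
                 for g in range(len(sparse) - 1)])
lin = np.stack(reconstruct_linear(sparse, 3))
print(f"linear   MAE: {mae(lin,  truth):5.1f} HU")
print(f"parallel MAE: {mae(pred, truth):5.1f} HU")
```

Output (the first held-out phantom of the seed-1 run):

```
linear   MAE:  54.3 HU
parallel MAE:  38.2 HU
```

The learned reconstructor removes much of the boundary ghosting that
linear interpolation produces on drifting organs: a 30% MAE reduction on
this volume, and 27% over the full held-out set of the bundled study
(47.5 → 34.5 HU, paired Wilcoxon p ≪ 0.01), with a further liver-region
gain from the range-clip model (34.1 → 28.0 HU inside the liver mask).

The same workflows are available as a CLI:

```
ctdense phantom --out data/ --n-volumes 30 --seed 1
ctdense train --data data/ --out model/ --targets-per-gap 3 --organ liver
ctdense reconstruct --input sparse.nii.gz --model model/ --method organ \
        --labels sparse_labels.nii.gz --out dense.nii.gz
ctdense evaluate --truth dense_gt.nii.gz --pred unet=dense.nii.gz --out report/
ctdense select-m --entry 1=5 --entry 2=12 --entry 3=20 --mu 15
```

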
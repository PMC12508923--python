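# sersdemux

Demultiplexing of PFOS Raman spectra from SERS mixtures with 1-D
encoder–decoder networks.

## The problem

Surface-enhanced Raman spectroscopy (SERS) amplifies the Raman signature of
trace contaminants such as perfluorooctanesulfonic acid (PFOS) enough to see
sub-ppb concentrations — but the measured spectrum is a noisy mixture of the
analyte signature, the substrate's own background, and shot noise. The two
PFOS marker lines are P1 at 997 cm⁻¹ (C–C) and P2 at 1,044 cm⁻¹ (S–O₃); P2
is the quantitation anchor because the blank substrate has no band there.

This package is for spectroscopists and ML practitioners who want a fully
seeded, CPU-only reference implementation of the demultiplexing approach:

* a synthetic-data generator for mixtures
  `M = K1·BKG + K2·PFOS + K3·GN` (K1, K2 ~ U(0.5, 5);
  K3 = max(K1·BKG + K2·PFOS) · U(0.01, 1)) with ground truth `K2·PFOS`,
  plus experimental-like PFOS-on-SERS stand-ins over a serial dilution,
  augmented by `C1·S + C2·noise`; default dataset sizes 2,160/240/60
  (train/validation/test), half simulated and half experimental-like;
* three architectures on length-896 spectra in [−1, 1]: **UNet**,
  **ResNet UNet**, and **Trans UNet** (a ResNet UNet whose bottleneck is
  element-wise multiplied with a transformer encoding of the input),
  implemented with hand-written adjoints in a compact numpy engine —
  no deep-learning framework required;
* training with Adam (lr 10⁻⁴), batch 8, mean-absolute-error loss;
* evaluation by zero-lag cross-correlation
  `R = Σ(xᵢ−x̄)(yᵢ−ȳ) / √(Σ(xᵢ−x̄)² Σ(yᵢ−ȳ)²)` and MAE in normalized
  units, reported as mean ± sample std;
* the three-step ground-truth procedure (baseline removal, 1,044 cm⁻¹
  intensity ratio, powder rescaling) and the P1/P2 calibration-curve
  analysis with a 3σ below-detection flag.

See `docs/methods.md` for the full model description and design choices.

## Worked example

```python
import numpy as np
from sersdemux import (DatasetConfig, build_dataset, records_to_arrays,
                       TransUNetDemultiplexer, evaluate)

splits = build_dataset(DatasetConfig(seed=1))     # 2160/240/60 records
X, Y   = records_to_arrays(splits.train)          # normalized to [-1, 1]
Xv, Yv = records_to_arrays(splits.validation)

est = TransUNetDemultiplexer(base_channels=8, embed_dim=32, n_layers=2,
                             epochs=30, seed=1)
est.fit(X, Y, Xv, Yv, verbose=True)
print(evaluate(est, splits.test).summary())
```

which prints (epoch lines abridged):

```
epoch 1/30 loss 0.26448 val_mae 0.14086
epoch 2/30 loss 0.11411 val_mae 0.09979
...
epoch 30/30 loss 0.05474 val_mae 0.05826
trans_unet: cross-correlation 0.8111 +/- 0.1609, MAE 0.0757 +/- 0.0651 (n=60)
```

The cross-correlation (≈1 means the demultiplexed spectrum has the right
shape: background and noise suppressed, marker peaks in place) and the MAE
(mean absolute deviation per point on the [−1, 1] scale) are computed
against each record's ground-truth PFOS component over the 60 held-out test
spectra. The numbers above are a desk-scale operating point (a ~0.2 M
parameter network, 30 epochs, ~14 minutes on one CPU); the metrics keep
improving with training budget. For reference, an ordinary-least-squares
projection onto the two known component templates — the linear floor for
this synthetic task — scores above 0.99 cross-correlation and below 0.01
MAE (bounded in the test suite).

The same pipeline is scriptable from the shell:

```bash
sersdemux simulate --seed 1 --out data.h5
sersdemux train --arch trans_unet --data data.h5 --epochs 30 \
          --base-channels 8 --embed-dim 32 --n-layers 2 --out trans.npz
sersdemux evaluate --checkpoint trans.npz --data data.h5 --report rep.json
sersdemux run-all --seed 1 --out runs/full          # everything, one seed
```

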
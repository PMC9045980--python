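# raunet — two-stage breast-tumor segmentation with a Recurrent Attention U-Net

`raunet` implements a two-stage deep-learning framework for segmenting
breast tumors in axial DCE-MRI slices, for researchers who need a fully
inspectable, CPU-runnable reference implementation of the method together
with a ground-truthed synthetic test bed.

Tumors occupy a tiny, low-contrast fraction of a slice dominated by chest
and background tissue. The framework attacks this in two stages:

1. **Stage 1 — breast ROI.** A U-Net (half the classic width; PReLU and
   group normalization throughout) segments the breast region of interest.
   Everything outside the (margin-dilated) ROI is masked away.
2. **Stage 2 — tumor.** A *Recurrent Attention U-Net* segments the tumor
   inside the ROI. Its encoder stages end in **dense residual modules** —
   cascades of three residual units with dilated 3×3 convolutions at rates
   (1, 2, 3), each unit accumulating all earlier unit inputs,
   `x_{t+1} = PReLU(x_1 + … + x_t + x_t³)` — which widen the receptive
   field without gridding holes. Its decoder replaces conv blocks with
   **recurrent attention modules**: a GRU consumes the globally max-pooled
   feature vector, its hidden state `h ∈ ℝ^{N/2}` (zero-initialized) is
   projected to channel weights `α ∈ (0,1)^N`, and the block emits
   `y_l = PReLU(x_l + x_l ⊙ α_l)`, iterated `L = 2` times.

Both stages train with the **Tversky loss** `1 − T(α, β)` where

    T = Σp₀g₀ / (Σp₀g₀ + α·Σp₀g₁ + β·Σp₁g₀),   α = 0.3, β = 0.7,

so missed lesion pixels cost more than false alarms (α = β = 0.5 is soft
Dice), optimized by Adam (lr 10⁻³) wrapped in Lookahead (k = 5,
α_slow = 0.5), batch size 4. Evaluation reports Jaccard, DSC, SEN, SPE,
PPV, ACC and the Hausdorff distance between foreground pixel sets.

Clinical DCE-MRI data are private, so the package ships a phantom
generator (`raunet.phantom`): breast-shaped bright regions over a chest
band, mass- and nonmass-type lesions (sharp versus irregular/blurred),
heavy class imbalance, optional bright distractor tissue outside the
breast, and mirroring/scaling/elastic augmentation. Networks and
optimizer run on a compact numpy autograd engine included in the package;
no GPU or deep-learning framework is required.

## Worked example

Fit the Recurrent Attention U-Net to small phantoms through the
scikit-learn-style estimator and score held-out slices:

```python
import numpy as np
from raunet import PhantomConfig, UNetSegmenter, generate_cases, split_cases

cases = generate_cases(
    PhantomConfig(image_size=64, n_slices_per_case=4, lesion_type="mass"),
    n_cases=12, seed=0,
)
train, test = split_cases(cases, train_fraction=0.8, seed=0)

def stack(cs):
    X = np.stack([s for c in cs for s in c.slices])
    y = np.stack([m for c in cs for m in c.tumor_masks])
    return X, y

X, y = stack(train)
Xt, yt = stack(test)

est = UNetSegmenter(variant="ra_unet", base_channels=4, epochs=30,
                    random_state=0).fit(X, y)
print(f"train loss {est.history_['train_loss'][-1]:.3f}  "
      f"held-out DSC {est.score(Xt, yt):.3f}")
```

```
train loss 0.199  held-out DSC 0.857
```

The final training loss is the per-slice Tversky loss (0 is a perfect
overlap); the score is the mean per-slice Dice coefficient on three unseen
phantom cases — at this desk scale the network recovers ~86% overlap with
the ground-truth lesions after ~300 optimizer steps.

The same workflow scales to the full pipeline: `TwoStageSegmenter` fits
the ROI net and the tumor net together, and the `raunet` CLI
(`raunet generate | train-roi | train-tumor | predict | evaluate`) runs
dataset generation, training, cascaded prediction and metric reports from
the shell.

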
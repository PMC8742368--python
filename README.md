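# mcistrat

Optimal-transport transfer learning for stratifying **early vs late mild
cognitive impairment (E-MCI / L-MCI)** from region-of-interest (ROI)
neuroimaging feature tables.

## The problem

Separating E-MCI from L-MCI patients matters clinically — the two stages
progress to Alzheimer's disease (AD) at different rates — but the contrast
between them in FDG-PET and VBM-MRI ROI features is subtle, while cohorts
are small (a few hundred subjects against 116 ROI features per modality).
Classifiers trained on the MCI samples alone overfit. The AD-vs-normal
control (NC) contrast in the *same* feature space is, by comparison, large
and easy to separate.

`mcistrat` exploits that asymmetry. Instead of the usual domain-adaptation
direction (map the easy source onto the hard target), it transports the
labelled E-MCI/L-MCI **training** samples onto the AD/NC domain, trains a
classifier where the boundary is clearly defined, and classifies
transported test samples there.

## The method

1. **Feature selection** — either a per-feature one-way ANOVA filter
   (keep p < 0.05), or rMLTFL, a multi-task sparse regression: three
   auxiliary classifiers (AD vs NC, AD vs MCI, MCI vs NC) predict a label
   for every target subject; stacking the true target label with the three
   predictions gives a multi-bit label matrix Y ∈ ℝ^(n×4), and

   min ‖Y − XW‖²_F + λ₁‖P‖₂,₁ + λ₂‖Qᵀ‖₂,₁
       + λ₃ Σᵢ ‖(Xw_t − Xw_i) − (y_t − y_i)‖²,  W = P + Q

   is solved by accelerated proximal gradient. Row-sparse P selects
   features, column-sparse Q identifies auxiliary domains; domains whose
   Q column vanishes are pruned and the model refitted.

2. **Class-paired optimal transport** — an entropic (Sinkhorn) coupling γ
   between target-train and source samples, optionally with an L1l2 or
   Lp l1 group penalty over target classes that softly enforces the
   pairing L-MCI → AD, E-MCI → NC. Training samples map by barycentric
   projection; held-out samples by a k-nearest-neighbour displacement
   extension.

3. **Kernel logistic regression** (linear or polynomial) trained on AD/NC
   plus the transported MCI training samples, with +1 = AD/L-MCI side.

4. **Bootstrap aggregation** — 5 bags by leave-one-fold-out subsampling;
   each bag refits its own transport and classifier; majority-vote labels
   and mean probabilities.

## Worked example

```python
import numpy as np
from mcistrat import (AdniLikeSpec, make_adni_like, PipelineConfig,
                      TransportConfig, KernelSpec, cross_validate)

table = make_adni_like(AdniLikeSpec(seed=0))      # 211/273/187/160 cohort
cfg = PipelineConfig(
    selection="rmltfl", lambdas=(1.0, 1.0, 1.0),
    transport=TransportConfig(regularizer="SD", epsilon=0.1),
    kernel=KernelSpec("linear"), classifier="ot_klr",
)
res = cross_validate(table, cfg, k=10, seed=0)
print(res.summary())
```

prints

```
Protocol: cv10 (seed 0)
========================================
accuracy: 68.48 +/- 7.36 %
AUC:      0.725 +/- 0.066
```

i.e. ten-fold cross-validated accuracy (percent, mean ± sd over folds) and
AUC of the transfer pipeline on the synthetic cohort: the subtle E/L-MCI
contrast is recovered well above the ~59% majority-class rate, and above
the no-transport logistic baseline (swap `classifier="logistic"` to see
it). The same objects drive the command line:

```bash
mcistrat simulate --kind adni --seed 0 --out runs/table.csv
mcistrat select   --input runs/table.csv --method anova --out runs/sel.json
mcistrat evaluate --input runs/table.csv --protocol cv10 --out runs/cv.json
mcistrat run      --config config.yaml        # full pipeline + manifest
```

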
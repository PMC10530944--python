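# eigenstep

A hybrid multi-class classifier for same-size grayscale images, built for
medical-imaging-style problems where a handful of global intensity patterns
separate a few diagnostic classes — the motivating case is dementia-severity
grading of 128×128 brain MRI slices (non / very-mild / mild / moderate).
The pipeline is:

1. **Smoothing** — a 3×3 box-average mask (every weight 1/9) slides over each
   image, replicate-padded at the borders, suppressing pixel-level noise.
2. **Eigenspace projection** — PCA on the flattened training images; an image
   becomes its scores on the top-K eigenvectors of the pixel covariance
   (K = 150 by default for full-size images).
3. **Stepwise linear discriminant analysis (SWLDA)** — features are admitted
   and removed one at a time by partial significance tests. The class labels
   are indicator-coded, Y ∈ {0,1}^{N×G}, and for a candidate feature x_j
   given the selected set S the partial statistic is the Wilks'-lambda ratio

   Λ = det E(S ∪ {j}) / det E(S),   F = (1 − Λ)/Λ · (ν_E − q + 1)/q,

   where E(·) is the residual scatter of the indicator regression, q = G − 1
   and ν_E the residual degrees of freedom; F is exact under the
   F(q, ν_E − q + 1) reference for a single added predictor, and for two
   classes reduces to the squared partial t of an ordinary least-squares fit.
   Forward steps admit the smallest p-value below α_enter = 0.35; backward
   steps remove the largest p-value above α_remove = 0.40; at most 125
   features are kept.
4. **Dense network** — selected scores feed a one-hidden-layer perceptron
   (512 ReLU units, inverted dropout 0.5, softmax output) trained with Adam
   (learning rate 0.001, batch 32, 100 epochs, stratified validation split
   0.25) on categorical cross-entropy.
5. **Evaluation** — stratified 10-fold cross-validation with per-fold
   refitting of every learned stage, accumulated into a row-normalized
   percentage confusion matrix with per-class sensitivity/specificity and
   both macro and support-weighted averages.

A synthetic phantom generator (`eigenstep.synth`) produces multi-class image
sets whose class signal lives in a low-dimensional subspace of pixel space,
so the whole pipeline is exercisable and testable without any external data.

## Worked example

```python
from eigenstep import (
    SynthSpec, generate_dataset, PipelineConfig, PreprocessConfig,
    StepwiseConfig, MLPConfig, EvalConfig, cross_validate,
)

spec = SynthSpec(image_height=32, image_width=32,
                 n_per_class=(200, 200, 200, 200),
                 effect_size=1.0, noise_sd=0.05, n_signal_modes=6, seed=7)
config = PipelineConfig(
    preprocess=PreprocessConfig(height=32, width=32),
    pca_k=40,
    stepwise=StepwiseConfig(max_features=20),
    mlp=MLPConfig(hidden_dim=64, epochs=60),
    eval=EvalConfig(n_folds=10, seed=7),
)
report = cross_validate(generate_dataset(spec), config)
print(report.to_text())
```

prints

```
Recognition Rates (%)
              non_demented very_mild      mild  moderate
non_demented      100.00      0.00      0.00      0.00
very_mild           0.00    100.00      0.00      0.00
mild                0.00      0.00    100.00      0.00
moderate            0.00      0.00      0.00    100.00
Average (macro)    100.00
Average (weighted) 100.00
```

Each row is a true class and shows where its images were predicted, as
percentages of that class; the macro average is the plain mean of the
diagonal recognition rates, while the weighted average is overall accuracy.
With four well-separated phantom classes the scaled-down pipeline classifies
every held-out image correctly; setting `effect_size=0.0` in the same spec
drops the macro average to the 25% chance floor (±10 points), confirming the
pipeline finds signal only where the generator put it.

The same run is available from the shell:

```bash
eigenstep synth --config config.yaml --out data/
eigenstep crossval --config config.yaml --manifest data/manifest.csv --out run/
eigenstep report run/
```

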
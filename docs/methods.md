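# Methods

## Model and procedure

The pipeline classifies N same-size grayscale images into G classes in four
stages. Smoothing replaces each pixel by the unweighted mean of its
size×size neighborhood (default 3×3, i.e. nine weights of 1/9); borders are
completed by replicating the nearest edge pixel so the output keeps the
input's size and range. Images are then flattened to D-vectors, centered on
the training mean, and decomposed by thin SVD; the top K right singular
vectors are the eigenvectors of the training covariance (divisor N−1), and
an image's features are its K projection scores. The stepwise discriminant
selector reduces those K scores to at most `max_features` columns, and a
one-hidden-layer softmax network maps the selected scores to class
probabilities.

### Stepwise selection

The labels are indicator-coded. Because the regressions always contain an
intercept, one indicator column is redundant and q = G − 1 response columns
are used. For a candidate feature j conditional on the selected set S, the
residual scatter matrices E(S) and E(S ∪ {j}) of the multivariate
least-squares fit give Wilks' Λ = det E(S ∪ {j}) / det E(S), and with a
single added predictor the Rao transform

F = (1 − Λ)/Λ · (ν_E − q + 1)/q,  ν_E = N − |S ∪ {j}| − 1

is exactly F(q, ν_E − q + 1) distributed under the null. For G = 2 this is
algebraically the squared partial t of the candidate's coefficient in an
ordinary single-response regression — the property the test suite uses as
its fidelity anchor. The texts describing this family of procedures
variously call the per-step tests Z-, t- or F-tests; here they are uniformly
the partial F above.

Each iteration runs one forward step (admit the minimum-p candidate if
p < α_enter and the cap leaves room; ties broken by smaller p then lower
feature id) followed by a backward sweep (repeatedly drop the maximum-p
selected feature while p > α_remove). Defaults are α_enter = 0.35,
α_remove = 0.40 and a cap of 125 features; a stricter 0.15/0.20 screening
pair ships as `StepwiseConfig.screening_preset()`. Requiring
α_enter ≤ α_remove rules out a feature re-entering with the same p-value
that just removed it; a `max_iterations` guard (default 1000) catches any
residual oscillation and raises, carrying the partial result, rather than
returning silently.

Degenerate numerics: residual scatters are positive semidefinite, so an
eigenvalue at or below 1e−12 × (total response sum of squares) is treated
as exact zero. A singular *reduced* scatter means the current selected set
already fits the labels perfectly — `partial_statistic` raises a
`CollinearityError` naming the feature; `run_stepwise` interprets that as
"nothing left to explain" in the forward direction and as "this feature is
redundant" (p = 1) in the backward direction. A singular *full* scatter is
a perfect fit by the candidate: Λ = 0, F = ∞, p = 0.

### Dense network

Defaults: 512 hidden ReLU units, inverted dropout 0.5 (training only),
softmax output, categorical cross-entropy, Adam with learning rate 0.001
and conventional moments (β₁ = 0.9, β₂ = 0.999, ε = 1e−8), batch 32, 100
epochs with no early stopping, stratified validation split 0.25 used for
monitoring only. The trainable-parameter count is
d·h + h + h·g + g (e.g. 100·512+512 = 51,712 plus 512·4+4 = 2,052, total
53,764). Weights start from a fan-in-scaled uniform (±√(6/fan_in)); biases
at zero. The implementation is plain numpy: at this scale (~50k parameters)
a framework adds nothing, and a single seeded generator driving
initialization, shuffling and dropout makes training bit-reproducible on a
platform. Epoch metrics are computed in inference mode (dropout off) after
each epoch. No class weighting is applied. The surrounding literature is
internally inconsistent about the input width of this network (150 PCA
components vs a 125-feature selection cap vs parameter arithmetic computed
for 100 inputs); the implementation therefore treats all three as
configuration and always sizes the input layer from the number of features
actually selected.

### Evaluation

Stratified k-fold assignment (default k = 10) deals each class's shuffled
members round-robin over a shuffled fold order, so per-fold class counts
deviate from proportionality by at most one; classes with fewer than two
members are rejected, and a class thinner than k simply misses some test
folds while remaining in every training fold. Within each fold the
eigenspace, the selection and the network are refitted on training folds
only — the smoothing filter has no fitted state and is applied once
globally. A `global_fit` switch reproduces the leakier protocol (eigenspace
and selection fitted on all data) for comparison. Reports keep raw doubles;
the display rounds half-even at 2 decimals. The macro average is the
unweighted mean of the diagonal of the row-normalized percentage matrix
(rows with zero support excluded); the weighted average equals overall
accuracy, 100·trace/N. Published recognition-rate tables in this layout
usually label their headline number a "weighted average" even when it is
the plain diagonal mean; `report_from_rates` computes both from a printed
table so the distinction is explicit. If no feature clears α_enter (as
happens on signal-free data), the fold falls back to the single smallest-p
feature so the classifier stage remains well-defined.

## Synthetic phantoms

`SynthSpec` draws, from one seeded stream in fixed order: the frequencies
of `n_signal_modes` low-frequency cosine-product patterns, one coefficient
vector per class (scaled so the class pattern's pixel standard deviation is
about 0.08·effect_size regardless of the mode count), then per-image i.i.d.
Gaussian pixel noise. Every image is a shared smooth elliptical "anatomy"
plus its class's fixed pattern plus noise, clipped to [0, 1]. The default
spec uses 128×128 images with per-class counts 320/224/90/8 — roughly a
tenfold scale-down of a public four-class dementia MRI collection's
3200/2240/896/64 imbalance — effect_size 1.0, noise 0.05, six modes.

What the phantoms emulate: class information concentrated in a
low-dimensional subspace of pixel space (the assumption the eigenspace +
stepwise method relies on), pixel noise, and class imbalance. What they do
not emulate: anatomical variability within a class (the only within-class
variation is pixel noise), registration error, intensity inhomogeneity, or
scanner effects. Passing tests therefore demonstrate the pipeline's
correctness and its ability to find subspace-confined signal, not clinical
performance on real MRI. No noise or intensity model for real scans was
available, so the phantom parameters are conventions chosen for clear
signal-to-noise contrast, not estimates.

## Problem sizes and numerical choices

Tests and the acceptance script run the full pipeline at 32×32 pixels, 40
components, a 20-feature cap, a 64-unit hidden layer and 60 epochs —
choices that keep the phantom studies desk-scale while leaving every stage's
logic identical to the full-size configuration (the defaults above). The
end-to-end studies use 200 images per class (high-signal) and 100 per class
(zero-signal control).

Other numerical conventions: the covariance divisor is N−1 (affects
eigenvalue scale only); eigenvector signs are fixed so each row's
largest-magnitude entry is positive, making serialized models comparable
across platforms; PCA is computed by thin SVD so the D×D covariance is
never materialized (equivalent to the Gram-matrix route for N < D);
bilinear resampling for resizing; ITU-R 601 luminance for color inputs;
intensities are floating [0, 1] internally and 8-bit only at file
boundaries. Whether smoothing precedes or follows resizing is a convention;
the pipeline resizes at load time and smooths afterwards.

## Known limitations

- The stepwise loop recomputes the reduced-model scatter for every
  candidate; at the full 150-feature/125-cap configuration this is the
  dominant cost. Sweep-operator updates would remove it but are not
  implemented.
- `fld_weights` (the indicator least-squares discriminant weights) is
  exposed for analysis but the classifier stage uses the network, not the
  linear weights.
- The one-hidden-layer network offers no convolutional inductive bias; on
  real images the eigenspace features carry all spatial structure.
- Bit-reproducibility is per-platform; across BLAS builds, final-epoch
  accuracies agree only to a couple of points.
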
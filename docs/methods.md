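# Methods

This note records the model, the free choices made where the design was
genuinely open, the defaults and why, and what the synthetic data can and
cannot establish.

## Model and procedure

The classifier is a linear softmax head over fixed embeddings with batch
normalization in front: the only trainable pieces are the normalization
scale/shift `γ, β`, the dense weights `W ∈ R^{d×2}` and bias `b`. The
flattened parameter vector also carries the normalization running
statistics (mean, variance), giving length `6d + 2`; the trailing `2d + 2`
coordinates are the dense layer, the only part calibrated for uncertainty.

Training: categorical cross-entropy, batch size 2, inverted dropout at rate
0.5 between normalization and the dense layer, adaptive moments
(β₁ = 0.9, β₂ = 0.999, ε = 1e−8) with *decoupled* weight decay — the dense
weights are shrunk by `(1 − λ)` each step independent of the learning
rate — and a triangular cyclic learning rate (base 1e−3, max 1e−2, period
100 steps). The "lazy" sparse-update mode skips moment updates for
dense-weight rows whose gradient is exactly zero in a step, which with 50%
dropout is roughly half the rows; disabling it gives plain dense updates.
Epoch count (default 50), the schedule bounds and the decay factor are
exposed in `TrainConfig`: the method fixes the components, not their
values.

At inference the normalization uses running statistics (momentum 0.99) and
dropout is off. Batch statistics at test time would make a prediction
depend on which other cases share its batch — unacceptable at batch size 2
— and a deterministic likelihood keeps the posterior sampler well defined.

### SWA and the trajectory subspace

Every `collect_every = 10` epochs the flattened parameters are folded into
a running average and the deviation *from the updated running mean* is
recorded (the literal "error between the current parameters and the
average" reading; deviations from the final mean are available behind a
flag). The PCA basis is the top right-singular-vectors of the deviation
matrix, sign-fixed by making each row's largest-magnitude entry positive so
the decomposition is deterministic.

Two independently-seeded training runs must share one subspace for the
curve to live in. The pipeline pools both runs' deviation rows, anchors the
subspace at the average of the two SWA solutions, and appends each SWA
solution's offset from that anchor as two extra deviation rows. The extra
rows guarantee the direction connecting the endpoints is exactly
representable, so projecting the SWA solutions into the subspace loses
nothing of the geometry the curve needs. Default rank 5; the curve stage
then works in its own 2-d slice, so rank mainly sets the ambient space.
Only the dense-layer coordinates of any reconstructed vector are taken from
the subspace; normalization statistics and scales stay frozen at the anchor
values.

### Bezier curve

`ϕ_θ(t) = (1−t)² w¹ + 2t(1−t) θ + t² w²` with `w¹, w²` the projected SWA
solutions, immutable by construction (the optimizer only ever touches θ).
θ starts at the segment midpoint, which makes the untrained curve exactly
the straight line between the endpoints — the natural zero-training
baseline. Each optimization step samples one `t ~ U[0,1]` (a `t_batch`
averaging variant is exposed), evaluates the training cross-entropy at
`ϕ_θ(t)` mapped through the basis, and takes an Adam step on θ; because the
loss sees only dense coordinates, the gradient is the dense block of the
basis times the midpoint coefficient `2t(1−t)`. Defaults: 30 epochs of 10
steps, lr 0.05.

### Posterior sampling

The sampling space is the 2-d affine frame centred at the segment midpoint
`c = (w¹+w²)/2` with axes `(w²−w¹)/2` and `θ − c`, so coordinates `(−1,0)`,
`(1,0)`, `(0,1)` are `w¹`, `w²`, `θ`. An isotropic `N(0, prior_sd² I)`
prior (default sd 1) covers the curve's convex hull at O(1) coordinates. A
1-d alternative that squashes a scalar coordinate through the standard
normal CDF onto the curve position `t` is available (`space="t1d"`); the
2-d frame is the default because it follows the subspace-inference
construction the curve comes from.

The log-likelihood is `−n_train · CE / temperature` (temperature default 1,
exposed because posterior tempering is a genuinely open choice here).
Elliptical slice sampling uses the standard shrinking-bracket transition;
non-finite likelihood proposals are treated as log-likelihood −∞ and the
bracket shrinks past them, and a 1000-iteration guard returns the current
state if the bracket ever collapses (the angle→0 limit reproduces the
current state, so this is safe). Defaults: burn-in 500, no thinning, 5000
kept draws. Since normalization is frozen, the normalized test features are
computed once and each posterior draw costs one dense layer + softmax.

Under a two-class softmax the sampled `(p_ACP, p_NOTACP)` rows sum to one,
so the two per-case class variances are identical by construction; the
package asserts this rather than reporting the two margins as independent
diagnostics.

### Decision layer

ArgMax calls the class with the larger mean sampled probability. The KS
branch needs reference distributions for each class: a fraction (default
0.2) of training patients per class is carved out *before* any fitting and
used only to build pooled ACP-probability reference samples. Holding them
out matters — references from patients the model trained on would
understate out-of-sample predictive spread and bias the KS p-values toward
rejection. References are part of the fitted model; test labels are never
touched at decision time.

The KS statistic is the exact pooled-ECDF sup-difference; the p-value is
the asymptotic series `Q(λ) = 2 Σ (−1)^{k−1} e^{−2k²λ²}`,
`λ = D√(nm/(n+m))`, truncated at terms below 1e−12 and clipped into
(0, 1] so the NOTACP/ACP p-value ratio is always defined. All ties (equal
class means, ratio exactly 1) resolve to NOTACP — the non-positive,
clinically conservative call.

The class-mean-difference filter (a Welch test between a case's two
probability margins, abstaining cases with p ≥ α over a grid
{0.05, 0.01, 0.005, 0.001}) is provided as the diagnostic it is: a
threshold of exactly 0 disables it, and identical margins (p ≈ 1) abstain
at every positive threshold.

## Synthetic cohort

The generator emulates the study cohort's skeleton: 23 ACP / 30 NOTACP
training patients with three images each, 16/17 single-image test patients,
13 negative-class diagnosis subclusters, augmentation to 500/500. Images
are drawn hierarchically — class centroid → subcluster mean (negative class
only, sd 1.5) → patient mean (sd 1.0) → image (sd 1.0) — with the class
centroids `separation = 3.0` apart along a random direction. That
separation gives a linear-head test accuracy in the 70–85% range, i.e. an
imperfectly separable problem comparable to the clinical task; the
subcluster spread makes the negative class visibly heterogeneous and is the
reason NOTACP-side uncertainty dominates. Augmentation is resampling with
Gaussian jitter (sd 0.1) in embedding space, keeping source patient IDs.

What the synthetic data does *not* carry: any real imaging covariance
structure, class-conditional feature correlations, scanner or site effects,
or label noise. Passing tests therefore establish that the machinery is
correct and that its qualitative behaviour (abstention concentrates errors,
boundary cases spread wider) holds under a controlled generative model —
not that the clinical operating points transfer to real MRI. A subcluster
mixture with centroids in common between train and test is genuinely
learnable even at zero centroid separation, which is why "separation
controls separability" statements are evaluated with the subcluster spread
switched off.

## Numerical choices

- Batch-normalization ε = 1e−3; probabilities clipped at 1e−12 inside the
  cross-entropy; KS p-values floored at 1e−300.
- Dense weights init `0.01 · N(0,1)` from the training seed; zero init
  would be symmetric but the two-seed recipe needs distinguishable optima.
- SVD sign convention as above; subspace coordinates are exact round-trips
  (`project ∘ to_full = id`) to 1e−10.
- Degenerate inputs fail loudly: all-zero deviation matrices, empty splits,
  rank larger than the deviation row count, all-abstained metric requests.

## Scaled study profile

End-to-end behavioural claims are evaluated on a desk-scale profile —
16-d embeddings, 12/15 training + 10/11 test patients, augmentation to
120/class, 500 ESS draws, 20 replicate seeds — chosen so a full replicate
set runs in about a minute on one CPU while leaving every stage
non-trivial (the subspace still has 12 deviation rows for rank 5, the test
split still has both classes in double digits). `scripts/acceptance.py`
reports the quantities this profile computes.

## Known limitations

- The optimizer is an AdamW-style approximation of lazy adaptive moments;
  true lazy behaviour only differs when gradient rows vanish exactly.
- The asymptotic KS p-value ignores finite-sample corrections; with the
  pooled reference samples (thousands of points) the asymptotic regime is
  appropriate, but p-values at very small n are approximate.
- Curve fitting optimizes a one-sample stochastic estimate of the curve
  loss; the t-grid property checked in tests (fitted max-loss no worse than
  the straight segment) is a statistical, not pointwise, guarantee.
- The ESS posterior lives in a 2-d slice of an already low-rank subspace;
  it quantifies parameter uncertainty *along the connecting curve family*,
  not full posterior uncertainty.
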
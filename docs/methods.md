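# Methods

This document describes the algorithms implemented by `strainnet` in the
package's own terms: what each stage computes, which conventions it fixes,
and why. The worked pipeline that ties the stages together is in the
README.

## 1. Kinematics and conventions

An impact is a 3-degree-of-freedom head rotational-velocity time history
`ω(t) = (ωx, ωy, ωz)` in rad/s, sampled uniformly (non-uniform input is
linearly resampled to 1 ms). The anatomical frame is **x anterior, y left,
z superior**, so the head's mid-sagittal (left–right symmetry) plane has
its normal along y. Profiles longer than 200 ms are rejected because the
downstream encoding window is fixed at 201 samples.

The *resultant* is the per-sample Euclidean norm `|ω(t)|`; the *peak
resultant* is its maximum, with ties broken toward the earliest sample so
the peak index is deterministic. The *rotation axis at peak* is the unit
direction `û = ω(t_peak)/|ω(t_peak)|`, parameterised by azimuth θ
(degrees in (−180, 180], measured in the x–y plane from +x toward +y) and
elevation α (degrees in [−90, 90], from the x–y plane toward +z):
`û = (cos α cos θ, cos α sin θ, sin α)`.

## 2. Geometric data augmentation

Recorded impacts are scarce; rigid-body geometry generates physically
meaningful variants. One augmentation *batch* applies, per base impact:

1. **Component permutation.** The three channels are reordered in each of
   the 6 orderings `xyz, xzy, yxz, yzx, zxy, zyx` (in that fixed order).
   Each permutation is a distinct loading direction with an identical
   resultant history.
2. **Random rigid rotation.** Every sample vector is premultiplied by one
   rotation matrix: axis uniform on the unit sphere (normalised standard
   normals), angle uniform in [0°, 90°]. Orthogonality preserves the
   resultant at every sample.
3. **Conjugate-axis conversion (optional, default on).** If the
   post-rotation axis at peak leaves the sampled half-space |θ| ≤ 90°, the
   profile is replaced by its mid-sagittal mirror image. Because the head
   is approximately left–right symmetric, a mirrored rotation produces a
   mirrored strain field with identical scalar strain summaries, so the
   mirrored profile is an equally valid training sample whose axis
   `(180°−θ, −α)` lies back inside the half-space.
4. **Magnitude scaling.** All samples are multiplied by one scalar chosen
   so the peak resultant is uniform in the injury-relevant open band
   (21.9, 40) rad/s; the waveform shape is preserved exactly.

**Mirror rule.** Angular velocity is a pseudovector: reflecting the motion
through a plane negates the in-plane components of ω and keeps the normal
component. For the mid-sagittal plane (normal +y) this gives
`(ωx, ωy, ωz) → (−ωx, ωy, −ωz)`. Under the angle convention above this
maps the peak axis (θ, α) to exactly (180°−θ, −α), which is how the
conjugate-axis formula and the mirror rule pin down the coordinate
convention jointly. The map is an involution, and
`axis_at_peak ∘ mirror ≡ conjugate ∘ axis_at_peak` is enforced by test.

`augment_dataset` produces `len(profiles) × 6 × n_batches` outputs with a
provenance record (parent id, permutation, rotation axis/angle, mirrored
flag, scale factor) per output, fully reproducible from one seed.

## 3. Input encoding

Each profile becomes a 3×201 matrix at 1 ms resolution (0–200 ms). All
three channels are shifted synchronously so the *resultant* peak lands at
index 100; inter-channel timing is untouched. The borders are filled by
replicating each channel's first/last sample, so the first difference
(acceleration) is exactly zero inside both pad regions. A profile whose
peak placement would push real samples outside the window is rejected
rather than truncated. Inputs are fed raw (rad/s), with no normalisation.

## 4. Network architecture

`CNNSpec` fixes the stack: three valid (un-padded) convolutions of 32
filters each — kernels 3×10, 1×10, 1×5 with strides 1×2, 1×2, 1×1 — then
flatten, dropout 0.2, a dense layer of 64 units and a dense output of
width 1. ReLU follows every layer *including the output*, since strains
are non-negative. Valid padding makes the first kernel collapse the
3-channel axis in one layer; the feature-map widths are 96, 44, 40
(`floor((W−k)/s)+1` from W=201) and the flattened width is 1×40×32 = 1280.
The parameter count is asserted against this arithmetic in tests.

The layers are implemented directly on NumPy (im2col convolution, manual
reverse-mode gradients, inverted dropout, Adam). The backward pass is
verified end-to-end against central finite differences in float64.

## 5. Training regime

`TrainingConfig` fixes: mean-squared-error loss, Adam (β₁=0.9, β₂=0.999),
learning rate 1e-6, 250 epochs, batch size 64, a 10% validation split and
validation-based early stopping (patience 25, best weights restored). One
independent model is trained per strain measure.

The learning rate, epoch and batch budget are deliberately small, which
makes initialisation the decisive design choice: Adam's per-weight step is
bounded by the learning rate, so across 250 epochs each weight can move
only a few thousandths in total. The packaged initialisation puts the
network into a regime where that budget is spent productively:

* **Labels are standardised internally** (divided by the training-split
  standard deviation) and the scale is folded back into the output layer
  after training — exact, because `relu(z)·c = relu(z·c)` for c > 0.
* **Hidden dense weights start near zero** (Glorot × 7e-6) with a
  **positive bias** (0.5). Flattened conv features are non-negative, so
  with zero-mean weights each hidden unit's pre-activation drifts with a
  single sign per update and units can be driven irreversibly below zero
  early in training; starting them inside the active region with nothing
  to unlearn keeps every unit alive and effectively linear.
* **The output layer is amplified** (Glorot × 120) and its bias is centred
  on the mean standardised label, so useful gradient signal reaches the
  lower layers from the first step and the rectified output starts active.

Convolution weights use plain Glorot initialisation. All of this lives in
`CNNSpec`/`TrainingConfig` defaults and can be overridden per run.

## 6. Synthetic impacts and strain oracle

Real impact recordings and finite-element strain labels are not shipped;
a generator and a closed-form oracle stand in so the pipeline is testable
end to end. No biofidelity is claimed.

**Generator.** Each impact is a raised-sine-squared resultant pulse
`A·sin²(πt/T_d)` on [0, T_d] along a random unit direction (duration
10–60 ms, peak 5–40 rad/s), optionally followed by a reversed pulse of
fraction 0.4 of the amplitude (probability 0.3), sampled at 1 ms.

**Oracle.** For measure m with peak resultant p, unit peak direction û and
resultant total variation TV:

    ε = eps_max(m) · H(p) · D(û) · S
    H(p) = p³ / (p³ + 30³)                      (saturating severity)
    D(û) = (1 + aₓuₓ² + a_y u_y² + a_z u_z²) / (1 + max a)   (direction)
    S    = 1 + 0.3 · min(1, TV / 2p)            (waveform complexity)

with `eps_max` = 0.45 / 0.35 / 0.25 and distinct direction weights per
measure, optional seeded Gaussian noise, clamped at zero. D depends only
on *even* powers of û, so the noiseless oracle is exactly invariant under
mid-sagittal mirroring — the property the conjugate-axis step relies on —
and H·S is nondecreasing under uniform magnitude scaling. Labels are
recomputed *after* augmentation (rotation and rescaling change the
oracle's inputs), mimicking per-impact re-simulation.

## 7. Evaluation protocol

* **Metrics.** `R² = 1 − SS_res/SS_tot` (SS_tot about the truth mean) and
  RMSE, both also reported on the *within-range* subset whose peak
  resultant lies strictly inside (21.9, 40) rad/s.
* **Cross-validation.** Per trial: shuffle with the trial seed, split into
  k = 10 folds, train on k−1 and predict the held-out fold, then pool all
  held-out predictions and compute one pooled R²/RMSE per trial. Repeated
  trials differ only in seed.
* **Corrected resampled t-test.** Repeated-CV scores are positively
  correlated through shared training data, so the naive paired t-test
  over-rejects. The corrected statistic inflates the variance:
  `t = d̄ / sqrt(s_d² (1/n + ρ))` with ρ = 1/(k−1) (the test/train size
  ratio) and n−1 degrees of freedom, one-tailed. A simulated correlated
  null in the test suite confirms the naive test over-rejects while the
  corrected test stays near the nominal 0.05.
* **Welch's one-tailed t-test** (Welch–Satterthwaite degrees of freedom)
  for unpaired comparisons with unequal variances. Significance level
  0.05 throughout.
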
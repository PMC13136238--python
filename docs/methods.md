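# Methods

## The problem and the model

Diffuse liver-fibrosis nodules in B-mode ultrasound are hard to segment for
three compounding reasons: their margins are gradual rather than capsular, so
there is no clean acoustic interface; their echotexture overlaps the
surrounding parenchyma in grayscale; and conventional softmax networks report
overconfident point probabilities exactly where the image is most ambiguous.
`espdnet` implements an encoder-decoder that treats the per-pixel class
probability as a random variable with a Dirichlet prior and uses the implied
epistemic uncertainty as an internal control signal, not just a diagnostic
output.

The network has four cooperating parts.

**Hybrid-attention encoder.** Four stages at strides 2/4/8/16. Each stage is
two 3x3 convolutions with group normalization (batch-independent, stable at
batch size 4) and ReLU, then attention, then 2x2 mean-pool downsampling.
Stages 0-1 use squeeze-and-excitation channel gates (cheap, suited to
low-level texture); stages 2-3 use CBAM channel + spatial attention for
semantic context. Skip features are taken after attention. An
`identity_gates` switch forces all gates to exactly 1, reducing the encoder
to a plain convolutional downsampler (the ablation anchor used in tests).

**Dual-path bottleneck (SPDF).** The stride-8 features pass through a stack
of deformable convolutions (offsets predicted per location, zero-initialized,
so the path starts as an ordinary convolution); the stride-16 features pass
through window-based self-attention (non-overlapping W x W windows, W = 4,
cost O(N W^2) instead of O(N^2)) and are upsampled back to stride 8. The
per-location variance across channels of the attention output is projected by
a learnable 1x1 affine to a single-channel probabilistic attention map — the
affine learns the polarity, since the direction of "variance means
(un)certainty" is not fixed a priori. Semantic features are modulated as
`F_sem * (1 + alpha * sigmoid(A_prob))` with `alpha` learnable from 0, so the
multiplier lives in [1, 1+alpha] and enhancement never suppresses below
identity. A pointwise FFN over the concatenated paths plus a 1x1 residual
projection of the input yields the bottleneck output; with `alpha = 0` and
zero FFN weights the block is exactly a residual pass-through.

**Evidential decoder (DEGD).** At each of four decoder scales an evidence
head emits two logits mapped to Dirichlet concentrations
`alpha_k = 1 + softplus(logit_k)`. This activation guarantees `alpha_k >= 1`,
hence total evidence `S >= K`, uncertainty `U = K/S` in (0, 1] (U = 1 iff
all alpha are 1), and smooth gradients; exponential alternatives are
explosive at small batch sizes. Expected probabilities are the Dirichlet
mean `p_k = alpha_k / S`, so the coarse mask (final-scale foreground `p`
upsampled to the input grid) is consistent with the uncertainty map by
construction. Encoder skips are modulated by `F * (1 + alpha * A_Dir)`
followed by 1x1 channel reduction; `A_Dir` comes from single-head
cross-attention (queries from the evidential probability mask, keys/values
from the bottleneck semantics and the fused edge map) at the two coarsest
modulated scales, and from a cheap gated MLP over
`[Q_pred, K_conf = 1 - U, V_evidence]` at the finest scale, whose
zero-initialized output starts the gate at sigmoid(0) = 0.5. Per-scale
uncertainty maps (strides 16/8/4/2) are exported for inspection.

**Boundary refiner (DBAR).** Sobel gradient magnitude of the raw image
(3x3 kernels, reflect padding, normalized per image by its maximum so the map
is contrast-invariant) is fused with a learnable semantic-edge head by
`sigmoid(w1 * E_sobel + w2 * E_sem + b)`. The semantic edges are computed
from the bottleneck output rather than from decoder features: the decoder
itself consumes the fused edge map, and sourcing edges upstream avoids a
circular dependency. Boundary attention is a conv stack over
`[U, 1 - 2|M - 0.5|, E_boundary]`; the refinement is the gated residual
`M <- clamp(M + A * dM, 0, 1)` applied twice, with `A` recomputed each
iteration so the gate tracks the evolving ambiguity band, `dM` bounded by
`0.5 * tanh` (the tempering keeps refined values from saturating
immediately; an amplitude of 0.25 destabilizes training outright), and
residual weights shared across iterations. Where `A = 0` the coarse mask
passes through bit-exactly. The clamp uses a straight-through gradient:
with a zero-outside gradient the network can lock into an all-background
state early in training and never recover.

## Losses

The region loss is `a*Dice + b*Focal + g*Boundary` with a = b = 1,
g = 0.5. Dice is the soft form with eps = 1 pooled over the batch
(per-sample averaging trained measurably worse at desk scale). Focal uses
gamma = 2, alpha_f = 0.25 with predictions clipped at 1e-7. The boundary
term is `mean(pred * phi)` with `phi` the signed Euclidean distance to the
mask contour (negative inside, zero on the contour pixels, positive
outside); during training `phi` is divided by the image diagonal so the term
is scale-free and commensurate with the O(1) Dice/Focal terms — unnormalized
it dominates the gradient and collapses training to all-background. An
empty target has no contour; the documented fallback is
`mean(pred) * D_max`.

The evidential loss is the expected cross-entropy under the Dirichlet,
`mean_pixels sum_k y_k [psi(S) - psi(alpha_k)]` (digamma psi), applied to
the final decoder scale against the nearest-downsampled target. It is
non-negative, decreases when true-class evidence grows and increases when
wrong-class evidence grows (asserted by finite differences). The total is
`liver + lambda(epoch) * w_EDL * EDL` with `w_EDL = 1` and `lambda` ramping
linearly over the first ~10% of epochs; the ramp prevents early evidence
collapse. An optional KL-to-uniform regularizer exists but defaults off.

## Training protocol

AdamW (decoupled weight decay 1e-5), batch size 4, ReduceLROnPlateau on
validation Dice (patience 5, factor 0.5), early stopping (patience 20),
best-model selection by validation Dice. Augmentation applies synchronized
geometric transforms (horizontal flip p = 0.5, rotation +/-15 deg, scale
+/-10%; nearest-neighbour for masks so they stay binary) and image-only
pixel transforms (brightness/contrast +/-20%, Gaussian noise). One master
seed drives phantom generation, shuffling, augmentation and initialization;
two runs with the same seed produce identical training logs. The full-scale
profile is 320 x 320 with encoder widths 32/64/128/256 and learning rate
1e-4; the desk-scale (tiny) profile is 64 x 64 with widths 8/16/32/64 and
learning rate 2e-3 — the narrow widths and larger rate are what a 14-epoch
schedule on a single CPU supports, and all reported desk-scale results use
them.

The whole network stack — reverse-mode autodiff, im2col convolution,
deformable bilinear sampling, windowed and cross attention, AdamW — is a
compact NumPy core (`espdnet.nn`), written for exact reproducibility and
small-problem efficiency.

## The phantom generator

The generator emulates the statistical regime of the target data rather than
acoustic physics: single-channel speckle images in [0, 1] with nodules
occupying 3-8% of the field, gradual margins, substantial grayscale overlap,
and four morphologies (cord-like fragments, dispersed small particles,
closely packed dense clusters with a guaranteed >= 1 px gap so connected
components equal the drawn nodule count, and fusiform spindles at half
contrast). Speckle is a multiplicative gamma field (mean 1, shape 25)
smoothed with sigma = 0.8 px so the grain has realistic spatial correlation;
gradual boundaries come from Gaussian-blurring the clean intensity field
(sigma = 2 px at the native 320 x 320 scale, scaled proportionally at
smaller sizes, exactly as resizing a real image would shrink transition
widths); optional acoustic shadows (probability 0.2) multiply a soft
vertical band by 0.5. Foreground fraction is enforced by rejection sampling
with a geometric rescaling fallback and errors out after 100 attempts.

Difficulty was calibrated against the performance band the method's field
reports on comparable real data (weak baselines around 0.61 Dice, strong
models around 0.85): with the chosen defaults, an idealized intensity
oracle (per-sample tuned smoothing + threshold) reaches ~0.66 Dice at
64 x 64 and the trained desk-scale models land at 0.72-0.79 — inside that
band. What the phantoms do not contain: real anatomy, depth-dependent
attenuation, operator variability, annotation noise. Passing desk-scale
tests therefore demonstrates that the implementation learns and that its
components behave as designed, not clinical performance.

## Desk-scale study and what it shows

The benchmark (`espdnet.experiments`) trains the evidential network and a
softmax baseline (same encoder/decoder, plain softmax head, Dice + Focal
loss, no bottleneck fusion or refinement) on 200 phantoms at 64 x 64 with a
7:1:2 split, 14 epochs, three seeds. Observed: validation Dice 0.76-0.79
(baseline 0.72-0.73), with the Dice advantage of the evidential model
reaching significance in the paired permutation test on some seeds;
uncertainty-error correlation +0.31 to +0.36.

Two directional claims do not reproduce at this scale and are reported as
honest negative results rather than adjusted away.

*Calibration ordering.* The evidential model's expected calibration error
(2.0-2.4%) is slightly worse than the softmax baseline's (1.6-1.8%). Both
are far better calibrated than the double-digit softmax ECE reported at
full scale; a 14-epoch Dice+Focal baseline never develops the saturation
pathology that evidential modeling corrects, while the boundary refiner
necessarily pushes refined probabilities toward {0, 1}, so the evidential
model's ECE reduces to its pixel error rate.

*HD95 ordering.* Whether refinement lowers the mean HD95 relative to the
coarse output is a coin flip at desk scale: per sample the refiner wins
about 18 of 40 comparisons, loses 13 and ties 9, but the mean is dominated
by one or two outlier samples in which refinement lifts a borderline
distant false positive over the 0.5 threshold (+9 to +17 px on that
sample's HD95). The measured sign of the seed-majority comparison has
flipped under floating-point-level code changes. The large full-scale
HD95 reduction evidently needs the full-scale regime — more training, more
resolution, and uncertainty maps sharp enough to gate distant artifacts.

## Numerical conventions

* HD95/ASSD: boundary pixels are mask minus its 8-connectivity erosion
  (outside-of-image treated as foreground, so a mask touching the border
  contributes only its interior-facing contour); distances are exact
  nearest-neighbour Euclidean; HD95 is the 95th percentile (linear
  interpolation) of the *pooled* symmetric directed-distance multiset —
  some tools take the maximum of per-direction percentiles instead.
  Empty masks return the image diagonal as a documented sentinel.
* Boundary-F1 tolerance defaults to 2 px.
* ECE uses 10 equal-width right-closed bins on [0, 1]; confidence is
  `max(p_fg, 1 - p_fg)` of the refined mask (for the baseline, of the
  softmax output).
* UEC is the point-biserial Pearson correlation between per-pixel
  uncertainty and the 0/1 error indicator, pooled over the split; constant
  inputs return 0 with a degenerate flag. This is an interpretation — the
  field uses the name without a formula.
* The paired permutation test flips signs of paired differences, statistic
  |mean difference|, exhaustive when 2^n fits the resample budget, with the
  +1 correction otherwise.
* All mask metrics binarize at 0.5.

## Known limitations

* No pretrained weights and no GPU path; the full 320 x 320 profile is
  functional but slow on a single CPU.
* K = 2 throughout; the code parameterizes the class count but only the
  binary case is exercised.
* The cross-attention wiring of the evidential decoder follows one reading
  of the method's prose (queries from the evidential mask, keys/values from
  bottleneck semantics and edges); other readings exist.
* Deep supervision of the per-scale uncertainty maps is available behind a
  flag but off by default; it showed no benefit at desk scale.
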
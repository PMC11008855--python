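# Methods

This note records the models implemented by `hybridpath`, the defaults and
why they were chosen, what the synthetic fixtures do and do not emulate, and
the numerical decisions made where the design was genuinely open.

## Impulse-noise filter (ASMDBUTMF)

The detector is value-based: a pixel is noisy iff it equals 0 or 255. This
cannot distinguish true black/white content from corruption; such pixels are
restored like noise (restored values are clamped to [1, 254] so the detector
never re-flags a restored site). Restoration runs in raster order and later
windows see earlier restorations, the convention of decision-based filters —
at high density this is what lets information propagate across large noise
patches.

Case analysis per flagged pixel, with C the count of non-noisy pixels (NNPs)
among the eight 3×3 neighbors:

- **C = 0**: expand to 5×5, 7×7, 9×9; the first window containing any NNP
  contributes the **median** of its NNPs (the median, not the mean, keeps
  the filter in the trimmed-median family). If even the 9×9 window is all
  noise, the global median of previously restored values is used (127 when
  nothing has been restored yet — the midpoint of the valid range).
- **C ∈ [3, 8]**: trimmed median of the 3×3 NNPs.
- **C ∈ {1, 2}**: α, β are the two smallest 3×3 NNPs; consult the 5×5
  window with count C₅: C₅ > 3 → mean of the 5×5 NNPs; C₅ = 3 → their
  median (this count is not covered by the α/β rules and routing it to the
  median is the least-surprising completion); C₅ = 2 → (α+β)/2, with β
  taken from the 5×5 NNPs when only one 3×3 NNP exists; C₅ = 1 → α.

Boundaries are handled by symmetric reflection. Medians of even-sized sets
round half-up to the nearest integer. RGB tiles are filtered per channel.
The inner loop is numba-compiled; a pure-Python reference path
(`restore_pixel`) implements the identical case logic and the tests assert
agreement between the two.

## Thresholding-based level set

The two competing weights are initialized at the image's 25th/75th
percentiles (falling back to min/max for two-valued images). One epoch is
one raster pass; three epochs are the default — with learning rates of order
(256 − px)/256 the weights effectively track their modes within a single
pass. A pixel equidistant from both weights updates **both**; this is the
only tie rule under which a constant image pulls both weights (and hence the
threshold) onto its value rather than stranding the farther weight.

The evolution equation combines distance regularization (weight μ = 0.2)
with an edge-weighted length flow (λ = 5, Dirac width ε = 1.5 px, time step
dt = 0.1, with dt·μ < 0.25 enforced). The energy's external term is
implemented as the standard edge-weighted contour length, whose gradient
flow is λ δ_ε(φ) div(ed ∇φ/|∇φ|); an optional balloon/area term exists but
is off by default. Because the edge indicator is computed on the image
scaled to [0, 1], unit-range gradients are small and ed stays close to 1
even at tissue boundaries; the length term is therefore net-shrinking, and
long evolutions erode small objects. The default of **40 iterations** is
where the flow has smoothed the thresholded initialization without eroding
nuclei at the phantom scale (radius ≈ 7–10 px); on the disk phantom the
median Dice is ≥ 0.99 and mean |∇φ| stays within [0.8, 1.2] throughout.
φ < 0 denotes the object interior.

## 33-feature morphometry

Only family counts (11 geometric, 8 directional, 14 intensity) and exemplar
members are fixed by the problem; the full inventory here is our
enumeration of standard morphometrics (see `FEATURE_NAMES`). Geometric
descriptors are aggregated over 8-connected components via
`skimage.measure.regionprops`; perimeter uses scikit-image's weighted
boundary approximation, under which a digital disk's roundness 4πA/P² falls
within [0.85, 1.1]. Directional features ray-march from each component's
centroid along the eight compass directions (0.25 px steps) and average
over components of ≥ 10 px (all components when none qualify). Intensity
statistics are computed over object pixels of the grayscale image
(Rec. 601 luminance for RGB), with skewness/kurtosis defined as 0 for
constant regions and Shannon entropy on a 256-bin histogram.

## Hybrid metaheuristic (CSCO-ROA)

Both families minimize over a box with clipping. The sand-cat rule uses the
linear sensitivity schedule rG: 2 → 0, transition variable R = 2·rG·rand −
rG (|R| ≤ 1 ⇒ exploitation toward the best position modulated by cos θ, θ ~
U[0°, 360°)), and the logistic chaotic stream μ ← 4μ(1−μ) in place of the
uniform draw of the sensitivity product (seed 0.7; seeds in
{0, ¼, ½, ¾, 1} are rejected since they collapse the orbit). The remora
rule proposes a sailfish lunge R_best − (rand·(R_best − R_rand)/2 − R_rand),
probes a small "experience attack" step accepted greedily, and otherwise
exploits via a fair coin between the whale log-spiral around the best and
host-feeding steps with amplitude S = 2(1 − t/T) (remora factor A = 0.01).
The printed form of the lunge admits two parenthesizations; the one used
satisfies the identity rand = 0 ⇒ R_best + R_rand.

The hybridization schedule is this package's design: it routes **each
agent each iteration** by the chaotic coin
(μ < 0.5 → sand-cat update, else remora), so both operator sets act every
iteration on a mixed population without extra parameters. Exploration draws
are per-dimension vectors; branch selectors are scalars. Once per iteration
the worst agent is replaced (toward the best with probability ½, else
uniformly resampled), and the best-so-far is tracked elitistically, making
the trace non-increasing by construction.

## Wrapper feature selection

Continuous positions in [−4, 4]³³ map to bits through a sigmoid transfer
with stochastic thresholding (a v-shaped |tanh| variant is available);
all-zero draws are repaired to the single most probable bit. The transfer's
random draw is derived from a CRC of the position bytes and the run seed, so
the objective is a pure function and runs are exactly reproducible. The
wrapper classifier is 5-NN with 3-fold stratified CV — chosen for speed and
determinism; the CVAE is reserved for final evaluation. The fitness weight
α = 0.99 follows common wrapper practice of prioritizing error over subset
size; both are exposed in `FSConfig`.

## Conditional VAE

Encoder 33 → 64 → 32 → (μ, log σ²) with latent dimension 8; decoder
z → 32 → (concat 2-dim one-hot label) → 64 → 33. Hidden activations are
ReLU; the encoder heads are linear and the decoder output is a sigmoid,
pairing with the Bernoulli reconstruction likelihood of min-max scaled
features. The label is injected only in the decoder (the encoder is
unconditioned). Training is minibatch SGD with momentum 0.9, batch 32,
learning rate 0.01, 200 epochs by default, with reparameterized sampling
z = μ + σ·ε; gradients are hand-derived and verified against central
finite differences in the test suite. Log-variances are clipped to ±20 for
numerical safety.

The classification rule — score each candidate label by the conditional
ELBO with z fixed at the posterior mean and return the argmin — is this
package's decision; it needs one deterministic pass per label and exploits
the fact that only the decoder sees the label. Layer sizes and the
hyperparameter-tuning search space (log₁₀ learning rate, z, h1, h2 boxes,
optimized by the hybrid metaheuristic in a unit box mapped affinely so
singleton ranges are legal) are defaults of this implementation.

## Metrics

All ten confusion-matrix formulas are implemented directly from counts with
malignant as the positive class. Ratios with zero denominators are NaN with
a warning and are excluded from fold averages (the per-metric count of
defined folds is reported). Cross-validation folds are stratified with a
seeded shuffle — stratification is not strictly implied by plain k-fold but
prevents degenerate folds at the sample sizes used here — and averages are
unweighted fold means. AUC uses the rank (Mann–Whitney) formulation with
tie averaging. PSNR uses MAX = 255 and reports a 100 dB cap for identical
images; Dice of two empty masks is 1.

## Synthetic fixtures: what they do and do not show

Phantoms are anti-aliased bright ellipses (nuclei) on a dark Gaussian-
textured background, placed by rejection sampling so footprints never touch;
class difference enters through radius mean/spread, eccentricity range and
intensity spread (malignant: larger, more variable). Intensities stay in
[1, 254] so no clean pixel collides with the impulse extremes. The feature
tables plant a known informative subset with a fixed mean shift. These
stands-ins make every contract testable offline, but they lack stain
variability, texture, touching nuclei, and class overlap of real
histopathology — passing tests demonstrate the correctness of the
algorithms and the recoverability of planted structure, not clinical
performance. Augmentation is original + 90° rotation + horizontal mirror
(factor 3); the multiplicity is this package's reading of "rotation and
flipping" augmentation.

Default study sizes (10 seeds per density for the denoiser sweep at
256×256, 10 seeds for disk segmentation, 10 optimizer/selection seeds,
1000-sample CVAE datasets, 40-phantom end-to-end runs) were chosen to give
stable medians from seeded simulations.

## Known limitations

- The value-based noise detector misclassifies true 0/255 content.
- The weak unit-scale edge indicator makes very long level-set evolutions
  erode small objects (see above); choose `iters` relative to object scale.
- The exact 33-feature inventory is an enumeration satisfying the family
  counts, not a published list; selected-feature counts on real data are
  therefore not comparable feature-by-feature.
- Wrapper selection on small n with strongly separable classes may return
  very small subsets (a single feature can already achieve zero CV error).
- The CVAE's conditional-ELBO rule relies on the decoder using the label;
  with an over-expressive latent space the label path can be bypassed
  (posterior collapse of the label signal). The small default latent
  dimension avoids this in practice.
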
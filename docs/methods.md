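# Methods

## Problem

Surface-enhanced Raman spectroscopy (SERS) can detect perfluorooctanesulfonic
acid (PFOS) in water at sub-ppb levels, but a measured spectrum is a mixture:
the PFOS signature sits on top of the substrate's own background (a broad
continuum plus substrate bands) and shot noise, and at trace concentrations
the analyte lines are faint. Two PFOS marker lines matter throughout:
P1 at 997 cm^-1 (C–C stretch) and P2 at 1,044 cm^-1 (S–O3 stretch). P2 is
the quantitation anchor because the blank substrate has no band there — the
identifiability assumption on which both the ground-truth procedure and the
calibration analysis rest.

The package does three things:

1. simulates realistic PFOS/background/noise mixtures and assembles seeded
   train/validation/test datasets;
2. trains 1-D encoder–decoder networks (UNet, ResNet UNet, Trans UNet) to
   map a noisy mixture spectrum to its clean PFOS component
   ("demultiplexing" plus SNR enhancement in one step);
3. evaluates recovery with zero-lag cross-correlation and mean absolute
   error, and reproduces the serial-dilution P1/P2 calibration analysis.

## Mixture model

All spectra live on a uniform grid, by default 400–1,800 cm^-1 with 896
points (the networks require a fixed input length of 896; the range is a
typical 785 nm Raman window bracketing both marker lines).

A simulated mixture is

    M = K1·BKG + K2·PFOS + K3·GN,      truth = K2·PFOS

with K1, K2 ~ U(0.5, 5), K3 = max(K1·BKG + K2·PFOS) × U(0.01, 1), and GN
zero-mean unit-variance white Gaussian noise on the grid. Unit variance
makes K3 the literal noise amplitude, consistent with deriving it from the
peak intensity of the noiseless mixture. Note the noise is severe: in the
worst draws its amplitude equals the mixture's maximum.

Experimental-like records emulate measured PFOS-on-SERS spectra across a
serial dilution (5, 0.5, 0.05, 0.005, 0.0005 ppb):

    S = enh(c)·jitter · PFOS + atten·BKG + ε,

where `enh(c)` is a non-monotone enhancement profile peaking at 0.05 ppb
(0.8, 1.2, 2.0, 0.9, 0.35 from high to low concentration; SERS enhancement
saturates and then degrades at high surface coverage), `jitter` is ~15 %
lognormal spot-to-spot variation, `atten ~ U(0.4, 0.9)`, and ε is white
noise with σ = 2 % of the clean maximum. Augmentation doubles the pool:
C1·S + C2·noise with C1 ~ U(0.5, 5) and C2 = max(C1·S) × U(0.01, 1) (the
same laws as K1/K3; the original description leaves the ranges open, and
mirroring the simulator is the least surprising choice). Drawn (C1, C2)
pairs are logged and exact collisions rejected, so no pair repeats within
one dataset build.

Dataset arithmetic (defaults): 1,080/120/30 simulated spectra; 630
experimental-like base spectra (126 per concentration), 30 reserved for
test, the remaining 600 augmented once each into a pool of 1,200 split
1,080/120; merged totals 2,160/240/60, half simulated and half
experimental-like in every split. A single integer seed drives every draw.

### Synthetic components

The PFOS reference is a deterministic sum of Lorentzian lines: the two
markers (997 cm^-1, amplitude 0.55; 1,044 cm^-1, amplitude 1.0 — dominant)
plus six minor lines. The substrate background is a smooth decaying
continuum plus seven broad Gaussian bands, none within ±15 cm^-1 of
1,044 cm^-1 (the generator refuses a configuration that violates this).
The bands are Gaussian rather than Lorentzian deliberately: Gaussian tails
decay fast enough that no background intensity leaks under the P2 anchor,
which keeps the anchor-ratio procedure well-conditioned; a Lorentzian band
at 1,098 cm^-1 would contribute ~2 % at 1,044 cm^-1 and bias low-ratio
estimates by ~10 %.

What the generator does **not** emulate: instrument line-shape convolution,
wavenumber miscalibration, cosmic-ray spikes, correlated (pink) noise, or
chemical matrix effects. Tests passing on this generator therefore show
that the pipeline is correct and the networks can learn the separation
task, not that the trained weights transfer to any particular instrument.

## Ground-truth procedure

A measured PFOS-on-SERS spectrum has no observable clean component, so its
training target is estimated in three steps: (1) remove the baselines of
both the on-SERS spectrum and the powder reference with the same smoother
and parameters; (2) ratio their peak intensities at the 1,044 cm^-1 anchor;
(3) scale the baseline-removed powder reference by that ratio. Step 3 uses
the baseline-removed (not raw) powder signal — the only reading consistent
with step 1 putting both spectra at the same baseline level. Peak
intensities are windowed maxima (±10 cm^-1) rather than single-bin values,
tolerating grid jitter and the apex falling between samples.

Baseline removal is asymmetric least squares (a Whittaker smoother with
asymmetric weights): smoothness λ = 1e5, asymmetry p = 0.001, 10
iterations. p = 0.001 (rather than the more common 0.01) keeps the
baseline from climbing into broad peak pedestals; with these defaults the
procedure recovers a known mixing ratio r ∈ {0.1, 0.7, 1.5} within 2 % on
the synthetic construction r·powder + background. λ is grid-resolution
dependent (the penalty acts on index-wise second differences); the default
is tuned for ~1.5 cm^-1 sampling.

## Architectures

All three networks map a length-896 single-channel spectrum in [-1, 1] to
an output of the same shape through a Tanh, with a four-level
encoder–decoder: each encoder level is a double conv(kernel 3, stride 1,
padding 1)–PReLU block followed by max-pooling (kernel 2), giving the
length trace 896 → 448 → 224 → 112 → 56; the decoder mirrors it with
transposed-convolution upsampling (kernel = stride = 2) and concatenated
encoder skips. Channel widths double per level from `base_channels`
(default 32: 32/64/128/256, bottleneck 512).

* **UNet**: plain double-conv blocks.
* **ResNet UNet**: the same blocks with an additive shortcut (identity, or
  1×1 conv when the channel count changes).
* **Trans UNet**: the ResNet UNet plus a transformer branch on the raw
  input — patch embedding (patch length 16 → 56 patches, matching the
  bottleneck length), learnable position embeddings, then L pre-norm
  residual layers of multi-head self-attention and a GELU MLP (defaults:
  embed 128, 4 heads, L = 4). The branch output is linearly projected to
  the bottleneck channel count and element-wise multiplied with the
  bottleneck activation.

Initialisation choices that matter on CPU-sized models: residual-branch
convolutions are damped (×0.1) so stacking blocks preserves activation
variance; the output head is damped ×0.5 so the initial pre-Tanh output is
not saturated (a saturated Tanh at initialisation stalls training almost
completely, which we observed directly); and the transformer projection
bias starts at 1 so the multiplicative fusion is identity-like at first
("open gate") and the convolutional path trains unimpeded.

The networks, backpropagation and Adam live in a compact numpy engine
(`sersdemux.nn`): channel-first tensors, one channel-mixing matmul per
kernel tap instead of im2col, and hand-written adjoints for every layer,
each verified against central-difference gradients in the test suite.

## Training and evaluation

Adam (lr 1e-4, β = 0.9/0.999), batch size 8, mean absolute error between
output and target, 50 epochs by default. MAE is computed over all points
of all spectra in a batch — with a fixed length of 896 this equals the
mean over spectra of per-spectrum MAE, the only scale-consistent reading.
Both the mixture and its target are normalized by the *mixture's* min–max
affine map onto [-1, 1], so each pair shares one scale and normalized MAE
is meaningful. Shuffling, initialisation and batching derive from one
seed; with a validation set the parameters of the best-validation-MAE
epoch are restored at the end (pure engineering; it does not extend the
epoch budget).

Evaluation reports per-record zero-lag cross-correlation (a Pearson-type
coefficient: affine-invariant, in [-1, 1], undefined — and refused — for
zero-variance inputs) and MAE in normalized units, aggregated as
mean ± sample standard deviation (ddof = 1; reported convention stated in
the output). Records whose normalized target has zero variance are
excluded with a logged warning and counted.

A useful reference point computed in the tests: ordinary least squares of
the raw mixture onto the two known component templates achieves mean test
MAE below 0.01 and mean cross-correlation above 0.99 in normalized units —
the linear floor a converged network should approach.

## Desk-scale problem sizes

The package's defaults (base 32 channels, embed 128, 50 epochs) match the
reference recipe. The acceptance computation and the comparison test run a
deliberately narrow configuration — base 8 channels, embed 32, L = 2,
trained for 30 epochs (single model) or 12 epochs (three-model
comparison) on the full 2,160-spectrum training split — chosen as the
package's own desk-scale operating point for a single CPU. The narrow
models are ~0.2 M parameters instead of ~3.5 M. At these budgets the
metrics are still improving when training stops: desk-scale results
characterise the pipeline and the relative ranking of the architectures,
not the converged performance of the approach (the training histories the
scripts print show the remaining slope).

## Calibration analysis

For each concentration the replicate spectra are averaged point-wise
(averaging before baseline removal, matching the stated acquisition order),
the mean spectrum is baseline-corrected, and the net peak heights at P1 and
P2 are ratioed. Net height = windowed apex minus the local background level
(median of a ±70 cm^-1 annulus excluding ±15 cm^-1 around both markers), so
any small offset the smoother leaves cancels out of the ratio — this makes
the ratio invariant when both peaks co-scale, which is the property the
ratio exists to provide. A concentration whose net P2 height is below
k·σ_noise (default k = 3, σ estimated robustly from the median absolute
deviation of first differences) is flagged below-detection and yields no
ratio rather than a spurious one. The package deliberately stops at the
flag: fitting a calibration model or estimating a physical limit of
detection is out of scope.

## Known limitations

* The numpy engine is single-threaded and CPU-bound; it is sized for
  hundreds of thousands of parameters, not millions.
* MAE-trained models underestimate peak amplitudes early in training
  (median-seeking behavior under target uncertainty); cross-correlation
  converges before MAE does.
* The AsLS λ default assumes ~1.5 cm^-1 sampling; very coarse grids need a
  smaller λ.
* `remove_baseline` leaves a small positive offset on pure-baseline input
  near the spectrum edges (second-difference penalty boundary effect).
* The below-detection rule is a statistical convention (3σ), not a
  physical detection-limit claim.
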
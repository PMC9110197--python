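# Methods

## Model

The segmentation network is a pair of parallel U-Nets over 50×50 grayscale
crops. UNet_A owns two encoders — one for the fused PET/CT image, one for
PET — with channel schedule 16, 32, 64, 128, 256; their bottleneck features
are summed and decoded by a single expanding path (128, 64, 32, 16).
UNet_B is a plain encoder/decoder on CT with twice the width (32…512 /
256…32). Every stage is two rounds of (3×3 convolution, batch
normalization, ReLU); downsampling is non-overlapping 2×2 max pooling with
floor semantics, giving the spatial ladder 50→25→12→6→3; upsampling is a
2×2 stride-2 transpose convolution, with one unit of output padding at the
12→25 stage so the decoder exactly mirrors the encoder sizes.

Three learned gates modulate the information flow:

* **Two-modal fusion** (UNet_A, per scale): the PET and PET/CT features are
  concatenated (2C channels) and multiplied elementwise by
  `σ(Conv3×3(ReLU(Conv1×1(·))))` of themselves. The gate has full 2C×H×W
  resolution. An alternative form in which the second convolution is also
  1×1 is available via `ModelSpec.block_options.gate_variant`.
* **Hybrid attention** (skip connections, per scale): channel attention then
  spatial attention over the concatenation of the fused UNet_A features and
  the UNet_B features, each in residual form `x + x⊙gate`. The channel gate
  comes from a shared two-layer MLP (hidden width ⌊C/3⌋, bias-free, ReLU)
  applied to global average- and max-pooled descriptors and summed before
  the sigmoid; the spatial gate from a 3×3 convolution of the channelwise
  mean and max maps. The composition order is configurable
  (`attention_order`, default channel-first).
* **Multiscale feature aggregation** (head): the four decoder scales of
  both subnetworks are concatenated pairwise, resampled bilinearly to full
  resolution, compressed to 16 channels each by 1×1 convolutions, and
  concatenated into F (64 channels). A channel gate α (sigmoid MLP on
  pooled F, hidden width ⌊64/3⌋ = 21) and a pixelwise gate β
  (`σ(Conv1×1(ReLU(Conv3×3(F·α))))`) combine as `F·α·β + F·α + F`; a 1×1
  convolution maps this to class logits.

The attended skip features (2C_A + C_B channels) are wider than the decoder
schedules; 1×1 convolutions reduce them to C_A for decoder_A and C_B for
decoder_B so that the printed per-stage widths stay true. For the full
model the final prediction comes from the MFA head; the two subnetwork
heads remain available and supervised. For the plain parallel variant the
final logits are the sum of the two subnetwork logit maps.

Seven variants share one construction path — `unet` (CT only, widths
64…1024), `meu_net` (three encoders of U-Net width with summed same-scale
features), `pu_net` (parallel, no gates), `sapu_net`/`capu_net` (one gate
family each), `mfpu_net` (aggregation head only), and the full `apu_net` —
so removing a block never changes the output contract.

## Training

Pixelwise cross-entropy on every active head (default weights 1/1/1 for
main, decoder_A, decoder_B), Adam with learning rate 0.005, batch size 8,
weight decay 10⁻⁷ (classic L2-in-gradient), 150 epochs by default, constant
learning rate. Dropout (p = 0.5) sits at both bottlenecks. Weight
initialization is Kaiming-normal (fan-in); a `(ModelSpec, seed)` pair fixes
every weight, and `(seed)` additionally fixes shuffling and dropout, so CPU
runs are bit-reproducible. Checkpointing keeps the parameters of the best
train-Dice epoch, ties resolved toward the latest epoch so that the batch
normalization running statistics are the most converged ones. No validation
split or early stopping is used by default. Training aborts with a
diagnostic on a non-finite loss.

The layer stack itself (`apunet.nn`) is a compact reverse-mode autodiff
engine over numpy arrays; convolutions are im2col/col2im matrix products
with a pointwise fast path, and every primitive's hand-written backward is
checked against central finite differences in the test suite.

## Synthetic phantoms

The generator emulates the statistical structure of small-lesion ROI crops:

* **Mask**: one 8-connected lesion whose area fraction is drawn uniformly
  from `lesion_area_range` (default 3–15 % of the frame). Three shape
  families — ellipse (compact), metaball blob (irregular margin), and
  lobulated union of overlapping disks — plus a `mixed` default that draws
  a family per sample, spanning the easy-to-hard spectrum on which the
  attention blocks are expected to matter. Rejection sampling enforces the
  area band and connectivity and fails loudly for infeasible configs.
* **PET**: flat background (0.20) plus a Gaussian-blurred lesion kernel
  (σ = 1 px) whose gain is solved so that the lesion/background mean
  intensity ratio equals `pet_contrast` (default 3.0) exactly on the
  noise-free image — the configured contrast is an exact post-condition,
  not an approximate target.
* **CT**: a smooth low-frequency random field (Gaussian-filtered noise
  rescaled to ≈0.30–0.55) with mild texture, plus a faint lesion footprint
  solved the same way for `ct_contrast` (default 1.3).
* **Noise and fusion**: independent Gaussian pixel noise (sd 0.03) on CT
  and PET, clipped to [0, 1]; the fused channel is exactly
  `α·PET + (1−α)·CT` with α = 0.5, a documented stand-in since real
  PET/CT fusion renderings vary by workstation.

What the phantoms do **not** model: attenuation and SUV physics, organ
anatomy, multi-lesion slices, partial-volume effects, and inter-scanner
variability. Passing tests therefore demonstrate correctness of the
architecture, optimization, and metrics — not clinical performance.

## Preprocessing

ROI extraction runs a circular Hough transform (Canny edges, radius range
3–20 px by default) and crops a 50×50 window at the strongest accumulator
peak; ties break toward the smaller radius, then row-major position, and a
peak below the normalized-vote threshold (0.3) is an error advising a
manual ROI. Crops are half-open windows in 0-based row/column coordinates
with edge replication at borders. Contrast enhancement is pluggable
(identity, gamma with exponent 1.5 > 1 so a bright lesion's mean ratio
cannot decrease, or CLAHE); augmentation is the lossless rigid family —
90/180/270° rotations and mirror flips (both-axes mirror included when both
flags are set), all pure pixel permutations.

## Metrics

DSC, Recall, VOE, and RVD are computed from exact pixel counts on 2-D
masks. Conventions for degenerate inputs (warned at runtime): both masks
empty gives DSC 1.0 and VOE 0.0; an empty ground truth leaves Recall and
RVD undefined (NaN, skipped by the aggregate mean). Aggregation is the
unweighted per-sample mean. VOE and RVD are *errors* (smaller is better)
and are reported literally from their definitions.

## Desk-scale experiments

Two reference experiments (in `apunet.experiments`) exercise the pipeline
at problem sizes chosen to run in minutes on one CPU core:

* **Memorization**: the full model at reduced width (base channels 4/8) is
  trained 200 steps on a single 50×50 phantom; a correct implementation
  reaches Dice ≈ 1 on that phantom.
* **Ablation ladder**: the five parallel variants are trained on shared
  64-train/16-test phantom sets (32×32, depth-4 models, 12 epochs, batch 8)
  across three seeds, with identical data and initialization seed within a
  seed so differences are purely architectural.

At this scale the synthetic task is easy enough that all variants reach
mean test Dice ≈ 0.97–0.99 and differences between variants sit within
seed-to-seed noise (≈0.01); the ablation check is therefore a trend check
with a 0.02 stochasticity tolerance — it verifies that no gate degrades the
baseline — rather than a strict ordering, which only a harder (clinical)
task could resolve.

## Known limitations

* CPU-only; at full default width the model trains slowly (the engine is
  numpy, one core), which is why the reference experiments use reduced
  widths.
* 2-D only; no DICOM/NIfTI ingestion (PNG + CSV manifests are canonical).
* The phantom generator's simplicity caps how much the attention blocks
  can show; conclusions about clinical data require clinical data.
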
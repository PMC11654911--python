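# Methods

## The optimizer

`lodgeseg.optimizer` is a box-bounded continuous maximizer in the AFOA family
(emperor-penguin huddling metaheuristic) with the APOM move set. A population
of `n` individuals carries positions, velocities, and elitist personal
memories; a global archive keeps the best solution ever evaluated. Each
iteration, every individual draws one move:

* **Strategy I (oscillation probing).** Two probes `X_b ± (v + β)` around the
  archived best are evaluated and the better one adopted by the individual
  (and by the archive if it improves it). The probe geometry is
  `λ_d = exp(−0.25·Ub_d·(t − 0.3·T)/T)·r_d` with `r_d ~ U(0,1)`,
  `v = λ^0.8 ⊙ (λ/4) ⊙ (Ub − Lb)`, and `β = Ub·q·λ` with a fair coin `q`.
  `λ` exceeds 1 before `t = 0.3·T` and shrinks afterwards, so probing is wide
  early and narrow late.
* **Strategy II (differential move).** `X_b + a·rand ⊗ (Xm_r1 − Xm_r2)` for
  two random memories; when the sampled memories coincide the population has
  contracted and the move falls back to `X_b + 0.25·rand ⊗ (Ub − Lb)`.
* **Strategy III (velocity move).** A momentum update pulled toward a random
  peer and the individual's own memory, each pull scaled by the guidance
  coefficient `a = exp(−d / (2·D^0.8))` of the corresponding distance.
* **Mutation.** Each coordinate is redrawn uniformly with probability 0.6,
  the rest inherited bit-exactly.

The dispatch draws `u ~ U(0,1)` against `Pr(t) = min(1, 0.3 + (t/T)^(2g))`
(default `g = 1`): strategy II with probability `1 − Pr`, otherwise uniformly
one of {I, III, mutation}. Early iterations are therefore ~70% exploratory
strategy II; by the end II vanishes.

Several of these formulas admit more than one reading when typeset without
grouping; the forms above are the adopted readings, each implemented in a
single small function (`compute_perturbation`, `guidance_coefficient`,
`selection_probability`, `select_strategy`) so an alternative reading is a
one-line change. They were chosen to satisfy the qualitative constraints the
method's narrative imposes (wide-then-narrow probing, `a ∈ (0,1]` decreasing
in distance, exploration fading over time) — not tuned against any outcome.

Conventions: maximization is canonical (negate to minimize); every move is
clipped to `[Lb, Ub]`; one seeded `numpy` generator per run, consumed in
population order, makes a (seed, config) pair reproduce the history exactly.
The bundled benchmark box is `[−0.5, 0.5]^m` — the algorithm's design box,
the same one the channel encoding uses.

## Channel encoding

A candidate is `x ∈ [−0.5, 0.5]^43`, one coordinate per tunable convolution
(31 encoder "DSCL" slots, then 12 decoder "USCL" slots). Decoding applies
`l' = l − ⌊l·x⌋` with floor toward −∞, so `x = −0.5` yields the maximal
widening `l + l/2` (64 → 96) and `x = +0.5` roughly halves the layer; decoded
widths are clamped to ≥ 1 (unexercised for the published counts). Reduction
ratios are printed as `100·(l − l')/l` rounded half-up (ties away from zero)
to two decimals; that convention reproduces all 43 published ratios exactly.

## Architecture reconstruction

The published material fixes the per-slot channel counts but shows the
topology only pictorially, so the layer table in `lodgeseg.model` is a
reconstruction — one consistent reading, frozen in a single table in code:

* encoder: 7×7 stride-1 stem (slot 1); stages of ConvNeXt blocks with 2×2
  stride-2 downsampling convolutions between them, consuming slots in order —
  stage widths 32/64/128/256 with 1/2/2/6 blocks, then a fourth downsample
  (slot "DSCL 27", whose role the slot list otherwise leaves unexplained) and
  a 2-block bottleneck;
* decoder: four levels of ×2 bilinear upsampling → concatenation with the
  same-resolution encoder output → 1×1 reduction → one ConvNeXt block (three
  USCL slots per level), then a final channel LayerNorm and 1×1 head to the
  4 class logits.

This allocation consumes the 31 + 12 slots exactly and reproduces the
baseline's doubling/halving channel profile with a uniform 4× block expansion
— the strongest internal-consistency check available. Each block is
depthwise 7×7 (pad 3) → channelwise LayerNorm → 1×1 expand → GELU → 1×1
project → residual.

**Residual alignment.** Independently tuned widths break identity shortcuts
(e.g. a block with 37 input and 44 output channels). The residual is aligned
parameter-free — surplus channels cropped, missing channels zero-padded —
rather than through a learned 1×1 projection. This choice is forced by the
published cost table: with 1×1 projections the optimized plan would *gain*
parameters over the baseline (5.56 M vs 5.39 M), while parameter-free
alignment yields 4.865 M vs 5.394 M, matching both the published ordering and,
almost exactly, the published optimized count (4.87 M).

**Cost accounting.** Parameters: `K²·C_in·C_out + C_out` per convolution,
`49·C + C` per depthwise, `2C` per LayerNorm. FLOPs: `2 × MAC` of the
convolutions at a stated input size (default 512×512), spatial sizes tracked
through the stride-2/×2 layers; normalization, activations, and interpolation
are not counted. Parameter counts of an instantiated network equal the table
count exactly (tested).

**Known limitation — the FLOPs ordering.** Under this reconstruction the
published optimized plan costs *more* conv FLOPs than the baseline (73.4 G vs
69.8 G at 512²) even though it has fewer parameters: it widens the
high-resolution early layers and narrows the low-resolution stage-4 layers,
and FLOPs weight layers by resolution. A published table reports the opposite
ordering for the authors' (unknown, likely differently resolution-weighted)
topology. The discrepancy is intrinsic to any uniform-resolution
reconstruction of this slot list; no claim about the FLOPs ordering between
the two published plans is made or tested. Within one topology the accounting
behaves correctly (linear in widths, strictly monotone), which is what the
search needs.

## Loss and metrics

Training uses `w_f·Focal + w_d·Dice` with `w_f = w_d = 1` (the combination
weights are a free design choice; 1:1, configurable). Focal:
`mean(−(1−p_t)^γ log p_t)`, `γ = 2`, on the predicted probability of the true
class, clamped at 1e−12 inside the log; no per-class α weighting. Dice:
`1 − (2Σpy + ε)/(Σp + Σy + ε)` averaged over classes, `ε = 1e−6` to avoid 0/0
on absent classes. The training path computes the exact analytic gradient of
the combined loss through the softmax (validated against finite differences).

All evaluation metrics derive from the K×K pixel confusion matrix (rows =
truth): PA = trace/total; per-class pixel accuracy is read as per-class
recall, MPA its mean; IoU = TP/(TP+FP+FN), mIoU its mean; F1 =
2TP/(2TP+FP+FN). Classes absent from both prediction and truth are undefined
and excluded from MPA/mIoU means (not scored 0 or 1). Row-normalized
confusion matrices put per-class recall on the diagonal; empty rows are
emitted as zeros with a warning.

## Multi-objective fitness and the search

`fit_i = 0.6·mIoU_i + 0.1·P_i + 0.3·f_i` with `P_i = 1 − params_i/Σparams`
and `f_i = 1 − FLOPs_i/ΣFLOPs` over a comparison pool. Pool-relative terms
make fitness incomparable across pools, so the search **freezes the
normalization pool at the seeded initial population**: every candidate in a
run is scored against the same cost sums, fitness becomes a static objective,
and the elitist best-fitness sequence is genuinely non-decreasing.
(Re-normalizing over each generation's population was implemented first and
rejected: the archived best's score then drifts with pool composition — it
was observed to *decrease* with an unchanged archive — which breaks elitism
as a reporting contract.) Rankings are invariant to rescaling all parameter
counts (or all FLOPs) by a common factor, so the resolution at which FLOPs
are measured does not affect the search.

Candidate evaluation: decode → build → train briefly with AdamW
(lr 1.5e−3, weight decay 5e−5, batch 4 — the full-scale training values) →
mIoU on the validation split; parameters and FLOPs come from the table and
are exact. A candidate whose training produces non-finite loss scores
mIoU = 0 with a warning instead of aborting the search. Per-candidate
training seeds derive from (run seed, evaluation index). The search runs the
full-scale configuration (population 8, 10 iterations) by default; tests and
examples use the smoke configuration (population 4, 2 iterations, 1 epoch).

## Synthetic scenes

The generator emulates the spatial statistics segmentation needs: a
Gaussian-smoothed random field (correlation length `blob_scale`, default 12 px)
is thresholded at the cumulative prior quantiles with classes ordered
BG < NL < HL < L along the field value. Nested level sets then place the HL
band along the borders of L patches — mirroring how lodged areas grade into
half-lodged crop at their edges. Default priors BG 0.25 / NL 0.45 / HL 0.20 /
L 0.10 encode the lodged-class rarity that motivates the focal+dice loss; the
real per-class proportions are not published, so these are stand-ins chosen
once. Per-class textures (dark-green high-frequency speckle for upright
canopy, oblique streaks for HL, smooth yellowish directional streaks for L,
low-texture brown for soil) plus additive Gaussian pixel noise make the
classes separable by local color/texture — a 5-NN pixel classifier on
(R, G, B, local variance) exceeds 70% accuracy, so the task the search trains
on is learnable but not trivial.

What the generator does **not** emulate: illumination gradients and shadows,
perspective and stitching artifacts, within-class phenological variation,
inter-class boundary mixing pixels, and georeferencing. Passing tests
therefore demonstrate that the search machinery works on a learnable 4-class
task with the right class structure — not field-accuracy on real UAV imagery;
the published real-data accuracies (PA/mIoU in the mid-90s) require the real
dataset and full-scale GPU training and are out of scope here.

Masks are stored as paletted single-channel PNGs (labels 0–3, lossless);
datasets ship with a JSON manifest and a deterministic 0.75/0.25 scene-level
train/val split. Tiling mirrors the orthophoto protocol: non-overlapping
2048/1024/512 tiles, all rescaled to 512 (bilinear image, nearest mask).
Labelme-style polygon JSON is rasterized with later-polygon-wins semantics.

## Numerical choices

* He (fan-in) normal initialization for all convolutions; zero biases;
  LayerNorm at identity. A final channelwise LayerNorm precedes the head.
* Inputs standardized per image and channel to zero mean / unit variance
  (leakage-free between splits). Together with He init this is what makes
  3-epoch candidate training informative — with raw [0,1] inputs the network
  is still in its collapse phase after 30 updates.
* float32 activations/parameters; loss and gradient assembled in float64.
* 7×7 convolutions via shift-and-accumulate (49 vectorized adds), avoiding
  im2col buffers; downsampling as space-to-depth + 1×1; ×2 bilinear
  upsampling in separable dense-matrix form with half-pixel centers.
* Strategy-I probe ties resolve to the `+` probe; strategy III excludes the
  mover itself when drawing the peer; mutation masks use `<` against the
  redraw probability.
* Desk-scale study conditions (tests, examples, acceptance): 64×64 scenes,
  40 train / 12 val, reference plan divided by 4 (≈ 0.37 M parameters),
  3 epochs for plan evaluation, 1 epoch per search candidate. Chosen once as
  the smallest configuration on which brief training reliably clears
  mIoU 0.5 for the baseline plan across seeds.

## Limitations

* The architecture is a reconstruction; absolute parameter/FLOP figures are
  convention-dependent, and the published FLOPs ordering between the two
  plans does not transfer (see above).
* The frozen-pool fitness normalization is one resolution of an ambiguity the
  source leaves open; any pool convention changes absolute fitness values
  (not mIoU/params/FLOPs themselves).
* The two-stage protocol (short-budget search, then full training of the
  winner) is supported by configuration but the full-scale stage is not an
  acceptance path anywhere in the repository.
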
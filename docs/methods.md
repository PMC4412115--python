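# Methods

## The problem

Cyanobacterial strains engineered for ethanol production (PDC/ADH cassette)
down-regulate the accessory pigment phycocyanin (PC). Under an epifluorescence
filter set chosen for this contrast (~388 nm excitation, 510 nm long-pass
emission with a 680 nm cut-off), three single-cell phenotypes are separable by
colour alone:

| phenotype          | pigmentation                  | appearance            |
|--------------------|-------------------------------|-----------------------|
| `WT_RED`           | full PC + chlorophyll a       | bright red            |
| `PRODUCER_ORANGE`  | reduced PC                    | orange, dimmer (red ≈ green signal) |
| `DEAD_GREEN`       | no photopigments              | unspecific green      |

Counting revertant (wild-type-pigmented) cells inside a producer culture gives
an early warning of genetic instability long before the bulk absorption
spectrum shifts. `phenoscope` implements the image-analysis chain for this
assay — flat-field correction, maximum-entropy segmentation, hue features and
a small neural-network classifier — together with a synthetic micrograph
generator that provides ground truth for every stage, since no real
micrographs are publicly deposited.

## Synthetic micrographs (`imgen`)

Scenes emulate a fixed monolayer of round-to-elliptical cells at 40×
magnification: axis-aligned ellipses with semi-axes drawn uniformly from
3–8 px, centres placed by rejection sampling with a minimum centre distance of
18 px (cells never touch; the segmenter has no splitting step), class labels
drawn i.i.d. from the configured class fractions. Default frame 1024×768 px;
the pipeline-scale helpers (training sets, mixing harness) use 640×480 frames
with ~50 cells each so a 20-frame sample carries ~1000 cells, matching the
protocol's 500–1000 cells over 20 stage positions while keeping a full
mixing run around a minute of CPU.

Default phenotype colours (8-bit RGB means) are `WT_RED` (200, 40, 10),
`PRODUCER_ORANGE` (150, 130, 10) — red ≈ green and dimmer — and `DEAD_GREEN`
(30, 180, 20), with a per-pixel spread of 15 inside cells; background level
10. These reproduce the qualitative hue ordering red < orange < green on the
hexcone scale and are fully configurable (YAML).

Noise semantics: `noise_sd = 0` disables the noise stage entirely, so
noiseless scenes render cell interiors at exactly the phenotype means — the
anchor for exact-value tests. Otherwise background pixels receive additive
Gaussian noise of sd `noise_sd` (default 15) and cell pixels of sd
`channel_sd`.

Illumination: a radial quadratic vignette, multiplicative, whose relative
corner-to-centre drop equals `vignette_strength` (default 0.25) and which is
normalized to **unit mean**. The unit-mean convention is deliberate: the
flat-field correction rescales by the blank's per-channel mean, and a
unit-mean field is the unique scaling that such a correction inverts exactly,
making the round trip (corrupt with field, correct with matching blank) an
identity up to 8-bit rounding. The blank image is the same field scaled to a
mean of mid-gray (128).

What the generator does *not* model: point-spread blur, photobleaching, cell
clumping or division, out-of-focus light, chromatic aberration. Passing tests
therefore demonstrate correctness of the analysis chain under its stated
assumptions (well-separated, colour-distinct cells), not performance on real
micrographs — on real data the limiting factors are touching cells (merged
particles; no watershed step, by design) and intermediate "dying" phenotypes.

## Flat-field correction (`preprocess`)

Per channel: `out = image × mean(blank) / blank`, clipped to [0, 255],
rounded half-up. The blank is 5×5 median-smoothed first so its shot noise is
not imprinted onto the corrected image; any non-positive smoothed blank pixel
is an error naming the channel and pixel. A constant blank is the identity.
For batches, `smooth_blank` lets the median filter run once per session.

## Segmentation (`segment`)

Red and green channels (the two information-bearing channels; blue carries
none) are thresholded independently with the Kapur maximum-entropy criterion:
the threshold `t` maximizes the sum of Shannon entropies of the histogram
restricted to levels ≤ t (background) and > t (foreground). Candidates with
an empty side are skipped rather than scored zero; ties resolve to the
smallest `t`. The implementation is closed-form over cumulative sums and is
tested for exact agreement with a brute-force entropy search.

The two binary masks are combined by pixelwise union (a dead cell visible
only in green is still registered), components are labeled with
8-connectivity, and two exclusion rules apply: area < 10 px (artifacts) and
any pixel on the image border (truncated cells). A component failing both is
tallied once under the size rule, keeping the accounting identity
`classified + excluded = registered`. Both the area reading of "10 pixel"
and the connectivity are configurable.

## Features (`features`)

Per particle: a normalized histogram of hexcone hue (B = 32 equal bins over
[0, 1)) over member pixels, plus the mean HSV value ("brightness") appended
as one extra input (length B + 1). Achromatic pixels take hue 0 by
convention. Hue is invariant to uniform intensity scaling, so the features
are robust to residual illumination error; brightness separates the dimmer
orange producers from bright wild-type cells. B = 32 balances hue resolution
against training-set size; it and the conventions above are carried in a
fingerprint stored with trained models so a model can refuse features
extracted under different conventions.

## Classifier (`classify`)

One hidden layer (default 10 units), sigmoid activations, three sigmoid
outputs with one-hot targets and sum-of-squares loss. Training is full-batch
iRPROP− (η⁺ = 1.2, η⁻ = 0.5, Δ₀ = 0.1, Δmax = 50): sign-based per-weight
step adaptation, flipped-gradient forgetting, no backtracking. When the
relative change of the training misclassification rate over a 20-epoch
window falls below 1% while the rate is still above target, a genetic
algorithm phase runs: population 30 seeded from the current weights plus
Gaussian perturbations (σ = 0.2), uniform crossover, 2 elites, 25
generations, fitness = misclassification rate with sum-of-squares error as
tie-break. Elitism guarantees the phase never returns a worse network; RPROP
then resumes from the best individual with reset step sizes. Training stops
at 0% training error (the assay's stop criterion) or after `max_rounds`
(default 2000) epochs, in which case the model is returned flagged
non-converged. Stopping at zero training error invites overfitting in
general; it is retained as the assay's convention, and on well-separated
synthetic phenotypes held-out accuracy stays ≥ 95% (tested across 10 seeds).

The "stall below 1%" trigger is read as a *relative* change over the window;
absolute would be stricter for error rates near zero. Both the window and
threshold are parameters.

## Pipeline and the in-silico mixing experiment (`pipeline`)

`analyze_sample` corrects, segments, featurizes and classifies each image of
a sample, isolating per-image failures, and aggregates counts into a
`SampleReport`. Fractions are reported both over all classified particles
and over viable (non-dead) particles only; the mixing percentages quoted for
the assay are over all cells, which is what `class_fractions` gives.

`mixing_experiment` renders samples at configured wt:producer ratios (dead
fraction 0; 20 frames, ~1000 cells, 3 replicates by default), classifies
them with a supplied or freshly trained model, and tabulates estimated
against realized true fractions — the in-silico analogue of the bench
validation in which wt and producer cultures were mixed at 0/100 through
100/0 and recovered by the classifier. On default phenotypes the
misclassification floor is zero, so the estimate equals the realized
ground-truth fraction and deviates from the nominal ratio only by binomial
label sampling (SE ≈ 1.4 pp per 1000-cell sample at 50:50).

## Spectra (`spectra`)

Bulk absorption spectra (400–750 nm) are normalized to A(680 nm) = 0.45 at
the chlorophyll peak; the PC/Chl indicator is A(620)/A(680) with linear
interpolation at non-sampled wavelengths. Reading at exactly 680 nm (rather
than peak-finding near it) keeps the value reproducible. Normalization is
idempotent and commutes with the ratio.

## Numerical conventions

- 8-bit conversion everywhere is round-half-up (`floor(x + 0.5)`), clip to
  [0, 255].
- All randomness flows through `numpy.random.default_rng` seeded from
  user-supplied integers; a fixed seed fixes every byte of generated scenes
  and every training trajectory.
- Model files are versioned JSON; loading a truncated, foreign or
  version-mismatched file raises, and predictions round-trip bit-for-bit.
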
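# Methods

## Overview

`songbert` implements a self-supervised pipeline for discovering the units
of birdsong without labels. A transformer encoder is pretrained to
reconstruct masked regions of canary-song spectrograms at full 2.7 ms
temporal resolution; its per-frame hidden states are then reduced with UMAP,
clustered with HDBSCAN, cleaned by temporal post-processing, and scored
against frame-level annotations. A synthetic canary-song generator supplies
waveforms with exact frame-level ground truth so every stage is testable on
one CPU.

## Spectrogram representation

Audio must be mono 44.1 kHz. Preprocessing is fixed by the method:

- causal 5th-order elliptic high-pass (0.2 dB ripple, 40 dB stopband,
  500 Hz cutoff), removing low-frequency cage noise;
- STFT with a 1,024-point Hann window and 119-sample hop: one time bin per
  2.698 ms (reported as 2.7 ms), just shorter than the briefest
  inter-syllabic gaps so frames do not straddle syllable boundaries;
- frequency truncation to FFT bins [20, 216) — exactly 196 rows, roughly
  0.86-9.3 kHz. The bin range is authoritative; printed Hz ranges that
  assume exactly 43 Hz/bin are treated as rounded descriptions;
- log-amplitude compression, `log(magnitude + 1e-8)`, then a single
  image-wise Z-score. Log compression makes a global recording gain an
  additive constant which the Z-score removes; the tiny floor only affects
  exact zeros.

Framing is centered with 512-sample reflection padding: an N-sample clip
yields exactly `1 + floor(N/119)` bins, frame k centered at sample `119 k`.
The synthetic generator labels frames by the sample at each frame center,
so waveforms and label sequences stay aligned through the whole pipeline.

## Network

The model is a CNN front-end plus a compact transformer encoder
(reference configuration, ~2.48 M trainable scalars):

- four (conv 5x5, pad 2, GELU, max-pool (2,1)) stages with channels
  32/64/64/64; pooling halves frequency (196 -> 98 -> 49 -> 24 -> 12) and
  never touches time;
- linear projection of the 64 x 12 = 768 per-bin features to d_model = 196;
- four pre-layer-norm encoder blocks: 4-head self-attention (head dim 49)
  with learned relative positional biases, then a 196 -> 768 -> 196 GELU
  feed-forward, both residual;
- final layer norm and a 196 -> 196 linear deprojection back to
  spectrogram space.

The relative positional scheme is Shaw-style learned relative-key
embeddings: one table of shape (2 x 512 + 1, 49) per block, shared across
heads, distances clipped at +/-512 bins; the logit is
`(q.k + q.r_{j-i}) / sqrt(49)`. This is one standard reading of "relative
learned positional encodings"; it was chosen because it is simple, strictly
relative (translation-equivariant away from window edges, verified by a
test), and lands the total parameter count at 2,476,660, matching the
reference budget of approximately 2.5 million parameters.

Frame latents for all downstream analysis are tapped at the
post-attention-residual, pre-feed-forward state of block 3 (1-indexed).
The phrase "the multi-head self-attention layer of block 3" is ambiguous
between pre/post residual and pre/post feed-forward; every intermediate
state is exposed by name, and the default is the earliest state that
includes the attention mixing of block 3.

The network, its training loops, and the linear probes run on a small
reverse-mode autodiff core over NumPy (`songbert._nn`), written for this
package: float32 by default, float64 for gradient checks, single-threaded
and bit-reproducible for fixed seeds. Every op's gradient is verified
against central finite differences in the test suite.

## Pretraining

Each optimization step draws random context windows (1,000 bins = 2.7 s at
reference scale) from training songs, applies a per-window frequency shift
(uniform on +/-50 bins, vacated rows zero-filled), then occludes one shared
mask across the batch and zeroes the masked columns. The loss is MSE over
masked cells only; the optimizer is Adam (lr 3e-4, batch 42 at reference
scale). Songs are split 80/20 at the song level; no window from a held-out
song ever enters a training batch (audited by a test).

Masks are unions of contiguous segments with lengths uniform on {0..250}
and positions uniform over the window (segments may overhang the edges and
are clipped). Segments accumulate until coverage reaches
`round(0.25 x 1000) = 250` bins; the final segment is trimmed to make
coverage exact. Two details are deliberate choices where the protocol is
underdetermined:

- the trimmed end of the final segment is chosen at random. Trimming
  always from the right would systematically over-mask early bins
  (measured: 0.31 at bin 0 vs 0.23 at bin 999); random-end trimming keeps
  the per-position masking probability flat at 0.25;
- overshoot past 25% is trimmed rather than rejected, giving a
  deterministic coverage contract (every mask covers exactly 250 bins).

Validation runs every 500 steps on a fixed, pre-drawn set of held-out
windows with fixed masks, so checks are comparable. The smoothed check
value averages all validation records in the trailing 1,000 optimization
steps (a literal reading of "1,000-step moving average"; the span is
configurable). Training stops after eight consecutive checks without
improvement of the smoothed value, or at `max_steps`.

## Clustering pipeline

One 196-dim latent per time bin is collected by tiling context windows
over each song (capped at 1,000,000 bins per fold). UMAP reduces to 2-D
(cosine metric, 200 neighbors, min-dist 0.1, seed 42 at reference scale);
HDBSCAN (min_cluster_size 5,000, min_samples 1) labels the 2-D points,
with -1 for noise. Two per-song cleanup passes follow, in this order:

1. noise reassignment: each -1 bin takes the label of the nearest
   non-noise bin in time; ties go left; a song with no labeled bin is
   left unchanged;
2. temporal smoothing: each bin takes the majority label of the length-w
   window centered on it (left-heavy for even w: `[i-w/2, i+w/2)`),
   truncated at song edges; ties go to the label appearing first in the
   window; the pass is non-recursive (all outputs computed from the
   original labels).

Both operations are verified against brute-force oracles on random
sequences.

## Evaluation

Ground-truth syllable labels are converted to phrase labels by absorbing
silent bins into the nearer adjacent syllable run (ties to the earlier
label; boundary silences take the single adjacent label). Metrics:

- V-measure (harmonic mean of homogeneity and completeness), via
  scikit-learn, checked against closed-form toy cases;
- cluster-to-truth mapping: the co-occurrence matrix is column-normalized
  (each predicted cluster sums to 1) and the Hungarian algorithm maximizes
  the summed normalized co-occurrence; surplus labels on either side are
  unmatched. Verified against exhaustive permutation search up to 6 x 6;
- frame error rates: *total* FER counts frames of unmatched predicted
  clusters as errors; *matched-only* FER restricts to frames whose cluster
  has a mapping;
- phrase statistics: mean run duration (bins) and Shannon transition
  entropy (base 2; the base cancels in correlations) of the
  next-distinct-run distribution, pooled over transitions within songs.
  Pooling the counts coincides with per-occurrence averaging for
  stationary usage; the alternative is noted but not implemented;
- weighted Pearson correlation between ground-truth and predicted phrase
  metrics, weighted by ground-truth run counts of each matched phrase
  ("frequency of occurrence" could also mean frames; the weight source is
  configurable, runs by default);
- a smoothing sweep tabulating all metrics for windows 0..500 in steps
  of 25.

## Linear probes

Four conditions measure the linear decodability of phrase identity from a
single frame vector: pretrained latents (block-3 tap), the same tap of a
randomly initialized network, the raw 196-dim spectrogram column, and full
fine-tuning (head on the deprojection output, backbone unfrozen). The
probe is always one linear map to the phrase classes trained with
cross-entropy and Adam (lr 1e-2 frozen / 3e-4 fine-tune, batch 42,
validation every 25 batches, 1,000-step moving average, patience 6,
capped at 5,000 batches; no masking or shifting). FER is the percentage of
mismatched frames on held-out songs; per-class FERs and their standard
deviation are reported alongside (both pooled and per-song views are
available, since either aggregation is defensible).

## Seasonal overlap

Embeddings of four temporal groups (two per season) are binned into
300 x 300 2-D histograms over one shared extent — the pooled bounding box
padded 1% per side, upper edges closed — and normalized. Overlap is the
Bhattacharyya coefficient `sum(sqrt(P*Q))`; the analysis reports the mean
of the 2 within-season pairs and the 4 between-season pairs. The pooled
extent is a choice; a per-group extent would inflate overlap for shifted
repertoires.

## Synthetic song generator

The generator emulates adult canary song structure: harmonic syllables
(1-2 harmonics, constant / upsweep / downsweep / trill pitch trajectories,
fundamentals spread over 1.5-7 kHz) of 50-180 ms, repeated 3-8 times per
phrase with 5-15 ms intra-phrase gaps; phrases separated by 150-400 ms
silences and chained by a strictly positive first-order Markov matrix with
small self-transition mass; additive white noise at 30 dB SNR; 5 ms
raised-cosine onset/offset ramps. A "seasonal variant" re-draws a fraction
(default 50%) of templates under the same ids to emulate repertoire
turnover between recording epochs.

What it does **not** emulate: amplitude and pitch jitter across renditions,
biophysical source-filter structure (syrinx dynamics), reverberation and
colored cage noise, juvenile plastic song, and overlap from other birds.
Passing tests on this material therefore demonstrates that the pipeline's
machinery is correct and that it recovers planted structure under mild,
controlled variability — not that it reaches any particular accuracy on
real recordings.

Per-song seeds derive from the corpus seed by a counter scheme
(`SeedSequence([seed, i])`), so corpora are reproducible and songs
independent.

## Desk-scale configuration

The `desk` preset exercises the full pipeline on one CPU in minutes and is
what the end-to-end tests run:

- model: conv channels 4/8/8/8, d_model 64 (4 heads of 16), FFN 128,
  2 blocks, context 250 bins (~0.67 s), relative-position clip 256;
  latents tapped at block 2;
- data: 8 synthetic songs of 5 s each (40 s of song, well inside the
  preset's 5-minute budget), 3 syllable types;
- training: Adam lr 1e-3, batch 4, 1,000 steps, validation every 50 steps,
  patience 8, frequency shifts reduced to +/-10 bins — with a 3-type
  repertoire the full +/-50-bin shift makes the reconstruction task far
  more diverse than the repertoire itself and dominates the short training
  budget;
- clustering: latents from the final layer-norm output — with only two
  blocks the deepest normalized state is the desk analog of the reference
  block-3 tap, and it clusters phrase structure best across seeds; UMAP
  neighbors 15, min-dist 0.1; HDBSCAN min_cluster_size 50, min_samples 1;
  smoothing window 300 bins (~0.8 s, the same order as the reference
  optimum of 200 bins relative to phrase duration);
- seasonal histograms: 50 x 50 bins, matched to the few thousand embedded
  frames per desk group (300 x 300 bins would leave nearly every bin with
  0 or 1 counts and depress all overlaps toward zero).

These are scale choices, not new method elements; every constant of the
reference protocol remains the default of the corresponding module.

## Numerical and degenerate-input conventions

- Z-score of a constant spectrogram, empty masks, empty coordinate sets,
  unnormalized histograms, zero weighted variance: explicit errors.
- Masks of ratio 0, smoothing windows 0 and 1, all-noise label sequences,
  single-template grammars: well-defined no-ops or trivial outputs.
- All randomness flows through `numpy.random.Generator` objects seeded at
  the interface; training, synthesis, UMAP (single-threaded), and the CLI
  are bit-reproducible for a fixed seed.

## Known limitations

- The NumPy autodiff core is single-threaded and CPU-bound; reference-scale
  pretraining (26,500 steps at batch 42, context 1,000) is far outside its
  intended envelope. The reference configuration is exercised structurally
  (shapes, taps, parameter count), while learning behavior is validated at
  desk scale.
- Mixed-precision training is not implemented; float32 is the working
  precision throughout.
- HDBSCAN comes from scikit-learn; results can differ in detail from the
  standalone `hdbscan` package on borderline densities.
- The song-detector stage of the original recording workflow is replaced
  by explicit song-interval inputs; the package never classifies
  song vs. non-song audio.
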
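# Methods

This note documents the models and procedures implemented in `dtwdemux`,
the parameters that matter, the choices made where the design was open, and
what the synthetic data can and cannot show.

## Raw-signal model and the simulator

A direct-RNA read's current trace has three parts, in sequencing order:
the DNA adapter (whose final ~18 nt encode the barcode), the poly(A) tail
(a long, near-constant plateau), and the RNA body. The simulator
(`dtwdemux.simulate`) emulates exactly this anatomy:

- **Adapter levels** come from a k-mer model: the expected current of each
  k-mer occupying the pore, read in translocation (3'→5') order. The
  bundled model (`synthetic_kmer_model`) is a fixed-seed table of 4⁵ = 1024
  five-mer levels drawn uniformly in 60–130 pA — the typical RNA002
  current range — so nothing has to be downloaded. The adapter leader
  (all bases before the barcode) is one fixed random sequence shared by
  every class, so only the final 18 nt differ between barcodes.
- **Dwell times.** Each base produces a run of identical samples. The mean
  dwell is `sample_rate / translocation_speed` (3012 Hz / 70 nt/s ≈ 43
  samples by default; an RNA004 preset uses 4000 Hz / 130 nt/s). Dwells are
  negative-binomial with variance `μ + d·μ²` (dispersion `d`, default
  0.25, clipped at ≥ 1 sample); `d = 0` degenerates to the deterministic
  `round(μ)`, which is what makes noise-free oracle tests exact.
- **Noise** is additive Gaussian per sample (default sd 2.5 pA,
  within-event measurement noise).
- **Poly(A)** is a single constant level (default 125 pA) held for the
  summed dwells of `polyA_len_nt` bases (default 150 nt).
- **RNA body** is a per-base random walk (step sd 8 pA) with *reflecting*
  boundaries at 60/130 pA. Reflection matters: a hard clip would park the
  walk at the boundary and fabricate plateaus that masquerade as poly(A).
- **Noise-class reads** are produced by three corruption operators:
  a stalled/blocked pore that overwrites ≥ 50% of the adapter tail with a
  suppressed-current plateau (40–65 pA, below the open-pore range);
  truncation of ≥ 50% of the adapter; and deletion of the poly(A) tail.
  The ≥ 50% severity floor is deliberate — milder corruptions leave the
  barcode span intact and are, correctly, not outliers. An earlier variant
  that *inserted* a plateau anywhere in the adapter was abandoned: the
  adaptive segmentation collapses any constant run into one or two
  segments, so inserted stalls left fingerprints near-typical and the
  noise-mining stage (correctly, given its input) found nothing.

`noise_fraction` is defined as the NOISE share of the *total* dataset, so
`simulate_dataset(k=4, n_per_barcode=100, noise_fraction=0.2)` yields 400
barcode reads plus 100 corrupted ones.

## Preprocessing

**Boundary detection.** The poly(A) onset is found in two stages. First, a
200-sample rolling window flags plateau candidates: variance below a
threshold and mean inside the poly(A) band (105–145 pA). The variance
threshold is adaptive by default — 2.5× the within-event noise variance,
itself estimated as the 5th percentile of 25-sample rolling variances —
because any fixed threshold either misses the plateau at high noise or
admits quiet stretches of the RNA body at low noise. Second, the onset is
refined inside a ±300-sample window by a two-piece Gaussian log-likelihood
changepoint that allows both mean and variance to change; on a noiseless
step it is exact, and the variance term is what separates a quiet plateau
from a loud adapter. Reads with no qualifying plateau are flagged
(`no_polya`) and routed to QC failure, never raised as errors.

**Segmentation.** The adapter span is cut into
`round(expected_adapter_bases × overseg_factor)` segments — 55 by default
(50 nominal bases, 10% over-segmentation so missed events cannot eat into
the barcode). Boundaries are the highest Welch *t* positions between
adjacent 15-sample windows, taken greedily in descending *t* (ties to the
lower index) with a 3-sample minimum spacing; if the greedy layout strands
itself on a very short slice, the slice is partitioned evenly instead. The
segmentation is an exact partition, so the dwell-weighted mean of segment
means equals the slice mean to float precision.

**Normalization and trimming.** Segment means are normalized by
median/MAD (scale factor 1.4826 for sd-consistency; MAD = 0 falls back to
z-scoring, sd = 0 to zeros) over *all* segments, then the final 25 values
are kept as the fingerprint. Normalizing before trimming keeps the
barcode's scale anchored to the whole adapter; whether to normalize before
or after trimming was an open choice, and before-trimming was adopted as
the more stable variant.

## Distance, kernel, classifier

DTW uses squared pointwise cost, step set {(1,0), (0,1), (1,1)}, both ends
anchored, square root applied to the accumulated cost, and an optional
Sakoe–Chiba band (off by default). The implementation is a numba kernel,
cross-checked in the tests against an exhaustive enumeration of all
warping paths on short series. The classification kernel is
`exp(−γ·DTWD)` with γ = 1.2. This kernel is not guaranteed positive
semidefinite; libsvm tolerates indefinite Gram matrices, and `fit` retries
once with 1e-8 diagonal jitter before giving up.

The classifier is a scikit-learn-style estimator wrapping
`SVC(kernel="precomputed", probability=True)` (one-vs-one, Platt scaling
via internal 5-fold CV, pairwise coupling; C = 1.0 by default and exposed).
`predict` returns the argmax of the calibrated probabilities so that the
label is always consistent with the confidence score, defined as the gap
between the two largest class probabilities. Status logic: NOISE top class
→ `noise` (bypasses the cutoff — noise rates are reported separately from
unclassified rates); confidence below the cutoff → `unclassified`; failed
fingerprint → `qc_fail`. A probability tie gives confidence 0 and is
unclassified at any positive cutoff.

## Training-set construction

- **Noise mining.** For each read, X = the median DTWD to reads of *other*
  barcode classes (capped at 200 random references per read for
  tractability). Outliers by robust Z-score, `(X − median) / MAD` with the
  all-zero convention at MAD = 0, become NOISE-class training instances:
  the top `n_noise` (default 400) with score above `z_cutoff` (default
  3.5, the classical robust-outlier convention; the threshold is config).
- **Diversity split.** Per barcode: 80 instances by greedy max-sum
  diversity on the within-class DTWD matrix, 80 by the mirrored greedy
  min-diversity from the remainder, 240 uniformly at random from the rest
  (stratified across replicate groups when provided) — 400 per barcode.

## Barcode design

Targets are sine/square waveforms over a 4-frequency × 4-phase grid,
median/MAD-normalized, from which the 12 most mutually DTW-distant are
chosen greedily (maximin). Candidate sequences are found by stochastic
hill-climbing (single-base mutations, 20 000 proposals per target with
restarts every 200) over the de Bruijn graph of *allowed* k-mers — those
whose level matches their reversal's within a tolerance (default: half the
inter-quartile range of model levels), since no 3'→5' DNA model exists and
the design must be robust to reading direction. Every evaluated sequence
is scored as the DTWD between its normalized predicted levels and the
target; the best 50 distinct sequences per target form the 600-candidate
pool (duplicates across targets retained).

Selection solves the Maximal Diversity Problem (max *sum* of pairwise
distances, k = 12) by greedy seeding from the farthest pair plus
best-improvement 1-swap exchange; exhaustive enumeration is available for
instances with C(M, k) ≤ 10⁶. One caveat discovered during development
and worth stating plainly: on a realistic candidate geometry the *sum*
objective alone favours near-duplicate extremes (two single-base variants
of the same far-out candidate beat a spread set on total distance while
being almost indistinguishable from each other — the worst property a
barcode pair can have). The production pipeline therefore adds a minimum
pairwise separation floor to the selection (default: the lower quartile of
the pool's distance distribution, relaxed in 10% steps if infeasible), a
generalization of deduplicating the final set. With the floor, the
selected set's minimum pairwise DTWD beats essentially every random
12-subset of the pool; without it, it falls below the random median.

## Calibration

On a held-out calibration set, each barcode b gets a baseline error rate
E_b = 100 × (misclassified among reads predicted b) / (reads predicted b).
For a target accuracy A_t (percent), the confidence threshold T is 0 when
E_b ≤ 100 − A_t (the baseline already meets the target, including the
q < 0 branch), else the linear-interpolation q-quantile of the
*misclassified* reads' confidences with q = 1 − (100 − A_t)/E_b.
Confidences strictly above T are retained. The construction assumes that
correct reads rarely sit below T and that the confidence scores are well
calibrated; with the idealized confidence distributions the achieved
accuracy lands within 0.5 pp of the target, while end-to-end on a noisy
classifier (where Platt probabilities are imperfect) the observed accuracy
can undershoot a 99% target by one to two percentage points. Both the
target and the observed value are always reported side by side.

## Adaptive sampling simulation

Reads stream in 100 ms chunks (~300 samples at 3012 Hz). Live
classification buffers chunks until the poly(A) onset is confirmed (the
same detector, with the minimum plateau length reduced to two rolling
windows since the plateau need only be confirmed, not spanned), then
fingerprints the buffered adapter and classifies; the samples buffered at
decision time are the latency proxy. The balancer rejects a classified
read when its barcode's tally (adapters, reads, or bases — configurable)
exceeds `slack` (default 1.2) × the mean tally over barcodes seen,
recomputed at every decision. Two guards: no barcode is rejected before
its tally reaches `min_count` (default 10) — with a handful of
observations the empirical distribution is noise, and cold-start
rejections were observed to hit the *rare* barcode — and reads without a
confident identity (noise, QC fail, below cutoff) are always accepted,
so misclassification can never silently discard a sample. Rejection frees
the channel after the consumed samples plus a penalty (default ~0.5 s);
accepting consumes the full read. Adapter-only molecules (no ligated RNA)
are classified like any adapter but produce no sequencer output; read and
base tallies are corrected against that output. Imbalance is scored with
the Gini coefficient G = Σᵢⱼ|xᵢ − xⱼ| / (2n²·mean).

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` run entirely on simulated data:
the demultiplexing experiment uses the designed 12-barcode set with 400
training and 200 test reads per class; the training-set builder runs on
4 × 500 clean + 700 corrupted reads; the calibration demonstration uses a
4-barcode model at high noise (sd 22 pA, giving a baseline error rate
around 10%) with 250 training, 400 calibration and 400 test reads per
class — calibration needs a sizeable held-out set because it estimates a
per-barcode quantile of the misclassified confidences; the balancing
study uses 100 paired
(balanced vs control) runs of a 120:12 two-barcode mixture on 4 channels
with a 250 000-sample budget. Every stochastic component takes an explicit
seed, and fixed seeds give bit-identical signals, selections, models and
predictions.

## Limitations

- The simulator's k-mer levels are i.i.d. uniform, so adjacent adapter
  events are uncorrelated; real pore models have sequence-driven
  correlation and heteroscedastic event noise. Synthetic accuracies are
  therefore optimistic and the tests validate *mechanism and contracts*
  (monotonic degradation with noise, trade-off shapes, count conventions),
  not real-data performance.
- The boundary detector is a single LLR/plateau method with a hook for
  external boundary files; it does not reproduce a learned adapter
  detector, and its poly(A) band assumes the RNA002-like current scale.
- Bidirectional k-mer filtering uses a simple level-vs-reversed-level
  tolerance; the tolerance default is a placeholder in the absence of a
  published criterion.
- The balancer's decision rule (slack × mean with a warm-up count) is one
  concretization of dynamic thresholding; no MinKNOW/Read Until
  connectivity is implemented, only the streaming interface a live adapter
  would need.
- POD5 input requires the optional `pod5` package; the TSV table and FAST5
  are the self-contained paths.
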
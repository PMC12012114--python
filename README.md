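# dtwdemux

Signal-level barcode design, demultiplexing and adaptive balancing for
nanopore **direct RNA sequencing** (dRNA-seq).

In dRNA-seq, native RNA is threaded 3'→5' through a pore behind a ligated
DNA adapter. The adapter's 3' end can carry a customizable 18-nt barcode,
but basecallers cannot read DNA sequenced in that direction — so `dtwdemux`
classifies reads **directly from the raw current trace**, before (or
instead of) basecalling:

1. **Fingerprint** — locate the DNA-adapter/poly(A) boundary (the poly(A)
   tail is a long, low-variance plateau), over-segment the adapter into
   events with a Welch *t*-statistic changepoint scan (~10% more segments
   than expected bases), normalize robustly (median/MAD), and keep the
   **last 25 segment means** `s` — the temporal tail of the adapter, where
   the barcode sits.
2. **Classify** — a one-vs-one SVM over the Dynamic-Time-Warping kernel

   `K(s₁, s₂) = exp(−γ · D_DTW(s₁, s₂))`, γ = 1.2,

   with Platt-scaled probabilities. Each prediction carries a **confidence
   score** (gap between the top two class probabilities); low-confidence
   reads are *unclassified*, and an explicit NOISE class absorbs signal
   artefacts (stalled/blocked pores, truncated adapters, missing poly(A)).
3. **Design** — build barcode sets de novo by maximizing pairwise DTWD:
   wave-like target patterns → per-target sequence search through a k-mer
   current model (restricted to direction-robust k-mers) → **Maximal
   Diversity Problem** selection,

   `max Σᵢ<ⱼ D_DTW(sᵢ, sⱼ) δ(i)δ(j)  s.t.  Σ δ(i) = k`,

   solved greedily with local exchange (an exhaustive search over
   C(4¹⁸, 12) ≈ 2.3×10¹²¹ sets being out of the question).
4. **Balance** — simulate barcode-specific adaptive sampling: classify each
   read the moment its poly(A) onset appears in the streamed chunks, then
   reject reads of over-represented barcodes (dynamic threshold: tally >
   slack × mean tally) so that a skewed pool yields even coverage (lower
   Gini coefficient) and low-abundance samples are enriched.

A seeded squiggle **simulator** (adapter levels from a k-mer model,
negative-binomial dwell times, Gaussian noise, poly(A) plateau, RNA-body
random walk, plus corruption operators for the noise class) makes the whole
stack testable with no external data.

## Worked example

```python
import dtwdemux as dx

model = dx.synthetic_kmer_model()            # bundled deterministic pore model
design = dx.design_barcodes(model, seed=1)   # 12 barcodes, pool of 600
print(len(design.barcodes), round(design.min_pairwise_dtwd, 2))
# 12 2.04

train = dx.simulate_fingerprints(design.barcodes, 400, kmer_model=model,
                                 sim_cfg=dx.SimConfig(seed=100))
test  = dx.simulate_fingerprints(design.barcodes, 200, kmer_model=model,
                                 sim_cfg=dx.SimConfig(seed=200))
clf = dx.DtwKernelSvmClassifier(gamma=1.2, C=1.0, random_state=0)
clf.fit(train.fingerprints, train.labels)
pred = clf.classify(test.fingerprints, conf_cutoff=0.5)
m = dx.evaluate(pred, test.labels)
print(round(m["accuracy"], 3), round(m["unclassified_pct"], 1))
# 1.0 1.3
```

The two printed lines say: the designed 12-barcode set keeps a minimum
pairwise signal distance of ~2 robust units, and at a confidence cutoff of
0.5 the classifier assigns 98.7% of test reads with perfect accuracy on
this synthetic draw.

The same flow is available from the shell:

```bash
dtwdemux design -k 12 --out barcodes.fasta --seed 1
dtwdemux simulate --barcodes barcodes.fasta --n-per-barcode 400 --out reads.tsv --seed 2
dtwdemux fingerprint --signals reads.tsv --truth reads.tsv.truth.tsv --out fp.tsv
dtwdemux train --fingerprints fp.tsv --out model/
dtwdemux demux --model model/ --signals reads.tsv --conf-cutoff 0.5 --out pred.tsv
dtwdemux evaluate --predictions pred.tsv --truth reads.tsv.truth.tsv --out metrics.json
```

Every command writes a JSON run manifest beside its outputs.

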
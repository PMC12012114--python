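"""Convenience builders for labeled fingerprint datasets.

These tie the simulator to the preprocessing front-end so classifier
experiments can be expressed in a couple of lines; signals are processed
one read at a time and discarded, keeping memory proportional to the
number of fingerprints, not samples.
"""

from __future__ import annotations

import numpy as np

from .kmers import KmerModel, synthetic_kmer_model
from .selection import LabeledFingerprintSet
from .signal import SegmentationConfig, extract_fingerprint
from .simulate import SimConfig, simulate_dataset

__all__ = ["simulate_fingerprints"]


def simulate_fingerprints(
    barcodes: dict[str, str] | list[str],
    n_per_barcode: int,
    noise_fraction: float = 0.0,
    sim_cfg: SimConfig | None = None,
    seg_cfg: SegmentationConfig | None = None,
    kmer_model: KmerModel | None = None,
    keep_failed: bool = False,
    corruption_ops: tuple[str, ...] | None = None,
) -> LabeledFingerprintSet:
    """Simulate reads and return their fingerprints with truth labels.

    QC-failed reads (no detectable poly(A), too-short adapter) are dropped
    unless ``keep_failed`` is set, in which case they appear as NaN rows.
    """
    sim_cfg = sim_cfg or SimConfig()
    seg_cfg = seg_cfg or SegmentationConfig()
    kmer_model = kmer_model or synthetic_kmer_model()
    kwargs = {} if corruption_ops is None else {"corruption_ops": corruption_ops}
    reads = simulate_dataset(barcodes, n_per_barcode, noise_fraction, sim_cfg, kmer_model, **kwargs)

    rows, labels, ids = [], [], []
    for read in reads:
        fp = extract_fingerprint(read, seg_cfg)
        if fp.ok:
            rows.append(fp.values)
        elif keep_failed:
            rows.append(np.full(seg_cfg.fingerprint_len, np.nan))
        else:
            continue
        labels.append(read.truth.barcode_label)
        ids.append(read.read_id)
    return LabeledFingerprintSet(np.asarray(rows), np.asarray(labels), np.asarray(ids))
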
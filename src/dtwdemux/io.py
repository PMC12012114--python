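"""File formats and run manifests.

The zero-dependency reference format for raw signal is a plain TSV table
(read_id TAB sample_rate TAB comma-separated float samples).  FAST5 input
is supported read-only through h5py.  POD5 requires the optional ``pod5``
package and raises a clear error when it is absent.  Fingerprints,
predictions and truth labels travel as TSV; barcodes as FASTA.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from .selection import LabeledFingerprintSet
from .simulate import RawRead, ReadTruth

__all__ = [
    "read_signals",
    "write_signals_tsv",
    "write_truth_tsv",
    "write_fingerprints_tsv",
    "read_fingerprints_tsv",
    "write_fasta",
    "read_fasta",
    "write_manifest",
]

logger = logging.getLogger("dtwdemux")
if not logger.handlers:  # log to stderr only; stdout stays pipeline-safe
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)


def write_signals_tsv(reads, path: str | Path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            samples = ",".join(f"{x:.6f}" for x in read.signal)
            fh.write(f"{read.read_id}\t{read.sample_rate:g}\t{samples}\n")


def _read_signals_tsv(path: Path):
    with open(path) as fh:
        any_row = False
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
            any_row = True
            signal = np.fromstring(fields[2], sep=",")
            yield RawRead(fields[0], signal, float(fields[1]))
        if not any_row:
            logger.warning("%s: no reads found", path)


def _read_signals_fast5(path: Path):
    import h5py

    with h5py.File(path, "r") as f:
        groups = [k for k in f.keys() if k.startswith("read_")]
        for name in groups:
            grp = f[name]
            raw = grp["Raw/Signal"][:]
            rate = float(grp["channel_id"].attrs.get("sampling_rate", 0.0)) if "channel_id" in grp else 0.0
            read_id = grp["Raw"].attrs.get("read_id", name[5:])
            if isinstance(read_id, bytes):
                read_id = read_id.decode()
            yield RawRead(str(read_id), raw.astype(np.float64), rate)


def read_signals(path: str | Path):
    """Iterate RawRead from a raw-signal TSV, FAST5 or POD5 file (by extension)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tsv", ".txt"):
        yield from _read_signals_tsv(path)
    elif suffix == ".fast5":
        yield from _read_signals_fast5(path)
    elif suffix == ".pod5":
        try:
            import pod5  # noqa: F401
        except ImportError as exc:
            raise RuntimeError("POD5 input requires the optional 'pod5' package") from exc
        import pod5 as _pod5

        with _pod5.Reader(path) as reader:
            for rec in reader.reads():
                yield RawRead(str(rec.read_id), rec.signal.astype(np.float64), float(rec.run_info.sample_rate))
    else:
        raise ValueError(f"unknown raw-signal format for {path} (detected extension {suffix!r})")


def write_truth_tsv(reads, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tlabel\tadapter_end_idx\tpolyA_end_idx\n")
        for read in reads:
            t = read.truth or ReadTruth("NONE", 0, 0)
            fh.write(f"{read.read_id}\t{t.barcode_label}\t{t.adapter_end_idx}\t{t.polyA_end_idx}\n")


def write_fingerprints_tsv(data: LabeledFingerprintSet, path: str | Path) -> None:
    n = data.fingerprints.shape[1]
    cols = {"read_id": data.read_ids, "label": data.labels}
    for j in range(n):
        cols[f"f{j + 1}"] = data.fingerprints[:, j]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_fingerprints_tsv(path: str | Path) -> LabeledFingerprintSet:
    df = pd.read_csv(path, sep="\t")
    fcols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
    return LabeledFingerprintSet(
        df[fcols].to_numpy(dtype=float),
        df["label"].to_numpy() if "label" in df else np.array(["NA"] * len(df)),
        df["read_id"].astype(str).to_numpy(),
    )


def write_fasta(barcodes: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in barcodes.items():
            fh.write(f">{name}\n{seq}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    name = None
    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            out[name] = ""
        elif name is not None:
            out[name] += line.strip()
    return out


def write_manifest(path: str | Path, command: str, params: dict, inputs: list[str] | None = None) -> None:
    """JSON run manifest written beside every output for reproducibility."""
    from . import __version__

    payload = {
        "tool": "dtwdemux",
        "version": __version__,
        "command": command,
        "parameters": params,
        "inputs": inputs or [],
    }
    blob = json.dumps(payload, sort_keys=True, default=str)
    payload["config_hash"] = hashlib.sha256(blob.encode()).hexdigest()[:16]
    Path(path).write_text(json.dumps(payload, indent=2, default=str))
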
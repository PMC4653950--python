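"""Readers and writers for the on-disk formats (FASTA, BED6, bedGraph, TSV).

All coordinates are written 0-based half-open.  FASTA reading goes through
pyfaidx; BED/TSV go through pandas.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from pyfaidx import Fasta

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def write_fasta(path: str | Path, sequences: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_bed_tags(path: str | Path, tags: pd.DataFrame, chrom: str = "chrSim") -> None:
    """Write per-position tag counts as BED6 (count in the score column)."""
    out = pd.DataFrame(
        {
            "chrom": chrom,
            "start": tags["pos"].to_numpy(),
            "end": tags["pos"].to_numpy() + 1,
            "name": "tag",
            "score": tags["count"].to_numpy(),
            "strand": tags["strand"].to_numpy(),
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed_tags(path: str | Path) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", header=None, names=BED6_COLUMNS)
    return pd.DataFrame(
        {"pos": bed["start"], "strand": bed["strand"], "count": bed["score"]}
    )


def write_bed_reads(path: str | Path, reads: pd.DataFrame, chrom: str = "chrSim") -> None:
    """Write read 5'-anchor positions as BED6 (one line per read)."""
    out = pd.DataFrame(
        {
            "chrom": chrom,
            "start": reads["pos"].to_numpy(),
            "end": reads["pos"].to_numpy() + 1,
            "name": "read",
            "score": 0,
            "strand": reads["strand"].to_numpy(),
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed_reads(path: str | Path) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", header=None, names=BED6_COLUMNS)
    return pd.DataFrame({"pos": bed["start"], "strand": bed["strand"]})


def write_bedgraph(path: str | Path, values: np.ndarray, chrom: str = "chrSim") -> None:
    """Write a dense per-position track, collapsing runs of equal values."""
    v = np.asarray(values)
    change = np.flatnonzero(np.diff(v) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [len(v)]))
    df = pd.DataFrame(
        {"chrom": chrom, "start": starts, "end": ends, "value": v[starts]}
    )
    df = df[df["value"] != 0]
    df.to_csv(path, sep="\t", header=False, index=False)


def write_tsv(path: str | Path, frame: pd.DataFrame, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index)


def sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path: str | Path, params: dict, files: list[str | Path]) -> dict:
    manifest = {
        "parameters": params,
        "files": {str(f): sha256(f) for f in files},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
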
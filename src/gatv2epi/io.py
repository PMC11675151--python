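"""Readers and writers for the plain-text formats used throughout the package.

Conventions
-----------
* BED files (enhancers, marker peak tracks) are 0-based half-open, tab
  separated, without header.
* Marker tracks are narrowPeak-like: seven columns
  ``chrom start end name score strand signalValue`` with the enrichment
  magnitude in column 7.
* ``tss.tsv`` stores 1-based TSS positions (annotation convention); the
  reader converts to 0-based coordinates, the writer converts back, so the
  on-disk file round-trips bit-identically.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

#: Fixed marker row order of the feature matrix.
MARKERS = ("H3K27me3", "H3K36me3", "H3K4me1", "H3K4me3", "H3K9me3", "CTCF", "DNase")

_ENHANCER_COLS = ["chrom", "start", "end", "id"]
_TRACK_COLS = ["chrom", "start", "end", "name", "score", "strand", "signal"]


def read_enhancer_bed(path) -> pd.DataFrame:
    """Read a 4-column enhancer BED file into ``chrom/start/end/id``."""
    df = pd.read_csv(path, sep="\t", header=None, names=_ENHANCER_COLS,
                     dtype={"chrom": str, "start": int, "end": int, "id": str})
    return df


def write_enhancer_bed(df: pd.DataFrame, path) -> None:
    df[_ENHANCER_COLS].to_csv(path, sep="\t", header=False, index=False)


def read_tss_table(path) -> pd.DataFrame:
    """Read a TSS TSV (``gene_id chrom pos strand``, 1-based positions).

    Returns a frame with ``pos`` converted to 0-based coordinates.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str,
                                            "pos": int, "strand": str})
    missing = {"gene_id", "chrom", "pos", "strand"} - set(df.columns)
    if missing:
        raise ValueError(f"tss table missing columns: {sorted(missing)}")
    df = df.copy()
    df["pos"] = df["pos"] - 1
    return df


def write_tss_table(df: pd.DataFrame, path) -> None:
    out = df[["gene_id", "chrom", "pos", "strand"]].copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", index=False)


def read_pairs_table(path) -> pd.DataFrame:
    """Read a BENGI-style pair table (``enhancer_id gene_id label`` + extras)."""
    df = pd.read_csv(path, sep="\t", dtype={"enhancer_id": str, "gene_id": str})
    missing = {"enhancer_id", "gene_id", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"pairs table missing columns: {sorted(missing)}")
    df["label"] = df["label"].astype(int)
    return df


def write_pairs_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_track_bed(path) -> pd.DataFrame:
    """Read a narrowPeak-like marker track (signalValue in column 7)."""
    df = pd.read_csv(path, sep="\t", header=None, names=_TRACK_COLS,
                     dtype={"chrom": str, "start": int, "end": int, "name": str,
                            "score": int, "strand": str, "signal": float})
    return df


def write_track_bed(df: pd.DataFrame, path) -> None:
    out = df.copy()
    if "name" not in out.columns:
        out["name"] = "."
    if "score" not in out.columns:
        out["score"] = 0
    if "strand" not in out.columns:
        out["strand"] = "."
    out["signal"] = out["signal"].map(lambda v: f"{v:.6f}")
    out[_TRACK_COLS].to_csv(path, sep="\t", header=False, index=False)


def read_samples_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"enhancer_id": str, "promoter_id": str,
                                            "chrom": str})
    df["label"] = df["label"].astype(int)
    return df


def write_samples_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tracks_dir(directory) -> dict[str, pd.DataFrame]:
    """Load all seven marker tracks (``<marker>.bed``) from a directory."""
    directory = Path(directory)
    tracks = {}
    for marker in MARKERS:
        p = directory / f"{marker}.bed"
        if not p.exists():
            raise FileNotFoundError(f"missing marker track: {p}")
        tracks[marker] = read_track_bed(p)
    return tracks


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
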
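"""Positive selection, promoter mapping, distance filtering and balanced
negative sampling for enhancer--promoter candidate pairs.

The pipeline turns a BENGI-style enhancer--gene table into a balanced set of
enhancer--promoter samples:

1. keep experimentally supported (label 1) pairs, collapsing duplicates;
2. map each gene to a promoter interval, TSS -1500/+500 bp by strand;
3. keep pairs whose enhancer-midpoint-to-TSS distance lies in [42 kb, 500 kb];
4. for each positive enhancer, sample promoters in the same distance range
   that it is not known to interact with, matching the positive count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

DISTANCE_LO = 42_000
DISTANCE_HI = 500_000

PROMOTER_UPSTREAM = 1500
PROMOTER_DOWNSTREAM = 500


class ElementType(str, Enum):
    ENHANCER = "enhancer"
    PROMOTER = "promoter"


@dataclass(frozen=True)
class RegulatoryElement:
    """An enhancer or promoter interval (0-based half-open)."""
    id: str
    etype: ElementType
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"{self.id}: start must be < end")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass
class EPPair:
    """A candidate edge between an enhancer and a promoter."""
    enhancer_id: str
    promoter_id: str
    label: int
    distance: float
    chrom: str
    split: str = "unassigned"


def select_positives(raw_pairs: pd.DataFrame) -> pd.DataFrame:
    """Keep label==1 rows and collapse duplicate (enhancer, gene) pairs."""
    missing = {"enhancer_id", "gene_id", "label"} - set(raw_pairs.columns)
    if missing:
        raise ValueError(f"pair table missing columns: {sorted(missing)}")
    pos = raw_pairs[raw_pairs["label"] == 1]
    pos = pos.drop_duplicates(subset=["enhancer_id", "gene_id"], keep="first")
    return pos.reset_index(drop=True)


def map_gene_to_promoter(tss: pd.DataFrame, chrom_sizes: dict) -> pd.DataFrame:
    """Map each gene's TSS to a promoter interval.

    '+' strand genes get ``[tss-1500, tss+500)``; '-' strand genes the
    mirror image ``[tss-500, tss+1500)``, so the interval always covers
    1500 bp on the 5' side of the reading direction.  Intervals are clamped
    to chromosome bounds.  When a gene has several TSS rows the first one
    is used (canonical TSS).
    """
    df = tss.drop_duplicates(subset=["gene_id"], keep="first").copy()
    unknown = set(df.chrom) - set(chrom_sizes)
    if unknown:
        raise KeyError(f"unknown chromosomes in TSS table: {sorted(unknown)}")
    up = np.where(df.strand == "+", PROMOTER_UPSTREAM, PROMOTER_DOWNSTREAM)
    down = np.where(df.strand == "+", PROMOTER_DOWNSTREAM, PROMOTER_UPSTREAM)
    size = df.chrom.map(chrom_sizes).to_numpy()
    start = np.maximum(df.pos.to_numpy() - up, 0)
    end = np.minimum(df.pos.to_numpy() + down, size)
    out = pd.DataFrame({
        "gene_id": df.gene_id.to_numpy(),
        "chrom": df.chrom.to_numpy(),
        "start": start.astype(int),
        "end": end.astype(int),
        "strand": df.strand.to_numpy(),
        "tss": df.pos.to_numpy().astype(int),
    })
    return out.reset_index(drop=True)


def ep_distance(enh_start: int, enh_end: int, tss: int) -> float:
    """Distance between an enhancer and a promoter: |enhancer midpoint - TSS|.

    The midpoint anchor is stable under enhancer-length variation; trans
    pairs (different chromosomes) must be rejected by the caller.
    """
    return abs((enh_start + enh_end) / 2.0 - tss)


def filter_by_distance(pairs: pd.DataFrame, lo: int = DISTANCE_LO,
                       hi: int = DISTANCE_HI) -> pd.DataFrame:
    """Keep pairs with lo <= distance <= hi (both bounds inclusive)."""
    keep = (pairs["distance"] >= lo) & (pairs["distance"] <= hi)
    return pairs[keep].reset_index(drop=True)


def sample_negatives(positives: pd.DataFrame, promoters: pd.DataFrame,
                     enhancers: pd.DataFrame, lo: int = DISTANCE_LO,
                     hi: int = DISTANCE_HI, seed: int = 0) -> pd.DataFrame:
    """Balanced negative sampling.

    For every enhancer in the positive set, candidate promoters are those on
    the same chromosome within ``[lo, hi]`` of its midpoint that it is not
    known to interact with.  Each enhancer receives a quota equal to its
    positive count; shortfalls (enhancers with too few candidates) are
    redistributed at random among enhancers with spare candidates, so the
    negative total matches the positive total whenever candidates suffice.
    Sampling is without replacement and deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    enh = enhancers.set_index("id")
    known = set(zip(positives.enhancer_id, positives.gene_id))

    candidates: dict[str, list[str]] = {}
    quota: dict[str, int] = {}
    for eid, grp in positives.groupby("enhancer_id", sort=True):
        if eid not in enh.index:
            raise KeyError(f"enhancer {eid} missing from annotation")
        row = enh.loc[eid]
        mid = (row.start + row.end) / 2.0
        proms = promoters[promoters.chrom == row.chrom]
        d = np.abs(proms.tss.to_numpy() - mid)
        ok = (d >= lo) & (d <= hi)
        cands = [g for g in proms.gene_id.to_numpy()[ok]
                 if (eid, g) not in known]
        if not cands:
            warnings.warn(f"enhancer {eid} has no negative candidates; skipped")
            continue
        candidates[eid] = sorted(cands)
        quota[eid] = len(grp)

    chosen: list[tuple[str, str]] = []
    spare: dict[str, list[str]] = {}
    deficit = len(positives)  # total quota: one negative per positive
    for eid in sorted(candidates):
        cands = candidates[eid]
        take = min(quota[eid], len(cands))
        picked = list(rng.choice(cands, size=take, replace=False)) if take else []
        chosen.extend((eid, g) for g in picked)
        leftover = [g for g in cands if g not in set(picked)]
        if leftover:
            spare[eid] = leftover
    deficit -= len(chosen)

    # redistribute the shortfall among enhancers that still have candidates
    while deficit > 0 and spare:
        eids = sorted(spare)
        eid = eids[int(rng.integers(len(eids)))]
        pool = spare[eid]
        g = pool.pop(int(rng.integers(len(pool))))
        chosen.append((eid, g))
        if not pool:
            del spare[eid]
        deficit -= 1

    prom_idx = promoters.set_index("gene_id")
    rows = []
    for eid, gid in chosen:
        row = enh.loc[eid]
        tss = int(prom_idx.loc[gid, "tss"])
        rows.append((eid, gid, 0, ep_distance(row.start, row.end, tss), row.chrom))
    return pd.DataFrame(rows, columns=["enhancer_id", "promoter_id", "label",
                                       "distance", "chrom"])


def prepare_samples(raw_pairs: pd.DataFrame, enhancers: pd.DataFrame,
                    tss: pd.DataFrame, chrom_sizes: dict,
                    lo: int = DISTANCE_LO, hi: int = DISTANCE_HI,
                    seed: int = 0):
    """Run the full preprocessing chain.

    Returns ``(samples, report)`` where ``samples`` has one row per
    candidate pair (both labels) and ``report`` counts each step.
    """
    positives = select_positives(raw_pairs)
    promoters = map_gene_to_promoter(tss, chrom_sizes)

    enh = enhancers.set_index("id")
    prom = promoters.set_index("gene_id")
    missing_e = set(positives.enhancer_id) - set(enh.index)
    missing_g = set(positives.gene_id) - set(prom.index)
    if missing_e or missing_g:
        raise KeyError(f"unannotated ids in pair table: "
                       f"{sorted(missing_e) + sorted(missing_g)}")

    rows = []
    for eid, gid in zip(positives.enhancer_id, positives.gene_id):
        e = enh.loc[eid]
        p = prom.loc[gid]
        if e.chrom != p.chrom:
            continue  # trans pairs unsupported
        rows.append((eid, gid, 1, ep_distance(e.start, e.end, int(p.tss)), e.chrom))
    pos = pd.DataFrame(rows, columns=["enhancer_id", "promoter_id", "label",
                                      "distance", "chrom"])
    pos_filtered = filter_by_distance(pos, lo, hi)
    neg = sample_negatives(
        pos_filtered.rename(columns={"promoter_id": "gene_id"}),
        promoters, enhancers, lo, hi, seed)
    samples = pd.concat([pos_filtered, neg], ignore_index=True)
    samples["split"] = "unassigned"
    report = {
        "raw_rows": int(len(raw_pairs)),
        "positives_selected": int(len(positives)),
        "positives_mapped": int(len(pos)),
        "positives_after_distance_filter": int(len(pos_filtered)),
        "negatives_sampled": int(len(neg)),
        "distance_lo": lo,
        "distance_hi": hi,
        "distance_metric": "enhancer_midpoint_to_tss",
        "seed": seed,
    }
    return samples, report
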
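"""Windowed epigenomic feature matrices (7 markers x 21 windows).

Each regulatory element is described by the element interval itself (window
0) plus ten abutting 2 kb windows on each side.  Within every window, other
annotated elements are masked out and the remaining bases aggregate peak
``signalValue`` as a per-base (overlap-length-weighted) mean.  Normalization
is a per-marker z-score followed by min--max rescaling to [0, 1], with
statistics fitted on the training split only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MARKERS


@dataclass(frozen=True)
class WindowScheme:
    window_size: int = 2000
    n_flank: int = 10

    @property
    def n_windows(self) -> int:
        return 2 * self.n_flank + 1

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.n_flank, self.n_flank + 1)


@dataclass
class NormalizationStats:
    """Per-marker z-score + min-max statistics, fitted on one split."""
    mean: np.ndarray   # (7,)
    sd: np.ndarray     # (7,)
    zmin: np.ndarray   # (7,)
    zmax: np.ndarray   # (7,)
    fitted_on: str = "train"

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "sd": self.sd.tolist(),
                "zmin": self.zmin.tolist(), "zmax": self.zmax.tolist(),
                "fitted_on": self.fitted_on}

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationStats":
        return cls(np.asarray(d["mean"]), np.asarray(d["sd"]),
                   np.asarray(d["zmin"]), np.asarray(d["zmax"]),
                   d.get("fitted_on", "train"))


def build_windows(start: int, end: int, scheme: WindowScheme,
                  chrom_length: int) -> np.ndarray:
    """Return the 21 ordered window intervals for an element.

    Window 0 is the element itself (variable length); flank windows are
    ``window_size`` wide and abut outward from the element boundaries.
    Windows are clamped to ``[0, chrom_length)``; fully out-of-range windows
    collapse to zero width.  Always returns shape ``(n_windows, 2)``.
    """
    w = scheme.window_size
    wins = []
    for off in scheme.offsets:
        if off == 0:
            a, b = start, end
        elif off < 0:
            a = start + off * w
            b = a + w
        else:
            b = end + off * w
            a = b - w
        a = min(max(a, 0), chrom_length)
        b = min(max(b, 0), chrom_length)
        if b < a:
            b = a
        wins.append((a, b))
    return np.asarray(wins, dtype=np.int64)


def subtract_intervals(window: tuple, others: np.ndarray) -> list[tuple[int, int]]:
    """Parts of ``window`` not covered by any interval in ``others``.

    ``others`` is an (n, 2) array; overlapping blockers are handled by a
    sweep over their merged extents.
    """
    a, b = int(window[0]), int(window[1])
    if b <= a:
        return []
    if len(others) == 0:
        return [(a, b)]
    ov = others[(others[:, 0] < b) & (others[:, 1] > a)]
    if len(ov) == 0:
        return [(a, b)]
    ov = ov[np.argsort(ov[:, 0], kind="mergesort")]
    out = []
    cursor = a
    for s, e in ov:
        s, e = int(max(s, a)), int(min(e, b))
        if s > cursor:
            out.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < b:
        out.append((cursor, b))
    return out


def mask_elements(window: tuple, other_elements: np.ndarray) -> list[tuple[int, int]]:
    """Mask other annotated elements out of an analysis window.

    ``other_elements`` must exclude the focal element itself.  Returns the
    retained sub-intervals; signal aggregation uses only these.
    """
    return subtract_intervals(window, np.asarray(other_elements).reshape(-1, 2))


class _SortedTrack:
    """A coordinate-sorted peak track supporting fast overlap queries."""

    def __init__(self, starts: np.ndarray, ends: np.ndarray, signal: np.ndarray):
        order = np.argsort(starts, kind="mergesort")
        self.starts = starts[order]
        self.ends = ends[order]
        self.signal = signal[order]
        # running max of ends lets us lower-bound the overlap scan even when
        # peak ends are not monotone in start order
        self.cummax_end = np.maximum.accumulate(self.ends) if len(self.ends) else self.ends

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "_SortedTrack":
        return cls(df["start"].to_numpy(np.int64), df["end"].to_numpy(np.int64),
                   df["signal"].to_numpy(np.float64))

    def weighted_sum(self, a: int, b: int) -> float:
        """Integral of per-base stacked signal over [a, b)."""
        if b <= a or len(self.starts) == 0:
            return 0.0
        hi = np.searchsorted(self.starts, b, side="left")
        lo = np.searchsorted(self.cummax_end[:hi], a, side="right")
        if lo >= hi:
            return 0.0
        s = self.starts[lo:hi]
        e = self.ends[lo:hi]
        v = self.signal[lo:hi]
        ov = np.minimum(e, b) - np.maximum(s, a)
        ov = np.maximum(ov, 0)
        return float(np.dot(ov, v))


def aggregate_signal(track, intervals) -> float:
    """Overlap-length-weighted mean signal over an interval set.

    Equivalent to the per-base mean of stacked peak signal across the
    intervals, with uncovered bases contributing 0.  Returns 0.0 for an
    empty interval set or when no peak overlaps.
    """
    if isinstance(track, pd.DataFrame):
        track = _SortedTrack.from_frame(track)
    total_len = 0
    total = 0.0
    for a, b in intervals:
        a, b = int(a), int(b)
        if b <= a:
            continue
        total_len += b - a
        total += track.weighted_sum(a, b)
    if total_len == 0:
        return 0.0
    return total / total_len


def featurize(element, tracks: dict, scheme: WindowScheme, chrom_length: int,
              other_elements=None, stats: "NormalizationStats | None" = None) -> np.ndarray:
    """Build one element's (7, 21) feature matrix.

    ``element`` is anything with ``chrom``, ``start``, ``end`` attributes;
    ``tracks`` maps every marker name to its peak table (or pre-sorted
    track); rows follow :data:`gatv2epi.io.MARKERS`, columns run window
    -10..+10.  If ``stats`` is given the matrix is normalized.
    """
    missing = [m for m in MARKERS if m not in tracks]
    if missing:
        raise KeyError(f"missing marker tracks: {missing}")
    wins = build_windows(element.start, element.end, scheme, chrom_length)
    if other_elements is None:
        masked = [[(int(a), int(b))] if b > a else [] for a, b in wins]
    else:
        others = np.asarray(other_elements).reshape(-1, 2)
        masked = [mask_elements(w, others) for w in wins]
    mat = np.zeros((len(MARKERS), scheme.n_windows))
    for mi, marker in enumerate(MARKERS):
        track = tracks[marker]
        if isinstance(track, pd.DataFrame):
            track = _SortedTrack.from_frame(track)
        for wi, ivs in enumerate(masked):
            mat[mi, wi] = aggregate_signal(track, ivs)
    if stats is not None:
        mat = apply_normalization(mat, stats)
    return mat


def featurize_elements(elements: pd.DataFrame, tracks: dict,
                       scheme: WindowScheme, chrom_sizes: dict,
                       mask: bool = True) -> dict[str, np.ndarray]:
    """Feature matrices for a whole annotation table.

    ``elements`` needs columns ``id chrom start end``; all elements on the
    same chromosome mask one another.  Returns ``{element_id: (7, 21)}``.
    """
    out: dict[str, np.ndarray] = {}
    for chrom, grp in elements.groupby("chrom", sort=True):
        size = chrom_sizes[chrom]
        ivs = grp[["start", "end"]].to_numpy(np.int64)
        chrom_tracks = {
            m: _SortedTrack.from_frame(df[df["chrom"] == chrom])
            for m, df in tracks.items()
        }
        for i, row in enumerate(grp.itertuples(index=False)):
            others = np.delete(ivs, i, axis=0) if mask else None
            out[row.id] = featurize(row, chrom_tracks, scheme, size,
                                    other_elements=others)
    return out


def fit_normalization(matrices, fitted_on: str = "train") -> NormalizationStats:
    """Fit per-marker z-score then min-max statistics on training matrices.

    Statistics pool all windows of all training elements per marker.  A
    constant marker (sd == 0) later maps to 0.0 everywhere.
    """
    mats = np.asarray(list(matrices), dtype=float)
    if mats.ndim != 3 or len(mats) < 2:
        raise ValueError("need at least 2 training matrices")
    per_marker = mats.transpose(1, 0, 2).reshape(mats.shape[1], -1)
    mean = per_marker.mean(axis=1)
    sd = per_marker.std(axis=1)
    safe_sd = np.where(sd > 0, sd, 1.0)
    z = (per_marker - mean[:, None]) / safe_sd[:, None]
    z[sd == 0] = 0.0
    return NormalizationStats(mean=mean, sd=sd, zmin=z.min(axis=1),
                              zmax=z.max(axis=1), fitted_on=fitted_on)


def apply_normalization(matrix: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    """Normalize a (7, 21) matrix into [0, 1] using fitted statistics.

    Values outside the training range are clipped; constant markers map
    to 0.
    """
    matrix = np.asarray(matrix, dtype=float)
    safe_sd = np.where(stats.sd > 0, stats.sd, 1.0)
    z = (matrix - stats.mean[:, None]) / safe_sd[:, None]
    z[stats.sd == 0] = 0.0
    span = stats.zmax - stats.zmin
    safe_span = np.where(span > 0, span, 1.0)
    out = (z - stats.zmin[:, None]) / safe_span[:, None]
    out[span == 0] = 0.0
    return np.clip(out, 0.0, 1.0)
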
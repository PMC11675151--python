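"""Self-contained synthetic fixtures for the EPI prediction pipeline.

The generator emulates the statistical structure the pipeline assumes on real
enhancer--promoter data:

* non-overlapping regulatory elements placed along toy chromosomes, with a
  clear margin so that every element carries 21 non-clamped 2 kb windows;
* a planted interaction network mixing one-to-one, one-to-many and
  many-to-many components (most enhancers contact only one or two promoters,
  a minority form denser clusters);
* positive-pair genomic distances that decay roughly exponentially within
  the admissible range, mimicking the decay of 3D contact frequency with
  linear distance;
* seven narrowPeak-like marker tracks in which elements participating in a
  true interaction carry elevated signal in their central windows (window 0
  strongest, decaying linearly out to +/-2), on top of Gaussian noise.

Everything is deterministic under ``SyntheticConfig.seed`` and round-trips
bit-identically through :mod:`gatv2epi.io`.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .sample_prep import map_gene_to_promoter

logger = logging.getLogger(__name__)

_TOPOLOGIES = ("one_to_one", "one_to_many", "many_to_many")


@dataclass
class SyntheticConfig:
    """Study conditions of the synthetic fixture.

    ``component_topology`` gives mixing weights for planted component
    shapes; they must sum to 1.  ``signal_effect`` is the mean signal
    elevation planted at truly interacting elements (in signal units, i.e.
    the same units as ``baseline_signal`` and ``noise_sd``).
    ``distance_decay`` (bp) is the scale of the exponential preference for
    nearby promoters when wiring positive pairs.
    """

    n_chromosomes: int = 2
    chrom_length: int = 16_000_000
    # the promoter universe is larger than the interacting subset, as in
    # real annotation-vs-benchmark proportions
    n_enhancers: int = 260
    n_promoters: int = 460
    component_topology: dict = field(default_factory=lambda: {
        "one_to_one": 0.45, "one_to_many": 0.35, "many_to_many": 0.2})
    distance_range: tuple = (42_000, 500_000)
    signal_effect: float = 1.5
    noise_sd: float = 0.3
    seed: int = 0
    interacting_fraction: float = 0.8
    enhancer_length_range: tuple = (200, 2000)
    baseline_signal: float = 1.0
    distance_decay: float = 70_000.0
    # Elements cluster in regulatory domains separated by gaps wider than
    # the maximum pairing distance, giving the archipelago component
    # structure real EPI networks show.
    domain_length: int = 1_000_000
    domain_gap: int = 700_000
    window_size: int = 2000
    n_flank: int = 10

    def __post_init__(self):
        total = sum(self.component_topology.get(k, 0.0) for k in _TOPOLOGIES)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("component_topology weights must sum to 1")
        if self.noise_sd <= 0 or self.signal_effect < 0:
            raise ValueError("noise_sd must be > 0 and signal_effect >= 0")
        if self.chrom_length < 2 * self.margin + 10 * self.window_size:
            raise ValueError("chrom_length too small for the window scheme")
        if not self.domains(0):
            raise ValueError("chrom_length too small to hold one domain")

    @property
    def margin(self) -> int:
        """Clearance from chromosome ends: 21 window-widths."""
        return (2 * self.n_flank + 1) * self.window_size

    def domains(self, _chrom_index: int) -> list[tuple[int, int]]:
        """Regulatory-domain intervals tiling a chromosome."""
        out = []
        pos = self.margin
        while pos + self.domain_length <= self.chrom_length - self.margin:
            out.append((pos, pos + self.domain_length))
            pos += self.domain_length + self.domain_gap
        return out

    def chrom_names(self):
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["distance_range"] = list(self.distance_range)
        d["enhancer_length_range"] = list(self.enhancer_length_range)
        return d


@dataclass
class SyntheticFixture:
    config: SyntheticConfig
    enhancers: pd.DataFrame          # chrom start end id
    tss: pd.DataFrame                # gene_id chrom pos(0-based) strand
    pairs: pd.DataFrame              # enhancer_id gene_id label component_id distance
    tracks: dict                     # marker -> chrom start end name score strand signal

    @property
    def promoters(self) -> pd.DataFrame:
        chrom_sizes = {c: self.config.chrom_length for c in self.config.chrom_names()}
        return map_gene_to_promoter(self.tss, chrom_sizes)

    def write(self, directory) -> None:
        write_fixture(self, directory)


def _split_counts(total: int, parts: int) -> list[int]:
    base = total // parts
    extra = total % parts
    return [base + (1 if i < extra else 0) for i in range(parts)]


def _place_intervals(rng, n, lengths, lo, hi, occupied_starts, occupied_ends):
    """Place ``n`` disjoint intervals with given lengths in [lo, hi).

    Rejection sampling against already-occupied intervals; bounded retries.
    """
    starts, ends = list(occupied_starts), list(occupied_ends)
    placed = []
    max_tries = 200 * max(n, 1)
    tries = 0
    for length in lengths:
        while True:
            tries += 1
            if tries > max_tries:
                raise ValueError(
                    "could not place all elements; chrom_length too small for "
                    "the requested element counts")
            s = int(rng.integers(lo, hi - length + 1))
            e = s + length
            sa, ea = np.asarray(starts), np.asarray(ends)
            if len(starts) == 0 or not np.any((sa < e) & (ea > s)):
                starts.append(s)
                ends.append(e)
                placed.append((s, e))
                break
    return placed


def generate_elements(config: SyntheticConfig):
    """Place non-overlapping enhancers and promoter TSSs on each chromosome.

    Returns ``(enhancers, tss)``: a BED-like enhancer frame and a TSS frame
    (0-based positions).  Promoter intervals are always 2 kb (TSS -1500/+500
    by strand), so a promoter's TSS is derived from its placed interval.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    enh_rows, tss_rows = [], []
    e_counts = _split_counts(config.n_enhancers, config.n_chromosomes)
    p_counts = _split_counts(config.n_promoters, config.n_chromosomes)
    lo_mn, lo_mx = config.enhancer_length_range
    for ci, chrom in enumerate(config.chrom_names()):
        domains = config.domains(ci)
        e_per_dom = _split_counts(e_counts[ci], len(domains))
        p_per_dom = _split_counts(p_counts[ci], len(domains))
        enh_iv, prom_iv = [], []
        for (dlo, dhi), ne, nprom in zip(domains, e_per_dom, p_per_dom):
            enh_lens = [int(rng.integers(lo_mn, lo_mx + 1)) for _ in range(ne)]
            dom_e = _place_intervals(rng, ne, enh_lens, dlo, dhi, [], [])
            starts = [s for s, _ in dom_e]
            ends = [e for _, e in dom_e]
            dom_p = _place_intervals(rng, nprom, [2000] * nprom, dlo, dhi,
                                     starts, ends)
            enh_iv.extend(dom_e)
            prom_iv.extend(dom_p)
        for i, (s, e) in enumerate(enh_iv):
            enh_rows.append((chrom, s, e, f"{chrom}_E{i:04d}"))
        for i, (s, e) in enumerate(prom_iv):
            strand = "+" if rng.random() < 0.5 else "-"
            tss = s + 1500 if strand == "+" else s + 500
            tss_rows.append((f"{chrom}_G{i:04d}", chrom, tss, strand))
    enhancers = pd.DataFrame(enh_rows, columns=["chrom", "start", "end", "id"])
    tss = pd.DataFrame(tss_rows, columns=["gene_id", "chrom", "pos", "strand"])
    return enhancers, tss


def _sample_partners(rng, anchor_pos, pool_ids, pool_pos, config, k):
    """Pick up to ``k`` partners from the pool within the distance range,
    preferring nearby ones with an exponential distance decay."""
    d = np.abs(pool_pos - anchor_pos)
    lo, hi = config.distance_range
    ok = (d >= lo) & (d <= hi)
    if not np.any(ok):
        return []
    idx = np.flatnonzero(ok)
    w = np.exp(-d[idx] / config.distance_decay)
    w = w / w.sum()
    k = min(k, len(idx))
    chosen = rng.choice(idx, size=k, replace=False, p=w)
    return [pool_ids[i] for i in np.atleast_1d(chosen)]


def generate_epi_network(enhancers: pd.DataFrame, tss: pd.DataFrame,
                         config: SyntheticConfig) -> pd.DataFrame:
    """Plant a positive interaction network over the elements.

    A configurable fraction of elements per chromosome is eligible for
    interactions; components are drawn from the topology mix until either
    pool runs dry.  Enhancers with no promoter in range are left isolated
    (logged).  Returns a pair table with ground-truth ``component_id``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    names = list(_TOPOLOGIES)
    weights = np.array([config.component_topology.get(n, 0.0) for n in names])
    rows = []
    comp_counter = 0

    for chrom in config.chrom_names():
        enh = enhancers[enhancers.chrom == chrom]
        prom = tss[tss.chrom == chrom]
        e_ids = list(enh.id)
        e_mid = dict(zip(enh.id, (enh.start + enh.end) / 2.0))
        p_ids = list(prom.gene_id)
        p_pos = dict(zip(prom.gene_id, prom.pos.astype(float)))

        n_e = int(round(config.interacting_fraction * len(e_ids)))
        n_p = int(round(config.interacting_fraction * len(p_ids)))
        e_pool = list(rng.permutation(e_ids)[:n_e])
        p_pool = list(rng.permutation(p_ids)[:n_p])

        forced_m2m = config.component_topology.get("many_to_many", 0.0) > 0

        def partners(anchor, pool, pos_map, k):
            ids = list(pool)
            pos = np.array([pos_map[i] for i in ids]) if ids else np.empty(0)
            return _sample_partners(rng, anchor, ids, pos, config, k)

        while e_pool and p_pool:
            kind = "many_to_many" if forced_m2m else rng.choice(names, p=weights)
            forced_m2m = False
            comp_edges = []
            if kind == "one_to_one":
                e = e_pool.pop(0)
                ps = partners(e_mid[e], p_pool, p_pos, 1)
                if not ps:
                    logger.info("enhancer %s isolated: no promoter in range", e)
                    continue
                comp_edges = [(e, ps[0])]
            elif kind == "one_to_many":
                # promoter hubs dominate: promoters reach higher degrees than
                # enhancers in observed EPI networks
                if rng.random() < 0.3:
                    e = e_pool.pop(0)
                    ps = partners(e_mid[e], p_pool, p_pos, int(rng.integers(2, 5)))
                    if not ps:
                        logger.info("enhancer %s isolated: no promoter in range", e)
                        continue
                    comp_edges = [(e, p) for p in ps]
                else:
                    p = p_pool.pop(0)
                    es = partners(p_pos[p], e_pool, e_mid, int(rng.integers(2, 9)))
                    if not es:
                        continue
                    comp_edges = [(e, p) for e in es]
            else:  # many_to_many
                e1 = e_pool.pop(0)
                ps = partners(e_mid[e1], p_pool, p_pos, int(rng.integers(2, 4)))
                if len(ps) < 2:
                    if not ps:
                        logger.info("enhancer %s isolated: no promoter in range", e1)
                        continue
                    comp_edges = [(e1, ps[0])]
                else:
                    others = []
                    for p in ps:
                        cand = partners(p_pos[p], [e for e in e_pool if e not in others],
                                        e_mid, 1)
                        others.extend(cand)
                        if len(others) >= 2:
                            break
                    es = [e1] + others
                    lo, hi = config.distance_range
                    comp_edges = [(e, p) for e in es for p in ps
                                  if lo <= abs(e_mid[e] - p_pos[p]) <= hi]
            if not comp_edges:
                continue
            cid = f"C{comp_counter:05d}"
            comp_counter += 1
            used_e = {e for e, _ in comp_edges}
            used_p = {p for _, p in comp_edges}
            e_pool = [e for e in e_pool if e not in used_e]
            p_pool = [p for p in p_pool if p not in used_p]
            for e, p in sorted(comp_edges):
                rows.append((e, p, 1, cid, abs(e_mid[e] - p_pos[p]), chrom))

    return pd.DataFrame(rows, columns=["enhancer_id", "gene_id", "label",
                                       "component_id", "distance", "chrom"])


def generate_signal_tracks(enhancers: pd.DataFrame, tss: pd.DataFrame,
                           pairs: pd.DataFrame, config: SyntheticConfig) -> dict:
    """Emit one narrowPeak-like table per marker (7 markers).

    Peak tracks are sparse, as real ones are: every element carries peaks
    over its central windows (the element itself and the two flanking
    windows on each side), and scattered background peaks cover the rest of
    each chromosome.  Elements participating in a positive pair have their
    central-peak mean elevated by ``signal_effect``, decaying linearly
    outward over windows -2..+2 (window 0 strongest); all peak signals ride
    on folded-Gaussian noise around ``baseline_signal``.
    """
    from .features import WindowScheme, build_windows

    scheme = WindowScheme(config.window_size, config.n_flank)
    chrom_sizes = {c: config.chrom_length for c in config.chrom_names()}
    prom = map_gene_to_promoter(tss, chrom_sizes)

    elements = pd.concat([
        enhancers[["chrom", "start", "end", "id"]],
        prom.rename(columns={"gene_id": "id"})[["chrom", "start", "end", "id"]],
    ], ignore_index=True)
    interacting = set(pairs.enhancer_id) | set(pairs.gene_id)

    offsets = np.arange(-scheme.n_flank, scheme.n_flank + 1)
    near = np.abs(offsets) <= 2
    tracks = {}
    for mi, marker in enumerate(gio.MARKERS):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3, mi]))
        rows = []
        for chrom, start, end, eid in elements.itertuples(index=False):
            wins = build_windows(start, end, scheme, chrom_sizes[chrom])
            values = np.abs(rng.normal(config.baseline_signal, config.noise_sd,
                                       size=len(offsets)))
            if eid in interacting and config.signal_effect > 0:
                values = values + np.where(
                    near, config.signal_effect * (1.0 - np.abs(offsets) / 3.0),
                    0.0)
            values = np.maximum(values, 1e-3)
            for (ws, we), off, v in zip(wins[near], offsets[near], values[near]):
                if we > ws:
                    rows.append((chrom, int(ws), int(we), f"{eid}_w{off:+d}",
                                 0, ".", float(v)))
        # sparse background peaks away from any planted structure
        for chrom in config.chrom_names():
            n_bg = chrom_sizes[chrom] // 25_000
            starts = rng.integers(0, chrom_sizes[chrom] - 2_000, size=n_bg)
            widths = rng.integers(500, 1_500, size=n_bg)
            sigs = np.maximum(np.abs(rng.normal(config.baseline_signal,
                                                config.noise_sd, size=n_bg)),
                              1e-3)
            for bi, (s, w, v) in enumerate(zip(starts, widths, sigs)):
                rows.append((chrom, int(s), int(s + w), f"bg_{chrom}_{bi}",
                             0, ".", float(v)))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                         "score", "strand", "signal"])
        df = df.sort_values(["chrom", "start", "end", "name"],
                            kind="mergesort").reset_index(drop=True)
        tracks[marker] = df
    return tracks


def generate_fixture(config: SyntheticConfig) -> SyntheticFixture:
    """Run the full generator: elements, network, tracks."""
    enhancers, tss = generate_elements(config)
    pairs = generate_epi_network(enhancers, tss, config)
    tracks = generate_signal_tracks(enhancers, tss, pairs, config)
    return SyntheticFixture(config, enhancers, tss, pairs, tracks)


def write_fixture(fixture: SyntheticFixture, directory) -> None:
    """Write ``enhancers.bed``, ``tss.tsv``, ``pairs.tsv``, seven marker BEDs
    and a JSON manifest into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    gio.write_enhancer_bed(fixture.enhancers, directory / "enhancers.bed")
    gio.write_tss_table(fixture.tss, directory / "tss.tsv")
    pairs = fixture.pairs.copy()
    pairs["distance"] = pairs["distance"].map(lambda v: f"{v:.1f}")
    gio.write_pairs_table(pairs, directory / "pairs.tsv")
    for marker, df in fixture.tracks.items():
        gio.write_track_bed(df, directory / f"{marker}.bed")
    manifest = {
        "seed": fixture.config.seed,
        "config": fixture.config.to_dict(),
        "n_enhancers": int(len(fixture.enhancers)),
        "n_promoters": int(len(fixture.tss)),
        "n_positive_pairs": int(len(fixture.pairs)),
        "n_components": int(fixture.pairs.component_id.nunique()),
    }
    gio.write_json(manifest, directory / "manifest.json")


def read_fixture(directory) -> SyntheticFixture:
    """Load a fixture written by :func:`write_fixture`."""
    directory = Path(directory)
    manifest = gio.read_json(directory / "manifest.json")
    cfg = dict(manifest["config"])
    cfg["distance_range"] = tuple(cfg["distance_range"])
    cfg["enhancer_length_range"] = tuple(cfg["enhancer_length_range"])
    config = SyntheticConfig(**cfg)
    enhancers = gio.read_enhancer_bed(directory / "enhancers.bed")
    tss = gio.read_tss_table(directory / "tss.tsv")
    pairs = gio.read_pairs_table(directory / "pairs.tsv")
    tracks = gio.read_tracks_dir(directory)
    return SyntheticFixture(config, enhancers, tss, pairs, tracks)
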
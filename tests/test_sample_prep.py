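"""Positive selection, promoter mapping, distance filter, negative sampling."""

import numpy as np
import pandas as pd
import pytest

from gatv2epi.sample_prep import (ep_distance, filter_by_distance,
                                  map_gene_to_promoter, prepare_samples,
                                  sample_negatives, select_positives)

CHROM_SIZES = {"chr1": 1_000_000}


def tss_frame(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "pos", "strand"])


class TestSelectPositives:
    def test_mixed_table_keeps_only_positive_rows(self):
        raw = pd.DataFrame({
            "enhancer_id": [f"e{i}" for i in range(10)],
            "gene_id": [f"g{i}" for i in range(10)],
            "label": [1, 0, 0, 1, 0, 1, 0, 0, 1, 0],
        })
        assert len(select_positives(raw)) == 4

    def test_all_negative_input_gives_empty_output(self):
        raw = pd.DataFrame({"enhancer_id": ["e1"], "gene_id": ["g1"], "label": [0]})
        assert select_positives(raw).empty

    def test_duplicate_positive_pairs_collapse(self):
        raw = pd.DataFrame({"enhancer_id": ["e1", "e1"], "gene_id": ["g1", "g1"],
                            "label": [1, 1]})
        assert len(select_positives(raw)) == 1

    def test_missing_columns_raise(self):
        with pytest.raises(ValueError):
            select_positives(pd.DataFrame({"enhancer_id": ["e1"]}))


class TestPromoterMapping:
    def test_plus_strand_is_1500_up_500_down(self):
        prom = map_gene_to_promoter(tss_frame([("g", "chr1", 10_000, "+")]),
                                    CHROM_SIZES)
        assert (prom.start[0], prom.end[0]) == (8_500, 10_500)

    def test_minus_strand_mirrors_reading_direction(self):
        prom = map_gene_to_promoter(tss_frame([("g", "chr1", 10_000, "-")]),
                                    CHROM_SIZES)
        assert (prom.start[0], prom.end[0]) == (9_500, 11_500)
        # 1500 bp on the 5' side of the reading direction (downstream coord)
        assert prom.end[0] - prom.tss[0] == 1_500

    def test_clamped_at_chromosome_start(self):
        prom = map_gene_to_promoter(tss_frame([("g", "chr1", 1_000, "+")]),
                                    CHROM_SIZES)
        assert (prom.start[0], prom.end[0]) == (0, 1_500)

    def test_unknown_chromosome_raises(self):
        with pytest.raises(KeyError):
            map_gene_to_promoter(tss_frame([("g", "chrX", 1_000, "+")]),
                                 CHROM_SIZES)

    def test_first_tss_used_for_multi_tss_genes(self):
        prom = map_gene_to_promoter(
            tss_frame([("g", "chr1", 10_000, "+"), ("g", "chr1", 50_000, "+")]),
            CHROM_SIZES)
        assert len(prom) == 1 and prom.tss[0] == 10_000


class TestDistance:
    def test_midpoint_to_tss(self):
        assert ep_distance(0, 1_000, 50_500) == 50_000.0

    def test_enhancer_centered_on_tss_gives_zero(self):
        assert ep_distance(9_000, 11_000, 10_000) == 0.0

    def test_nonnegative_for_random_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            s = int(rng.integers(0, 10_000))
            e = s + int(rng.integers(1, 5_000))
            t = int(rng.integers(0, 20_000))
            assert ep_distance(s, e, t) >= 0

    def test_filter_bounds_inclusive(self):
        pairs = pd.DataFrame({"distance": [41_999, 42_000, 250_000,
                                           500_000, 500_001]})
        kept = filter_by_distance(pairs)
        assert kept.distance.tolist() == [42_000, 250_000, 500_000]

    def test_filter_empty_input(self):
        assert filter_by_distance(pd.DataFrame({"distance": []})).empty


def _universe():
    """An enhancer with several in-range promoters for negative sampling."""
    enh = pd.DataFrame({"chrom": ["chr1"], "start": [500_000],
                        "end": [501_000], "id": ["e1"]})
    # promoter TSSs at varying offsets from the enhancer midpoint 500 500
    tss_pos = [550_500, 600_500, 700_500, 900_500, 505_500]  # last one too close
    tss = tss_frame([(f"g{i}", "chr1", p, "+") for i, p in enumerate(tss_pos)])
    promoters = map_gene_to_promoter(tss, {"chr1": 2_000_000})
    return enh, promoters


class TestNegativeSampling:
    def test_single_candidate_is_forced(self):
        enh, promoters = _universe()
        positives = pd.DataFrame({"enhancer_id": ["e1"], "gene_id": ["g0"],
                                  "label": [1]})
        # keep only one non-interacting in-range promoter
        prom = promoters[promoters.gene_id.isin(["g0", "g1", "g4"])]
        neg = sample_negatives(positives, prom, enh, seed=0)
        assert neg.promoter_id.tolist() == ["g1"]

    def test_balanced_and_disjoint_from_positives(self):
        rng = np.random.default_rng(1)
        n = 100
        enh = pd.DataFrame({"chrom": "chr1",
                            "start": rng.integers(1_000_000, 9_000_000, n),
                            "id": [f"e{i}" for i in range(n)]})
        enh["end"] = enh.start + 1_000
        tss = tss_frame([(f"g{i}", "chr1", int(p), "+") for i, p in
                         enumerate(rng.integers(500_000, 9_500_000, 400))])
        promoters = map_gene_to_promoter(tss, {"chr1": 10_000_000})
        rows = []
        for i in range(n):
            mid = enh.start[i] + 500
            d = np.abs(promoters.tss - mid)
            ok = promoters.gene_id[(d >= 42_000) & (d <= 500_000)]
            if len(ok):
                rows.append((f"e{i}", ok.iloc[0], 1))
        positives = pd.DataFrame(rows, columns=["enhancer_id", "gene_id", "label"])
        neg = sample_negatives(positives, promoters, enh, seed=3)
        assert len(neg) == len(positives)
        pos_set = set(zip(positives.enhancer_id, positives.gene_id))
        neg_set = set(zip(neg.enhancer_id, neg.promoter_id))
        assert not pos_set & neg_set
        assert len(neg_set) == len(neg)  # no duplicates: without replacement
        # every sampled pair re-passes the distance filter by brute force
        prom_tss = promoters.set_index("gene_id").tss
        e_idx = enh.set_index("id")
        for eid, gid in neg_set:
            d = abs((e_idx.loc[eid].start + e_idx.loc[eid].end) / 2
                    - prom_tss.loc[gid])
            assert 42_000 <= d <= 500_000

    def test_deterministic_under_seed(self):
        enh, promoters = _universe()
        positives = pd.DataFrame({"enhancer_id": ["e1", "e1"],
                                  "gene_id": ["g0", "g1"], "label": [1, 1]})
        a = sample_negatives(positives, promoters, enh, seed=11)
        b = sample_negatives(positives, promoters, enh, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_candidates_warns_and_skips(self):
        enh, promoters = _universe()
        positives = pd.DataFrame(
            {"enhancer_id": ["e1"] * 4,
             "gene_id": ["g0", "g1", "g2", "g3"], "label": [1] * 4})
        with pytest.warns(UserWarning):
            neg = sample_negatives(positives, promoters, enh, seed=0)
        assert len(neg) == 0  # all in-range promoters already interact


class TestPrepareSamples:
    def test_never_more_negatives_than_positives(self, small_fixture):
        fx = small_fixture
        sizes = {c: fx.config.chrom_length for c in fx.config.chrom_names()}
        samples, report = prepare_samples(fx.pairs, fx.enhancers, fx.tss,
                                          sizes, seed=5)
        n_pos = int((samples.label == 1).sum())
        n_neg = int((samples.label == 0).sum())
        assert n_neg <= n_pos
        assert report["positives_after_distance_filter"] == n_pos
        # no pair carries both labels
        key = list(zip(samples.enhancer_id, samples.promoter_id))
        both = samples.assign(k=key).groupby("k").label.nunique()
        assert (both == 1).all()
        # all distances re-check by brute force
        assert ((samples.distance >= 42_000) & (samples.distance <= 500_000)).all()
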
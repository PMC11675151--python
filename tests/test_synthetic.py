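"""Synthetic fixture generator: determinism, planted structure, signal model."""

import filecmp
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from _oracles import bfs_components
from conftest import small_config
from gatv2epi.features import WindowScheme, featurize
from gatv2epi.io import MARKERS
from gatv2epi.synthetic import (SyntheticConfig, generate_elements,
                                generate_epi_network, generate_fixture,
                                read_fixture, write_fixture)


class TestConfig:
    def test_topology_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            small_config(component_topology={"one_to_one": 0.5,
                                             "one_to_many": 0.2,
                                             "many_to_many": 0.2})

    def test_chromosome_must_fit_window_scheme(self):
        with pytest.raises(ValueError):
            small_config(chrom_length=50_000)


class TestElements:
    def test_zero_enhancers_still_places_promoters(self):
        enh, tss = generate_elements(small_config(n_enhancers=0))
        assert enh.empty and len(tss) == 60

    def test_same_seed_gives_identical_coordinates(self):
        a = generate_elements(small_config())
        b = generate_elements(small_config())
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_elements_disjoint_and_clear_of_chromosome_ends(self):
        cfg = small_config(n_enhancers=50)
        enh, tss = generate_elements(cfg)
        margin = 21 * cfg.window_size
        prom_ivs = [(p - 1500, p + 500) if s == "+" else (p - 500, p + 1500)
                    for p, s in zip(tss.pos, tss.strand)]
        ivs = sorted(list(zip(enh.start, enh.end)) + prom_ivs)
        # brute-force overlap scan over every interval pair
        for i in range(len(ivs)):
            for j in range(i + 1, len(ivs)):
                assert ivs[i][1] <= ivs[j][0] or ivs[j][1] <= ivs[i][0]
        assert min(s for s, _ in ivs) >= margin
        assert max(e for _, e in ivs) <= cfg.chrom_length - margin

    def test_placement_failure_signals_small_chromosome(self):
        with pytest.raises(ValueError, match="too small"):
            generate_elements(small_config(n_enhancers=400, n_promoters=400,
                                           chrom_length=1_200_000))

    def test_enhancer_lengths_vary_within_range(self):
        cfg = small_config()
        enh, _ = generate_elements(cfg)
        lengths = enh.end - enh.start
        lo, hi = cfg.enhancer_length_range
        assert lengths.between(lo, hi).all() and lengths.nunique() > 5


class TestNetwork:
    def test_pure_one_to_one_mix_caps_degree_at_one(self):
        cfg = small_config(component_topology={"one_to_one": 1.0,
                                               "one_to_many": 0.0,
                                               "many_to_many": 0.0})
        enh, tss = generate_elements(cfg)
        pairs = generate_epi_network(enh, tss, cfg)
        assert len(pairs) > 0
        assert pairs.enhancer_id.value_counts().max() == 1
        assert pairs.gene_id.value_counts().max() == 1

    def test_many_to_many_mix_yields_dense_component(self, small_fixture):
        comps = bfs_components(zip(small_fixture.pairs.enhancer_id,
                                   small_fixture.pairs.gene_id))
        assert any(sum(1 for n in c if "_E" in n) >= 2 and
                   sum(1 for n in c if "_G" in n) >= 2 for c in comps)

    def test_all_pair_distances_within_configured_range(self, small_fixture):
        lo, hi = small_fixture.config.distance_range
        assert small_fixture.pairs.distance.between(lo, hi).all()

    def test_recorded_components_match_bfs_of_written_graph(self, small_fixture):
        pairs = small_fixture.pairs
        oracle = set(bfs_components(zip(pairs.enhancer_id, pairs.gene_id)))
        recorded = {frozenset(set(grp.enhancer_id) | set(grp.gene_id))
                    for _, grp in pairs.groupby("component_id")}
        assert recorded == oracle


class TestSignal:
    @staticmethod
    def _central_means(fx, ids):
        scheme = WindowScheme(fx.config.window_size, fx.config.n_flank)
        out = []
        elements = pd.concat([
            fx.enhancers.rename(columns={"id": "eid"}),
            fx.promoters.rename(columns={"gene_id": "eid"})])
        for eid in ids:
            row = elements[elements.eid == eid].iloc[0]
            mat = featurize(row, fx.tracks, scheme, fx.config.chrom_length)
            out.append(mat[:, fx.config.n_flank].mean())
        return np.array(out)

    def test_seven_marker_tracks_generated(self, small_fixture):
        assert set(small_fixture.tracks) == set(MARKERS)
        for df in small_fixture.tracks.values():
            assert (df.signal > 0).all()
            assert (df.start < df.end).all()

    def test_zero_effect_makes_groups_indistinguishable(self):
        cfg = small_config(n_enhancers=120, n_promoters=180, signal_effect=0.0,
                           chrom_length=4_000_000, interacting_fraction=0.5)
        fx = generate_fixture(cfg)
        interacting = set(fx.pairs.enhancer_id) | set(fx.pairs.gene_id)
        all_ids = list(fx.enhancers.id) + list(fx.tss.gene_id)
        inter = [i for i in all_ids if i in interacting]
        isolated = [i for i in all_ids if i not in interacting]
        assert len(inter) + len(isolated) >= 200
        a = self._central_means(fx, inter)
        b = self._central_means(fx, isolated)
        assert sps.ttest_ind(a, b, equal_var=False).pvalue > 0.01

    def test_planted_effect_exceeds_three_standard_errors(self):
        cfg = small_config(n_enhancers=120, n_promoters=180,
                           chrom_length=4_000_000, interacting_fraction=0.5)
        fx = generate_fixture(cfg)
        interacting = set(fx.pairs.enhancer_id) | set(fx.pairs.gene_id)
        all_ids = list(fx.enhancers.id) + list(fx.tss.gene_id)
        inter = [i for i in all_ids if i in interacting]
        isolated = [i for i in all_ids if i not in interacting]
        assert len(inter) + len(isolated) >= 200
        a = self._central_means(fx, inter)
        b = self._central_means(fx, isolated)
        se = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
        assert a.mean() - b.mean() > 3 * se


class TestFixtureIO:
    def test_written_files_are_byte_identical_under_same_config(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_fixture(generate_fixture(small_config()), d1)
        write_fixture(generate_fixture(small_config()), d2)
        names = sorted(p.name for p in d1.iterdir())
        assert names == sorted(p.name for p in d2.iterdir())
        for name in names:
            assert filecmp.cmp(d1 / name, d2 / name, shallow=False), name

    def test_round_trip_preserves_tables(self, tmp_path, small_fixture):
        write_fixture(small_fixture, tmp_path)
        back = read_fixture(tmp_path)
        pd.testing.assert_frame_equal(back.enhancers, small_fixture.enhancers)
        pd.testing.assert_frame_equal(back.tss, small_fixture.tss)
        assert len(back.pairs) == len(small_fixture.pairs)
        for m in MARKERS:
            pd.testing.assert_frame_equal(back.tracks[m],
                                          small_fixture.tracks[m])
        assert back.config == small_fixture.config

    def test_bed_coordinates_are_zero_based_half_open(self, tmp_path,
                                                      small_fixture):
        write_fixture(small_fixture, tmp_path)
        bed = Path(tmp_path / "enhancers.bed").read_text().splitlines()
        first = bed[0].split("\t")
        row = small_fixture.enhancers.iloc[0]
        assert (first[1], first[2]) == (str(row.start), str(row.end))
        # tss.tsv positions are 1-based on disk
        tss_line = Path(tmp_path / "tss.tsv").read_text().splitlines()[1]
        assert int(tss_line.split("\t")[2]) == small_fixture.tss.pos.iloc[0] + 1

    def test_pairs_row_count_matches_generated(self, tmp_path, small_fixture):
        write_fixture(small_fixture, tmp_path)
        n = len(Path(tmp_path / "pairs.tsv").read_text().splitlines()) - 1
        assert n == len(small_fixture.pairs)
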
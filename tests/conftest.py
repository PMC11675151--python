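"""Shared fixtures: a small single-chromosome toy dataset for unit tests and
the full default-conditions pipeline (generated once per session)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gatv2epi.features import WindowScheme, featurize_elements
from gatv2epi.graph import build_dataset, build_graph
from gatv2epi.sample_prep import map_gene_to_promoter, prepare_samples
from gatv2epi.synthetic import SyntheticConfig, generate_fixture


def small_config(**overrides) -> SyntheticConfig:
    kw = dict(n_chromosomes=1, chrom_length=2_000_000, n_enhancers=40,
              n_promoters=60, seed=123)
    kw.update(overrides)
    return SyntheticConfig(**kw)


@pytest.fixture(scope="session")
def small_fixture():
    return generate_fixture(small_config())


def run_pipeline(config: SyntheticConfig, seed: int, shuffle_labels: bool = False):
    """Fixture -> samples -> features -> split graphs, as a plain helper."""
    fx = generate_fixture(config)
    chrom_sizes = {c: config.chrom_length for c in config.chrom_names()}
    samples, report = prepare_samples(fx.pairs, fx.enhancers, fx.tss,
                                      chrom_sizes, seed=seed)
    if shuffle_labels:
        rng = np.random.default_rng(seed + 7919)
        samples = samples.copy()
        samples["label"] = rng.permutation(samples["label"].to_numpy())
    prom = map_gene_to_promoter(fx.tss, chrom_sizes)
    elements = pd.concat([
        fx.enhancers[["chrom", "start", "end", "id"]],
        prom.rename(columns={"gene_id": "id"})[["chrom", "start", "end", "id"]],
    ], ignore_index=True)
    feats = featurize_elements(elements, fx.tracks, WindowScheme(), chrom_sizes)
    graphs, plan, stats = build_dataset(samples, feats, seed=seed)
    return {"fixture": fx, "samples": samples, "features": feats,
            "graphs": graphs, "plan": plan, "stats": stats, "report": report}


@pytest.fixture(scope="session")
def study_pipeline():
    """The default study conditions (two chromosomes, planted signal at
    5x noise), used by the end-to-end and acceptance tests."""
    return run_pipeline(SyntheticConfig(seed=1), seed=1)


@pytest.fixture(scope="session")
def trained_study(study_pipeline):
    """One 50-epoch training run on the study pipeline (shared across tests)."""
    from gatv2epi.model import ModelConfig
    from gatv2epi.train import TrainConfig, train

    model, history = train(study_pipeline["graphs"], ModelConfig(seed=1),
                           TrainConfig(epochs=50, seed=1))
    return {"model": model, "history": history}


@pytest.fixture()
def tiny_graph():
    """A hand-sized two-component sample graph with random features."""
    rng = np.random.default_rng(42)
    samples = pd.DataFrame({
        "enhancer_id": ["e1", "e1", "e2", "e3", "e3"],
        "promoter_id": ["p1", "p2", "p2", "p3", "p4"],
        "label": [1, 0, 1, 1, 0],
        "distance": [50_000.0, 120_000.0, 90_000.0, 200_000.0, 450_000.0],
        "chrom": ["chr1"] * 5,
        "split": ["train"] * 5,
    })
    feats = {k: rng.random((7, 21)) for k in
             ["e1", "e2", "e3", "p1", "p2", "p3", "p4"]}
    return build_graph(samples, feats)[0]
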
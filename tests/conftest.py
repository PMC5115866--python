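"""Shared fixtures: small synthetic worlds and trained pipelines."""

import pytest

from ppilr import WorldConfig, generate
from ppilr.pipeline import build_features, score_pairs, total_lrs, train_models

SMALL = dict(n_proteins=400, n_modules=20, n_negative_sample=5000, seed=1)


@pytest.fixture(scope="session")
def small_world():
    return generate(WorldConfig(**SMALL))


@pytest.fixture(scope="session")
def small_features(small_world):
    w = small_world
    return build_features(
        w.evidence, w.ortholog_maps, w.species_interactions, w.correlations,
        w.dataset_manifest, w.neighborhoods, w.known_human, w.known_any)


@pytest.fixture(scope="session")
def small_models(small_world, small_features):
    return train_models(small_features, small_world.refs_train)


@pytest.fixture(scope="session")
def small_scores(small_world, small_features, small_models):
    has_structure = {p.id: p.has_structure
                     for p in small_world.proteins.values()}
    return score_pairs(small_features, small_models,
                       has_structure=has_structure)


@pytest.fixture(scope="session")
def small_lrs(small_scores):
    return total_lrs(small_scores)
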
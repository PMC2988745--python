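import pytest

from gsmaudit import (
    GeneratorSpec,
    build_flux_problem,
    generate_model,
    toy1_medium,
    toy1_model,
)

#: small planted-defect spec exercising every feature class at once
SMALL_SPEC = dict(
    n_backbone=8,
    n_isozyme_pairs=1,
    n_complexes=1,
    n_parallel_routes=2,
    n_orphan_clusters=2,
    orphan_cluster_size=2,
    n_deadend_branches=2,
    n_unused_genes=2,
)

#: spec whose models stay within 8 reactions, for exhaustive vertex oracles
TINY_SPEC = dict(
    n_backbone=3,
    n_isozyme_pairs=0,
    n_complexes=1,
    n_parallel_routes=0,
    n_orphan_clusters=1,
    orphan_cluster_size=1,
    n_deadend_branches=1,
    n_unused_genes=0,
)

GRID_SEEDS = list(range(20))


@pytest.fixture
def toy1():
    return toy1_model()


@pytest.fixture
def toy1_med():
    return toy1_medium()


@pytest.fixture
def toy1_problem(toy1, toy1_med):
    return build_flux_problem(toy1, toy1_med, "GROWTH")


@pytest.fixture
def small_model():
    return generate_model(GeneratorSpec(seed=7, **SMALL_SPEC))
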
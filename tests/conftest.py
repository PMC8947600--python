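import pytest

from ngmcs import (
    EngineOptions,
    apply_medium,
    build_g_matrix,
    extend_with_nutrients,
    toy_network,
)


@pytest.fixture(scope="session")
def cm1():
    """The single-nutrient toy network and its medium."""
    return toy_network("CM1")


@pytest.fixture(scope="session")
def cm2():
    """The two-nutrient toy network (adds the gene-less rescue route)."""
    return toy_network("CM2")


@pytest.fixture(scope="session")
def quick_opts():
    return EngineOptions(max_solutions=50, time_limit_per_solution=30.0)


def full_gmatrix(model, medium):
    """Gene rows plus one nutrient row per medium entry."""
    g = build_g_matrix(model)
    return extend_with_nutrients(g, apply_medium(model, medium), medium)
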
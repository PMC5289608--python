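import numpy as np
import pytest

from ictair import (
    ChannelMode,
    ExpressionMatrix,
    GeneSet,
    RefineParams,
    generate_scenario,
    ictair,
    scenario_s1,
)


@pytest.fixture
def six_gene_matrix():
    """One sample whose sorted expression is [3, 2, 1, -1, -2, -3]."""
    return ExpressionMatrix(
        gene_ids=("g1", "g2", "g3", "g4", "g5", "g6"),
        sample_ids=("s1",),
        values=np.array([[3.0], [2.0], [1.0], [-1.0], [-2.0], [-3.0]]),
        channel_mode=ChannelMode.pre_normalized,
    )


@pytest.fixture
def top_two_targets():
    """Targets holding the two highest expression values of the fixture."""
    return GeneSet("R", "desc", ("g1", "g2"))


def random_matrix(n_genes, n_samples, seed, round_to=None):
    rng = np.random.default_rng(seed)
    values = rng.standard_normal((n_genes, n_samples))
    if round_to is not None:
        values = np.round(values, round_to)
    return ExpressionMatrix(
        gene_ids=tuple(f"g{i}" for i in range(n_genes)),
        sample_ids=tuple(f"s{i}" for i in range(n_samples)),
        values=values,
        channel_mode=ChannelMode.pre_normalized,
    )


@pytest.fixture(scope="session")
def s1():
    """Scenario S1 (canonical planted regulon), generated once per session."""
    return generate_scenario(scenario_s1(42))


@pytest.fixture(scope="session")
def s1_refined(s1):
    """Full refinement of S1 with the canonical parameters, run once."""
    matrix, listed, _ = s1
    params = RefineParams(n_permutations=200, seed=42)
    return ictair(listed, matrix, params), params
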
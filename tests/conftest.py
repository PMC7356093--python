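import pytest

from straindiff.pipeline import analyse_pair
from straindiff.simulate import SimulationConfig, simulate_strain_pair


@pytest.fixture(scope="session")
def small_sim():
    """A 50 kb pair with every event class, including one excision scar."""
    config = SimulationConfig(
        genome_length=50_000,
        n_genes=8,
        inserts_a=[2, 0, 1],
        inserts_b=[1, 2, 1],
        n_shared_copies=[6, 3, 0],
        n_indel_1bp=4,
        n_substitutions=2,
        n_scars=1,
        seed=11,
    )
    ga, gb, fa, fb, truth, library = simulate_strain_pair(config)
    return dict(
        config=config, genome_a=ga, genome_b=gb, features_a=fa, features_b=fb,
        truth=truth, library=library,
    )


@pytest.fixture(scope="session")
def small_result(small_sim):
    return analyse_pair(
        small_sim["genome_a"], small_sim["genome_b"],
        small_sim["features_a"], small_sim["features_b"],
    )


@pytest.fixture(scope="session")
def study_sim():
    """The full-size study conditions: 200 kb, 8+8 differential inserts
    (two TIR-bearing types, one repeat-less), 42 shared copies, 4 one-letter
    indels, 1 substitution, 1 gene disruption."""
    config = SimulationConfig(seed=11)
    ga, gb, fa, fb, truth, library = simulate_strain_pair(config)
    return dict(
        config=config, genome_a=ga, genome_b=gb, features_a=fa, features_b=fb,
        truth=truth, library=library,
    )


@pytest.fixture(scope="session")
def study_result(study_sim):
    return analyse_pair(
        study_sim["genome_a"], study_sim["genome_b"],
        study_sim["features_a"], study_sim["features_b"],
    )
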
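import numpy as np
import pytest

import lmerbin as lb


@pytest.fixture(scope="session")
def small_community():
    """Small two-species community: 150+150 fragments of 1000 bp, error-free."""
    cfg = lb.default_two_species_community(
        fragments_per_species=(150, 150), fragment_length=1000,
        error_rate=0.0, seed=11, genome_length=100_000)
    fragments, genomes = lb.build_community(cfg)
    return cfg, fragments, genomes


@pytest.fixture(scope="session")
def small_features(small_community):
    _, fragments, _ = small_community
    return lb.build_feature_matrix(fragments, l=4)


@pytest.fixture(scope="session")
def small_labels(small_community):
    _, fragments, _ = small_community
    return {f.id: f.label for f in fragments}


def random_dna(rng: np.random.Generator, length: int,
               alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=length))
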
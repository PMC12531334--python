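import numpy as np
import pytest

from lesionrx.synth import (
    GridSpec,
    generate_lesions,
    generate_receptors,
    generate_term_matrix,
    generate_tracts,
    generate_transcriptome,
    generate_world,
)


@pytest.fixture(scope="session")
def small_world():
    return generate_world(GridSpec((16, 16, 16)), n_networks=4, seed=1)


@pytest.fixture(scope="session")
def noiseless_terms(small_world):
    return generate_term_matrix(
        small_world, terms_per_network=3, noise_sd=0.0, effect=1.0, seed=2
    )


@pytest.fixture(scope="session")
def receptors(small_world):
    return generate_receptors(small_world, n_receptors=4, smoothness_vox=3.0, seed=3)


@pytest.fixture(scope="session")
def transcriptome(small_world):
    return generate_transcriptome(
        small_world, sites_per_network=10, n_genes=40, split_effect=5.0, seed=4
    )


@pytest.fixture(scope="session")
def lesions(small_world):
    return generate_lesions(
        small_world, n_patients=60, size_range_vox=(10, 80), seed=5
    )


@pytest.fixture(scope="session")
def tracts(small_world):
    return generate_tracts(small_world, n_subjects=4, bundles_per_subject=8, seed=6)
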
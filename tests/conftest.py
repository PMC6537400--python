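import numpy as np
import pytest

from baculoscan.synthetic import design_spec, generate_genome, study_scale_spec


@pytest.fixture(scope="session")
def small_genome():
    """20-kb synthetic genome with 18 ORFs, 3 hr clusters (6 repeats), 1 CNE,
    one overlapping pair and one wrapping ORF."""
    spec = design_spec(
        11,
        genome_length=20_000,
        n_orfs=18,
        n_plus=8,
        hr_cluster_sizes=(3, 2, 1),
        n_overlap_pairs=1,
    )
    return generate_genome(spec)


@pytest.fixture(scope="session")
def study_genome():
    """Study-scale genome: 125,477 bp, 144 ORFs (70/74), 8 hrs / 30 repeats,
    1 CNE, seed 1."""
    return generate_genome(study_scale_spec(1))


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
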
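import numpy as np
import pytest

from compspec.synthetic import SyntheticSpec, generate_synthetic_dataset


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    """A reduced planted-structure dataset spec shared by pipeline tests:
    2 OP classes x 12 segments x 4 kb, strong coupling."""
    return SyntheticSpec(
        classes=("op1", "op2"),
        n_segments_per_class=12,
        segment_len=4_000,
        n_chromosomes=2,
        gene_density=2.0,
        coupling_beta=0.9,
        n_terms=5,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_spec, tmp_path_factory):
    """(fasta, bed, terms, truth) for the shared small dataset."""
    outdir = tmp_path_factory.mktemp("small_synth")
    return generate_synthetic_dataset(small_spec, outdir)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
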
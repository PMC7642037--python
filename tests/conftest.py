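import numpy as np
import pytest

from gelnet.simulate import (
    SimulationSpec,
    simulate_expression,
    simulate_promoters,
    write_full_fixture,
)


@pytest.fixture(scope="session")
def block_spec():
    """Three planted co-expression blocks over 40 samples; expected
    within-block PCC = 2^2 / (2^2 + 1^2) = 0.8."""
    return SimulationSpec(
        n_genes=300, n_samples=40, module_sizes=(60, 50, 40), signal_sd=2.0,
        noise_sd=1.0, seed=3
    )


@pytest.fixture(scope="session")
def block_sim(block_spec):
    return simulate_expression(block_spec)


@pytest.fixture(scope="session")
def promoter_sim():
    """120 genes with 1-kb promoters; motif planted 3x in the first 12."""
    spec = SimulationSpec(
        n_genes=120, module_sizes=(40, 30), promoter_length=1000, motif="TGACGTCA",
        n_background_motifs=4, planted_copies=3, enriched_fraction=0.1, seed=9
    )
    return simulate_promoters(spec)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """A full on-disk fixture set (expression TSV, FASTA, GFF3, GMT, motifs)."""
    out = tmp_path_factory.mktemp("fixture")
    spec = SimulationSpec(n_genes=120, n_samples=20, module_sizes=(40, 30), seed=4)
    paths = write_full_fixture(out, spec)
    return paths


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
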
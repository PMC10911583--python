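import pytest

from tyhybrid.pipeline import StudyConfig, run_study
from tyhybrid.simulate import GenomeSpec, simulate_parental_pair


@pytest.fixture(scope="session")
def small_spec():
    return GenomeSpec(
        n_chromosomes=6,
        chrom_length=300_000,
        snp_divergence=0.01,
        n_full_length={"Ty1": 10},
        n_solo_ltr={"Ty1": 4},
        seed=42,
    )


@pytest.fixture(scope="session")
def small_pair(small_spec):
    return simulate_parental_pair(small_spec)


@pytest.fixture(scope="session")
def small_study():
    """Noise-free synthetic cross exercising every SV class, shared by tests."""
    cfg = StudyConfig(
        n_chromosomes=6,
        chrom_length=400_000,
        n_full_length=12,
        n_solo_ltr=4,
        n_lines=12,
        n_reads_per_line=150,
        seed=11,
    )
    return run_study(cfg)
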
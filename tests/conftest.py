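import numpy as np
import pytest

from refotu.simdata import SimConfig, generate_reference_db, generate_samples


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), length))


def mutate(seq: str, n_sub: int, rng: np.random.Generator) -> str:
    """Exactly n_sub substitutions at distinct positions."""
    s = list(seq)
    for pos in rng.choice(len(s), size=n_sub, replace=False):
        s[pos] = rng.choice([c for c in "ACGT" if c != s[pos]])
    return "".join(s)


@pytest.fixture(scope="session")
def tiny_config() -> SimConfig:
    return SimConfig(
        seed=5, n_ref_species=20, n_novel_species=3, n_community_species=12,
        n_case_samples=3, n_control_samples=4, n_longitudinal_subjects=2,
        n_timepoints=3, mean_reads_case=3400, sd_reads_case=50,
        mean_reads_control=3400, sd_reads_control=50,
        redundancy_per_species=2)


@pytest.fixture(scope="session")
def tiny_study(tiny_config):
    records, truth = generate_reference_db(tiny_config)
    samples, sheet = generate_samples(tiny_config, truth)
    return records, truth, samples, sheet
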
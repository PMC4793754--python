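import numpy as np
import pytest

from tickdup.synthetic_data import (
    EventSpec,
    SimulationConfig,
    simulate_transcriptome,
)


@pytest.fixture(scope="session")
def small_transcriptome():
    """A small planted transcriptome shared by detection/cluster tests:
    30 singletons, two events (10 purifying pairs each, Ks 0.1 / 0.25),
    2 three-member families."""
    cfg = SimulationConfig(
        n_singletons=30,
        events=(EventSpec(10, 0.1, 0.1), EventSpec(10, 0.25, 0.1)),
        n_multigene_families=2,
        family_size=3,
        cds_length_codons=150,
        omega_positive_fraction=0.0,
        seed=11,
    )
    return simulate_transcriptome(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_codon_pair(rng, p_diff=0.5):
    """A random pair of sense codons differing at 0-3 positions."""
    from tickdup._codons import SENSE_CODONS

    a = SENSE_CODONS[rng.integers(len(SENSE_CODONS))]
    while True:
        b = list(a)
        for pos in range(3):
            if rng.random() < p_diff:
                b[pos] = "ACGT"[rng.integers(4)]
        b = "".join(b)
        from tickdup._codons import is_stop

        if not is_stop(b):
            return a, b
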
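import numpy as np
import pytest

from rarecode import codon_usage as cu
from rarecode import motif_scan as ms
from rarecode import synthetic_data as sd


@pytest.fixture(scope="session")
def usage_table() -> cu.CodonUsageTable:
    """Synthetic genome usage table, synonym skew 4."""
    return sd.synth_usage_table(seed=11, skew=4.0)


@pytest.fixture(scope="session")
def weights(usage_table) -> cu.WeightTable:
    return cu.relative_adaptiveness(usage_table)


@pytest.fixture(scope="session")
def urich_pwm() -> ms.PWM:
    """A sharp U-rich hexamer PWM (DNA alphabet: T-rich), emulating a
    CPEB-family binding element."""
    column = [0.04, 0.04, 0.04, 0.88]  # A C G T
    return ms.PWM("urich6", np.array([column] * 6))


@pytest.fixture(scope="session")
def urich_dist(urich_pwm) -> ms.ScoreDistribution:
    return ms.score_distribution(urich_pwm)


def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """A random in-frame CDS with no internal stop codons."""
    sense = [c for c in cu.ALL_CODONS if c not in cu.STOP_CODONS]
    return "".join(rng.choice(sense, size=n_codons))
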
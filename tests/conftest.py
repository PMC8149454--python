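import numpy as np
import pandas as pd
import pytest

from cisreg.motifs import PWM, BackgroundModel


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def abox_pwm():
    """Sharp TAAT-core A-box motif (TTCTAATTAC)."""
    return PWM.from_consensus("abox", "TTCTAATTAC", consensus_prob=0.85)


@pytest.fixture
def uniform_bg():
    return BackgroundModel.uniform()


@pytest.fixture
def small_bg(rng):
    return BackgroundModel.iid(300, 200, rng=rng)


def random_pwm(rng, length=8, sharpness=5.0, id="m"):
    """Dirichlet-random PWM, peakier for larger sharpness."""
    mat = rng.dirichlet(np.full(4, 1.0 / sharpness), size=length)
    return PWM.from_matrix(id, np.clip(mat, 1e-6, 1.0), pseudocount=1e-3)


def random_dna(rng, length):
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lut[rng.integers(0, 4, size=length)].tobytes().decode()


@pytest.fixture
def luciferase_toy():
    """Hand-sized well table: control ratios {2, 2}, one test group at 2x."""
    return pd.DataFrame([
        {"group": "blank", "bio_replicate": 1, "tech_replicate": 1, "firefly": 200, "renilla": 100},
        {"group": "blank", "bio_replicate": 2, "tech_replicate": 1, "firefly": 300, "renilla": 150},
        {"group": "effector", "bio_replicate": 1, "tech_replicate": 1, "firefly": 400, "renilla": 100},
        {"group": "effector", "bio_replicate": 2, "tech_replicate": 1, "firefly": 600, "renilla": 150},
    ])
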
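"""Shared fixtures: the default synthetic corpus and well-scaled random models."""

import numpy as np
import pytest

from cochlear_eis import (
    ArrayGeometry,
    BiphasicPulse,
    BlockVariant,
    CorpusSpec,
    ElectrodePairKey,
    TransimpedanceModel,
    generate_parameter_matrix,
)

TWO_PI = 2.0 * np.pi


@pytest.fixture(scope="session")
def geometry():
    return ArrayGeometry()


@pytest.fixture(scope="session")
def corpus_spec():
    return CorpusSpec()


@pytest.fixture(scope="session")
def corpus_models(geometry, corpus_spec):
    return generate_parameter_matrix(geometry, corpus_spec)


@pytest.fixture(scope="session")
def adjacent_model(corpus_models):
    """Representative adjacent-pair model (stim 3, rec 5)."""
    return corpus_models[ElectrodePairKey(stim=3, rec=5)]


def draw_random_model(rng: np.random.Generator, variant=BlockVariant.PARALLEL_RCPE1):
    """Well-scaled random circuit: corners inside the EIS band, tissue-like p."""
    r1 = 10 ** rng.uniform(2.0, 3.0)
    r2 = 10 ** rng.uniform(1.7, 2.7)
    p1 = rng.uniform(0.6, 0.95)
    p2 = rng.uniform(0.6, 0.95)
    fc1 = 10 ** rng.uniform(1.0, 2.5)  # 10 Hz - 300 Hz
    fc2 = 10 ** rng.uniform(3.5, 4.9)  # 3 kHz - 80 kHz
    y1 = (1.0 / (TWO_PI * fc1)) ** p1 / r1
    y2 = (1.0 / (TWO_PI * fc2)) ** p2 / r2
    variant = BlockVariant(variant)
    return TransimpedanceModel.from_values(
        R1=r1 if variant is BlockVariant.PARALLEL_RCPE1 else None,
        Y1=y1, p1=p1, R2=r2, Y2=y2, p2=p2, variant=variant,
    )


def draw_random_pulse(rng: np.random.Generator):
    return BiphasicPulse(
        amplitude=800e-6, phase_duration=10 ** rng.uniform(-5.7, -3.7)
    )
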
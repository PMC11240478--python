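import numpy as np
import pytest

from thzcontrast import (
    Band,
    EffectSpec,
    FrequencyGrid,
    Modality,
    SampleType,
    SimConfig,
    Spectrum,
    generate_dataset,
)


@pytest.fixture
def grid():
    """Small strictly increasing grid, 0.06-4.0 THz at 0.02 THz."""
    return FrequencyGrid(0.06 + 0.02 * np.arange(198))


@pytest.fixture
def null_dataset():
    """Default-world null dataset: no effects, equal offsets, noise_sd 0.1."""
    return generate_dataset(SimConfig(seed=11))


@pytest.fixture
def effect_dataset():
    """Dataset with a flat +0.2 nanoparticle effect on ATR tumor cells in 3-4 THz."""
    config = SimConfig(
        seed=11,
        effects=(
            EffectSpec(
                target=(Modality.ATR, SampleType.TUMOR_NP),
                band=Band(3.0, 4.0),
                magnitude=0.2,
            ),
        ),
    )
    return generate_dataset(config)


def make_spectrum(grid, signal, modality=Modality.ATR, sample_type=SampleType.NORMAL):
    return Spectrum(
        modality=modality, sample_type=sample_type, grid=grid, signal=np.asarray(signal)
    )
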
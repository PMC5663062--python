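import numpy as np
import pytest

from chrysoraman import (
    PeakPattern,
    Peak,
    SyntheticConfig,
    reference_library,
    scaled_detection_config,
)

# the study conditions for synthetic round-trip experiments: 6 replicates of
# Gaussian peaks (FWHM 12 cm^-1, strongest peak 4000 a.u.) over a fifth-order
# fluorescence background with additive noise of 20 a.u.
STUDY_BACKGROUND = (800.0, 400.0, -300.0, 100.0, 0.0, 0.0)


def study_config(seed: int = 7, **overrides) -> SyntheticConfig:
    kwargs = dict(background_coefficients=STUDY_BACKGROUND, seed=seed)
    kwargs.update(overrides)
    return SyntheticConfig(**kwargs)


@pytest.fixture(scope="session")
def library():
    return reference_library()


@pytest.fixture(scope="session")
def detection():
    """Detection profile matched to the 4000 a.u. synthetic amplitude."""
    return scaled_detection_config(4000.0, 12.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_pattern(cultivar: str, spec: dict[float, float]) -> PeakPattern:
    return PeakPattern(
        cultivar=cultivar,
        peaks=[Peak(position=p, normalized_intensity=v) for p, v in sorted(spec.items())],
    )
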
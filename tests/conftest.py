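import numpy as np
import pytest

from hemovision import (
    Annotation,
    LabeledImage,
    NormBox,
    SCHEME_3,
    SimConfig,
    generate_dataset,
)
from hemovision.synth_flow import DEFAULT_MIXTURE_3


@pytest.fixture(scope="session")
def noiseless_config() -> SimConfig:
    """Three-class scenes with no pixel noise, blur, or defocus."""
    return SimConfig(
        mixture=dict(DEFAULT_MIXTURE_3),
        noise_sd=0.0,
        blur_sigma_px=0.0,
        defocus_probability=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def noiseless_frames(noiseless_config) -> list[LabeledImage]:
    return generate_dataset(noiseless_config, 40, seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_annotation(rng: np.random.Generator, n_classes: int = 3) -> Annotation:
    w = float(rng.uniform(0.01, 0.4))
    h = float(rng.uniform(0.01, 0.4))
    cx = float(rng.uniform(w / 2, 1 - w / 2))
    cy = float(rng.uniform(h / 2, 1 - h / 2))
    return Annotation(int(rng.integers(0, n_classes)), NormBox(cx, cy, w, h))


@pytest.fixture()
def random_annotations(rng):
    return [random_annotation(rng) for _ in range(25)]
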
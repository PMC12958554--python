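import numpy as np
import pandas as pd
import pytest

from nucmim.corpus import ImageCorpus, NucleusImage, SlideImage, split_corpus
from nucmim.model import TINY, MaskedAutoencoder, ModelConfig
from nucmim.synthetic import MorphParams, generate_labeled_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def micro_cfg():
    """A microscopic geometry for oracle-level forward/backward checks."""
    return ModelConfig(
        image_size=16, patch_size=8, d=8, enc_depth=1, enc_heads=2,
        dec_d=8, dec_depth=1, dec_heads=2, mask_ratio=0.5,
    )


@pytest.fixture(scope="session")
def tiny_model():
    """An untrained tiny-profile masked autoencoder (fixed init)."""
    return MaskedAutoencoder(TINY, seed=0)


@pytest.fixture(scope="session")
def two_class_cohort():
    """Well-separated 2-class cohort (small vs large nuclei), 60 per class."""
    cohort = generate_labeled_cohort(
        {"small": MorphParams(area_px=200), "large": MorphParams(area_px=600)},
        n_per_class=60, side_px=56, seed=11,
    )
    return split_corpus(cohort, (0.8, 0.2), seed=11)


@pytest.fixture
def small_corpus(rng):
    """A 10-image corpus with labels and splits for I/O round-trips."""
    images = [
        NucleusImage(
            pixels=rng.random((24, 24)).astype(np.float32),
            centroid=(i * 3 + 12, i * 2 + 12),
            window_um=20.0,
            source="slideA",
            cell_id=f"c{i}",
        )
        for i in range(10)
    ]
    labels = pd.Series([("x" if i < 5 else "y") for i in range(10)], name="label")
    splits = pd.Series(["train"] * 8 + ["val", "test"], name="split")
    return ImageCorpus.from_images(images, labels=labels, splits=splits)


@pytest.fixture
def gradient_dtype():
    """Run a block in float64 for finite-difference gradient checks."""
    import nucmim.nn as nn

    old = nn.DTYPE
    nn.DTYPE = np.float64
    yield np.float64
    nn.DTYPE = old
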
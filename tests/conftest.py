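import numpy as np
import pytest

from icgperf.classifier import FeedForwardNetClassifier
from icgperf.features import GreenHistogramFeatures
from icgperf.synthetic import SceneParams, generate_dataset


def random_patch(rng: np.random.Generator, h=None, w=None) -> np.ndarray:
    """Uniformly random uint8 RGB patch (unstructured, for oracle checks)."""
    h = h if h is not None else int(rng.integers(4, 40))
    w = w if w is not None else int(rng.integers(20, 90))
    return rng.integers(0, 256, size=(h, w, 3), dtype=np.uint8)


@pytest.fixture(scope="session")
def dataset470():
    """The balanced synthetic analogue of the 470-frame study dataset."""
    samples = generate_dataset(n=470, class_balance=0.5, seed=1)
    patches = [s.patch for s in samples]
    X = GreenHistogramFeatures(k=25).fit(patches).transform(patches)
    y = np.array([s.label for s in samples])
    return X, y


@pytest.fixture(scope="session")
def extreme_separable_Xy():
    """Zero-noise, maximally separated features: adequate slices full,
    inadequate slices empty."""
    base = SceneParams(green_sigma=0.0, noise_sd=0.0)
    samples = []
    import dataclasses

    for i in range(30):
        samples.append(
            dataclasses.replace(base, green_mu_high=200.0, perfused_fraction=1.0, seed=i)
        )
        samples.append(
            dataclasses.replace(
                base, green_mu_low=0.0, perfused_fraction=0.0, seed=1000 + i
            )
        )
    from icgperf.synthetic import generate_roi_patch

    labeled = [generate_roi_patch(p) for p in samples]
    patches = [s.patch for s in labeled]
    X = GreenHistogramFeatures(k=25).fit(patches).transform(patches)
    y = np.array([s.label for s in labeled])
    return X, y


@pytest.fixture(scope="session")
def trained_small_model(extreme_separable_Xy):
    X, y = extreme_separable_Xy
    return FeedForwardNetClassifier((20,), "relu", epochs=30, random_state=0).fit(X, y)
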
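import numpy as np
import pytest

from caencoder.omics_data import MultiOmicsDataset, OmicsModality
from caencoder.synthetic_data import SyntheticSpec, generate


@pytest.fixture
def tiny_dataset() -> MultiOmicsDataset:
    """12 samples, 2 classes, three small modalities — fast and fully visible."""
    rng = np.random.default_rng(7)
    ids = [f"P{i:02d}" for i in range(12)]
    labels = np.array(["tumA"] * 6 + ["tumB"] * 6)
    mods = []
    for name, dim in (("cnv", 5), ("mrna", 4), ("rppa", 3)):
        shift = np.where(labels == "tumA", 1.0, -1.0)[:, None]
        vals = rng.normal(size=(12, dim)) + shift
        mods.append(OmicsModality(name=name, values=vals,
                                  feature_names=[f"{name}{j}" for j in range(dim)],
                                  sample_ids=ids))
    return MultiOmicsDataset(modalities=mods, labels=labels)


@pytest.fixture
def small_synthetic() -> MultiOmicsDataset:
    """Three-class numeric-only dataset big enough for short trainings."""
    return generate(SyntheticSpec(
        n_classes=3, samples_per_class=(20, 20, 20), modality_dims=(12, 9, 6),
        latent_factor_dim=4, class_separation=6.0, shared_signal_fraction=0.6,
        noise_sd=0.5, categorical_fraction=0.0, seed=11))
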
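import numpy as np
import pytest

import fmcnet as F
from fmcnet.dataset_io import SplitSpec, build_input_tensors, make_splits


def make_split_tensors(images, labels, seed, target_size=64):
    records = [F.SampleRecord(str(i), int(lab)) for i, lab in enumerate(labels)]
    records = make_splits(records, SplitSpec(seed=seed))
    split_arr = np.array([r.split for r in records])
    return build_input_tensors(images, labels, split_arr, target_size, 3), split_arr


@pytest.fixture(scope="session")
def tiny_spec():
    return F.ArchitectureSpec(variant="FMC", size_profile="tiny")


@pytest.fixture(scope="session")
def small_dataset():
    """High-separation synthetic dataset small enough for quick training."""
    cfg = F.SyntheticConfig(n_samples=240, seed=7)
    images, labels, phenotypes, masks = F.generate_arrays(cfg)
    return cfg, images, labels, phenotypes, masks


@pytest.fixture(scope="session")
def trained_tiny(small_dataset, tiny_spec):
    """A tiny-profile FMC model trained from scratch on the small dataset."""
    _, images, labels, _, masks = small_dataset
    splits, split_arr = make_split_tensors(images, labels, seed=7)
    model = F.build_architecture(tiny_spec, rng=np.random.default_rng(7))
    model, history = F.train(model, splits, F.from_scratch_config(seed=7, epochs=20))
    return {"model": model, "splits": splits, "split_arr": split_arr,
            "images": images, "labels": labels, "masks": masks,
            "history": history}
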
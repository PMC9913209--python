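import numpy as np
import pytest

from tlradiomics import fixtures, transfer


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-patient cohort at 32 px, shared across read-only tests."""
    spec = fixtures.SyntheticCohortSpec(n=40, patch_size=32, seed=11)
    patches, table = fixtures.generate_target_cohort(spec)
    return patches, table


@pytest.fixture(scope="session")
def tiny_net_cfg():
    return transfer.NetworkConfig(
        stage_channels=(8, 12, 16), input_size=32, width_scale=1.0
    )


def toy_blob_images(n, size, seed, bright_fraction=0.5):
    """Linearly separable toy set: bright central blob vs dark noise."""
    rng = np.random.default_rng(seed)
    n_bright = int(round(n * bright_fraction))
    labels = np.array([1] * n_bright + [0] * (n - n_bright))
    yy, xx = np.mgrid[0:size, 0:size]
    c = (size - 1) / 2
    blob = np.exp(-(((yy - c) ** 2 + (xx - c) ** 2) / (2 * (size / 6) ** 2)))
    imgs = []
    for lab in labels:
        base = 0.1 + 0.05 * rng.standard_normal((size, size))
        if lab == 1:
            base = base + 0.8 * blob
        img = np.clip(base, 0, 1)
        imgs.append(np.stack([img, img, img], axis=-1))
    return np.stack(imgs), labels, blob > 0.5
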
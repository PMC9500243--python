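import numpy as np
import pytest

from plateletdet.geometry import Box


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_boxes(rng, n, lo=0, hi=64, integer=True, label="platelet"):
    """n random valid boxes with corners in [lo, hi]."""
    out = []
    while len(out) < n:
        if integer:
            xs = rng.integers(lo, hi, size=2)
            ys = rng.integers(lo, hi, size=2)
        else:
            xs = rng.uniform(lo, hi, size=2)
            ys = rng.uniform(lo, hi, size=2)
        x0, x1 = sorted(map(float, xs))
        y0, y1 = sorted(map(float, ys))
        if x1 > x0 and y1 > y0:
            out.append(Box(x0, y0, x1, y1, label=label))
    return out


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """A small on-disk synthetic dataset shared across tests in a session."""
    from plateletdet.synthetic_smear import SmearConfig, generate_dataset

    out = tmp_path_factory.mktemp("tiny_voc")
    cfg = SmearConfig(image_size=128, n_platelets=(2, 6),
                      n_erythrocytes=(2, 5), erythrocyte_diameter=(40.0, 60.0),
                      platelet_diameter=(6.0, 14.0), seed=7)
    split = generate_dataset(cfg, n_images=10, out_dir=out, seed=7,
                             counts=(6, 2, 2))
    return cfg, split, out
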
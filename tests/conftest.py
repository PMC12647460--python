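import numpy as np
import pytest

from phenotraits.synthetic import SceneSpec, generate_rosette, generate_silique_scene


@pytest.fixture(scope="session")
def rosette_scene():
    """A deterministic 8-leaf non-overlapping rosette with ground truth."""
    spec = SceneSpec(organ_class="leaf", n_organs=8, image_size=384, seed=11)
    image, truth = generate_rosette(spec)
    return image, truth


@pytest.fixture(scope="session")
def silique_scene():
    """A deterministic 12-silique scene without crossings."""
    spec = SceneSpec(
        organ_class="silique", n_organs=12, size_range=(60, 110),
        image_size=384, seed=3,
    )
    image, truth = generate_silique_scene(spec)
    return image, truth


@pytest.fixture(scope="session")
def crossing_silique_scene():
    """A silique scene with forced crossing capsule pairs."""
    spec = SceneSpec(
        organ_class="silique", n_organs=10, size_range=(60, 110),
        overlap=0.4, image_size=384, seed=3,
    )
    image, truth = generate_silique_scene(spec)
    return image, truth


def random_instance_map(rng, shape=(64, 64), n_instances=4):
    """Scatter random rectangles as instances (later ones overwrite)."""
    out = np.zeros(shape, dtype=np.int32)
    for k in range(1, n_instances + 1):
        h = rng.integers(4, 16)
        w = rng.integers(4, 16)
        r = rng.integers(0, shape[0] - h)
        c = rng.integers(0, shape[1] - w)
        out[r : r + h, c : c + w] = k
    # drop labels wiped out by overwriting and relabel densely
    from phenotraits.io_formats import relabel_contiguous

    out, _ = relabel_contiguous(out)
    return out
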
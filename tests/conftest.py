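import numpy as np
import pytest

from kflbpcm import PlantImage
from kflbpcm.synth import SceneSpec, default_species, render_scene


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def make_image(pixels, label="x", stage=1):
    return PlantImage(np.asarray(pixels, dtype=np.uint8), label=label, stage=stage)


def textured_image(rng, kind, size=32, label="x", stage=1):
    """Tiny images of trivially different texture for classifier tests."""
    if kind == "noisy":
        px = rng.integers(0, 256, (size, size, 3))
    else:  # smooth ramp with mild noise
        ramp = np.linspace(60, 200, size)[:, None]
        px = np.clip(ramp + rng.normal(0, 2, (size, size)), 0, 255)
        px = np.repeat(px[..., None], 3, axis=2)
    return make_image(px, label=label, stage=stage)


@pytest.fixture(scope="session")
def texture_dataset(rng):
    """10 noisy + 10 smooth 32×32 images: separable by any histogram feature."""
    imgs = [textured_image(rng, "noisy", label="noisy") for _ in range(10)]
    imgs += [textured_image(rng, "smooth", label="smooth") for _ in range(10)]
    return imgs


@pytest.fixture(scope="session")
def separable_points():
    """Two tight 2-D clouds around ±(5, 5): linearly separable by construction."""
    gen = np.random.default_rng(7)
    a = gen.normal(0, 0.1, (20, 2)) + 5.0
    b = gen.normal(0, 0.1, (20, 2)) - 5.0
    X = np.vstack([a, b])
    y = np.array(["pos"] * 20 + ["neg"] * 20)
    return X, y


@pytest.fixture(scope="session")
def small_plant_images():
    """A few 96×96 renders of the default species, one per (species, stage)."""
    species = default_species()
    imgs = []
    for i, (name, sp) in enumerate(species.items()):
        for stage in (2, 3):
            scene = SceneSpec(species=(sp,), stage=stage, rotation_deg=45.0 * i,
                              seed=100 + 10 * i + stage)
            imgs.append(render_scene(scene, size=(96, 96)))
    return imgs
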
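import numpy as np
import pytest

from dsseg.stacks import REFERENCE_SPACING, ImageStack
from dsseg.synth import IntensityModel, NucleusSpec, render


@pytest.fixture
def spacing():
    return REFERENCE_SPACING


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_stack(rng, spacing):
    """A small random 8-bit stack for round-trip and filter oracles."""
    vox = rng.integers(0, 256, size=(5, 32, 32), dtype=np.uint8)
    return ImageStack(vox, spacing, 8)


def render_nuclei(centers_um, size_um, snr=5.0, seed=7, semi_axes=(4.0, 2.0, 2.0), orientation=(0.0, 0.0, 1.0)):
    """Render an explicit list of identical nuclei (helper for fixtures)."""
    u = np.asarray(orientation, float)
    u = u / np.linalg.norm(u)
    nuclei = [NucleusSpec(np.asarray(c, float), semi_axes, u) for c in centers_um]
    model = IntensityModel.from_snr(snr)
    return render(nuclei, size_um, model, REFERENCE_SPACING, seed=seed)


@pytest.fixture
def five_separated_scene():
    """Five laterally well-separated nuclei at SNR 5 with known centroids.

    All five share the central z-slices so that every populated slice holds
    enough foreground for a stable per-slice Otsu split.
    """
    centers = [(8, 8, 17.5), (28, 8, 17.5), (8, 28, 17.5), (28, 28, 17.5), (18, 18, 17.5)]
    return render_nuclei(centers, (36, 36, 35))
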
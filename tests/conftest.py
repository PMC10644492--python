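import numpy as np
import pytest

from spykit import synth


def disk_mask(radius: int, pad: int = 5) -> np.ndarray:
    n = 2 * (radius + pad) + 1
    yy, xx = np.mgrid[:n, :n] - (radius + pad)
    return (xx ** 2 + yy ** 2) <= radius ** 2


def rectangle_mask(h: int, w: int, pad: int = 5) -> np.ndarray:
    out = np.zeros((h + 2 * pad, w + 2 * pad), dtype=bool)
    out[pad:pad + h, pad:pad + w] = True
    return out


@pytest.fixture(scope="session")
def straight_spike():
    """A straight default-appearance spike with ground truth."""
    spec = synth.SpikeSpec(orientation=90.0)
    mask, patch, truth = synth.render_spike(spec, seed=11)
    return {"spec": spec, "mask": mask, "patch": patch, "truth": truth}


@pytest.fixture(scope="session")
def small_scene():
    """A 3-spike scene with truth, shared across tests."""
    spec = synth.random_scene_spec(3, seed=21)
    image, truth = synth.render_scene(spec)
    return {"spec": spec, "image": image, "truth": truth}


@pytest.fixture(scope="session")
def spike_record(small_scene):
    from spykit.segment import SegmentationParams, extract_spike, segment_image

    _, scene, work = segment_image(small_scene["image"], SegmentationParams())
    return extract_spike(work, scene, 1)
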
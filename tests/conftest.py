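import numpy as np
import pytest

from ceusquant import CineLoop, Roi


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_cine(rng):
    """A 20-frame 16x16 random cine at 10 Hz."""
    frames = rng.integers(0, 256, size=(20, 16, 16), dtype=np.uint8)
    return CineLoop(frames=frames, frame_rate_hz=10.0)


@pytest.fixture
def full_frame_roi():
    return Roi(label="other:full", shape_kind="rectangle", bounds=(0, 0, 16, 16))


def random_roi(rng, frame_shape, label="other:random"):
    """Draw a random circle / rectangle / polygon ROI inside frame_shape."""
    rows, cols = frame_shape
    kind = rng.choice(["circle", "rectangle", "polygon"])
    if kind == "circle":
        return Roi(
            label=label,
            shape_kind="circle",
            center=(rng.uniform(2, rows - 3), rng.uniform(2, cols - 3)),
            radius=rng.uniform(1.0, min(rows, cols) / 3),
        )
    if kind == "rectangle":
        top = rng.integers(0, rows - 4)
        left = rng.integers(0, cols - 4)
        return Roi(
            label=label,
            shape_kind="rectangle",
            bounds=(top, left, rng.integers(2, rows - top - 1), rng.integers(2, cols - left - 1)),
        )
    # star-shaped polygon around a random center: simple (non-self-intersecting)
    cr = rng.uniform(rows * 0.3, rows * 0.7)
    cc = rng.uniform(cols * 0.3, cols * 0.7)
    n_vert = int(rng.integers(3, 9))
    angles = np.sort(rng.uniform(0, 2 * np.pi, size=n_vert))
    radii = rng.uniform(2.0, min(rows, cols) * 0.45, size=n_vert)
    verts = [(cr + r * np.sin(a), cc + r * np.cos(a)) for r, a in zip(radii, angles)]
    return Roi(label=label, shape_kind="polygon", vertices=verts)
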
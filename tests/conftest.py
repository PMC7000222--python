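import numpy as np
import pytest

from fretscope import SceneConfig, generate_scene
from fretscope.synthetic import noise_free


def disk_mask(radius: float, shape=(64, 64), center=None) -> np.ndarray:
    """Binary disk: pixels whose center lies within ``radius`` of ``center``."""
    if center is None:
        center = ((shape[0] - 1) / 2, (shape[1] - 1) / 2)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def linescan_oracle(pair, mask, bin_width_px=1.0):
    """Brute-force re-derivation of the linescan recovery profile.

    Naive per-line bilinear sampling and naive binning, independent of the
    package's vectorized sampling code path.
    """
    pre, post = pair.pre.donor[0], pair.post.donor[0]
    centroid = np.asarray(mask.centroids[0])
    max_line = max(float(np.hypot(*(centroid - p)))
                   for p in mask.boundaries[0].astype(float))
    n_bins = max(1, int(np.ceil(max_line / bin_width_px)))
    sums = np.zeros((2, n_bins))
    counts = np.zeros(n_bins)

    def bilinear(img, r, c):
        r0 = min(max(int(np.floor(r)), 0), img.shape[0] - 2)
        c0 = min(max(int(np.floor(c)), 0), img.shape[1] - 2)
        fr, fc = r - r0, c - c0
        return ((1 - fr) * (1 - fc) * img[r0, c0]
                + (1 - fr) * fc * img[r0, c0 + 1]
                + fr * (1 - fc) * img[r0 + 1, c0]
                + fr * fc * img[r0 + 1, c0 + 1])

    for p0 in mask.boundaries[0].astype(float):
        vec = centroid - p0
        length = float(np.hypot(*vec))
        ts = list(np.arange(0.0, length, 1.0))
        if not ts or ts[-1] < length:
            ts.append(length)
        for t in ts:
            pt = p0 + (vec / length) * t
            k = min(int(t / bin_width_px), n_bins - 1)
            sums[0, k] += bilinear(pre, *pt)
            sums[1, k] += bilinear(post, *pt)
            counts[k] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        return (1 - (sums[0] / counts) / (sums[1] / counts)) * 100


@pytest.fixture(scope="session")
def clean_scene():
    """Zero-noise default-geometry scene with ground truth."""
    cfg = noise_free(SceneConfig(image_shape=(72, 72), cell_radius_px=24,
                                 n_frames=12, boundary_motility_amp_px=0.0,
                                 seed=7))
    frames, truth = generate_scene(cfg)
    return cfg, frames, truth
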
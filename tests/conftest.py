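import numpy as np
import pytest

from cristaquant import Image2D, SIGMA_PER_FWHM


def flood_fill_segments(values: np.ndarray, threshold_fraction: float):
    """Brute-force 8-connected segmentation oracle.

    Thresholds at ``threshold_fraction`` of the global maximum and
    labels components by explicit stack-based flood fill; returns the
    sorted list of pixel counts per segment.
    """
    vmax = values.max()
    if vmax <= 0:
        return []
    mask = values >= threshold_fraction * vmax
    seen = np.zeros_like(mask, dtype=bool)
    ny, nx = mask.shape
    sizes = []
    for i in range(ny):
        for j in range(nx):
            if not mask[i, j] or seen[i, j]:
                continue
            stack = [(i, j)]
            seen[i, j] = True
            size = 0
            while stack:
                a, b = stack.pop()
                size += 1
                for da in (-1, 0, 1):
                    for db in (-1, 0, 1):
                        na, nb = a + da, b + db
                        if 0 <= na < ny and 0 <= nb < nx and mask[na, nb] and not seen[na, nb]:
                            seen[na, nb] = True
                            stack.append((na, nb))
            sizes.append(size)
    return sorted(sizes)


@pytest.fixture
def flood_fill_oracle():
    return flood_fill_segments


def gaussian_blob(shape, center_rc, fwhm_px, amplitude=1000.0):
    """Analytic Gaussian spot on a zero background (pixel-centre sampling)."""
    sigma = fwhm_px * SIGMA_PER_FWHM
    rr, cc = np.indices(shape)
    r0, c0 = center_rc
    return amplitude * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma**2))


@pytest.fixture
def make_blob_image():
    def _make(shape=(64, 64), centers=((32, 32),), fwhm_nm=80.0, pixel_size_nm=20.0):
        img = np.zeros(shape)
        for rc in centers:
            img += gaussian_blob(shape, rc, fwhm_nm / pixel_size_nm)
        return Image2D(img, pixel_size_nm)

    return _make
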
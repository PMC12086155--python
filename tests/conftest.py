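import numpy as np
import pytest

from leafcolor.histogram import ColorHistogram
from leafcolor.metrics import REFERENCE_GREEN_PALETTE


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def palette_histogram():
    """One pixel per reference palette code (12 green codes, 4 per band)."""
    counts = {}
    for codes in REFERENCE_GREEN_PALETTE.values():
        for code in codes:
            counts[code] = 1
    return ColorHistogram.from_counts(counts)


@pytest.fixture
def random_grid(rng):
    """A 64x64 RGB image with a broad random color distribution."""
    return rng.integers(0, 256, size=(64, 64, 3), dtype=np.uint8)


def brute_force_metrics(grid, mask, dark_mode="threshold"):
    """Per-pixel loop oracle for intensity and dark-green proportion.

    Deliberately avoids the histogram path: iterates over pixels one by one
    and applies the definitions directly.
    """
    from leafcolor.metrics import DARK_GREEN_CODES

    h, w = grid.shape[:2]
    n_green = 0
    intensity_sum = 0.0
    dark = 0
    bands = {"dark": 0, "medium": 0, "light": 0}
    for i in range(h):
        for j in range(w):
            if not mask[i, j]:
                continue
            r, g, b = (int(v) for v in grid[i, j])
            if not (g > r and g > b):
                continue
            n_green += 1
            intensity_sum += (r / 255 + g / 255 + b / 255) / 3
            if g <= 85:
                bands["dark"] += 1
            elif g <= 170:
                bands["medium"] += 1
            else:
                bands["light"] += 1
            if dark_mode == "threshold":
                if g <= 85:
                    dark += 1
            else:
                if (r, g, b) in DARK_GREEN_CODES:
                    dark += 1
    if n_green == 0:
        return None
    return {
        "n_green_pixels": n_green,
        "intensity": intensity_sum / n_green,
        "dark_green_proportion": dark / n_green,
        "band_proportions": {k: v / n_green for k, v in bands.items()},
    }
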
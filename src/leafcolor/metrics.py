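"""Leaf-color response variables from a color histogram.

Two statistics summarize the green pixels of a segmented canopy photo:

* **normalized intensity** ``I`` — the pixel mean of ``(R + G + B)/3`` after
  scaling each channel to [0, 1].  ``I = 0`` is black, ``I = 1`` is white;
  dark, chlorophyll-rich leaves score low.
* **dark-green proportion** — the fraction of green pixels classified dark
  green, an RGB proxy for nitrogen status.

A pixel is *green* when its G value strictly exceeds both R and B; only
green pixels enter either statistic.  The G channel splits into three bands:
dark (0-85), medium (86-170), light (171-255).  Dark-green membership has
two definitions, selectable by ``mode``:

* ``"threshold"`` (default) — G <= 85, robust to the exact palette a GIF
  quantizer produced;
* ``"codeset"`` — membership in the four dark codes most commonly produced
  by 256-color palette reduction of lettuce canopies, (0,43,0), (0,85,0),
  (51,85,0), (51,85,51).

The codeset is a strict subset of the dark band, so the codeset proportion
can never exceed the threshold proportion.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InputError, NoGreenPixelsError
from .histogram import ColorHistogram, RGBTriple

#: G-channel band edges: dark is [0, 85], medium [86, 170], light [171, 255].
DARK_BAND_MAX = 85
MEDIUM_BAND_MAX = 170

#: The four dark-green codes used by the literal "codeset" definition.
DARK_GREEN_CODES: frozenset[RGBTriple] = frozenset(
    {(0, 43, 0), (0, 85, 0), (51, 85, 0), (51, 85, 51)}
)

#: Twelve green codes commonly observed after 256-color palette reduction of
#: lettuce canopy photos, four per band.  Used as the default synthetic leaf
#: palette and as a classification fixture.
REFERENCE_GREEN_PALETTE: dict[str, tuple[RGBTriple, ...]] = {
    "dark": ((0, 43, 0), (0, 85, 0), (51, 85, 0), (51, 85, 51)),
    "medium": ((102, 128, 0), (102, 128, 51), (102, 170, 0), (102, 170, 51)),
    "light": ((102, 213, 102), (153, 213, 51), (153, 213, 102), (204, 255, 102)),
}

DARK_MODES = ("threshold", "codeset")


def is_green(r: int, g: int, b: int) -> bool:
    """Green-pixel rule: G strictly exceeds both R and B (ties excluded)."""
    return g > r and g > b


def filter_green(hist: ColorHistogram) -> ColorHistogram:
    """Histogram restricted to colors passing the green-pixel rule."""
    return hist.filter(is_green)


def classify_green_band(color: RGBTriple) -> str:
    """Band of a green color by its G value: 'dark', 'medium' or 'light'."""
    r, g, b = color
    if not is_green(r, g, b):
        raise InputError(f"color {color!r} does not satisfy the green rule")
    if g <= DARK_BAND_MAX:
        return "dark"
    if g <= MEDIUM_BAND_MAX:
        return "medium"
    return "light"


def normalized_intensity(hist: ColorHistogram) -> float:
    """Count-weighted mean of (R+G+B)/3 with channels scaled to [0, 1].

    Expects a green-filtered histogram; raises :class:`NoGreenPixelsError`
    when it is empty.
    """
    if not hist:
        raise NoGreenPixelsError("cannot compute intensity of an empty histogram")
    total = hist.total_pixels
    weighted = sum(n * (r + g + b) for (r, g, b), n in hist.items())
    return weighted / (3.0 * 255.0 * total)


def dark_green_proportion(hist: ColorHistogram, mode: str = "threshold") -> float:
    """Fraction of green pixels classified dark green.

    ``threshold``: G <= 85.  ``codeset``: color is one of the four reference
    dark codes.  Denominator is the total green pixel count in either mode.
    """
    if mode not in DARK_MODES:
        raise InputError(f"unknown dark-green mode {mode!r}; expected {DARK_MODES}")
    if not hist:
        raise NoGreenPixelsError("cannot compute dark proportion of an empty histogram")
    total = hist.total_pixels
    if mode == "threshold":
        dark = sum(n for (r, g, b), n in hist.items() if g <= DARK_BAND_MAX)
    else:
        dark = sum(n for c, n in hist.items() if c in DARK_GREEN_CODES)
    return dark / total


@dataclass(frozen=True)
class ColorMetricsResult:
    """The color statistics of one plant image (one device, one photo)."""

    intensity: float
    dark_green_proportion: float
    band_proportions: dict[str, float]
    n_green_pixels: int
    mode: str = "threshold"

    def as_dict(self) -> dict:
        d = {
            "intensity": self.intensity,
            "dark_green_proportion": self.dark_green_proportion,
            "n_green_pixels": self.n_green_pixels,
            "mode": self.mode,
        }
        d.update({f"p_{band}": p for band, p in self.band_proportions.items()})
        return d


def compute_metrics(hist: ColorHistogram, mode: str = "threshold") -> ColorMetricsResult:
    """Apply the green rule, then both color statistics and band proportions."""
    green = filter_green(hist)
    if not green:
        raise NoGreenPixelsError("no pixels pass the green rule")
    total = green.total_pixels
    band_counts = {"dark": 0, "medium": 0, "light": 0}
    for color, n in green.items():
        band_counts[classify_green_band(color)] += n
    return ColorMetricsResult(
        intensity=normalized_intensity(green),
        dark_green_proportion=dark_green_proportion(green, mode=mode),
        band_proportions={b: c / total for b, c in band_counts.items()},
        n_green_pixels=total,
        mode=mode,
    )


def average_metrics(a: ColorMetricsResult, b: ColorMetricsResult) -> ColorMetricsResult:
    """Device-averaged metrics: arithmetic mean of two devices' results.

    Two cameras render the same canopy differently; with no ground truth to
    prefer either, their average is the more robust per-plant value.
    """
    if a.mode != b.mode:
        raise InputError(f"cannot average metrics with modes {a.mode!r} and {b.mode!r}")
    bands = {
        band: (a.band_proportions[band] + b.band_proportions[band]) / 2.0
        for band in a.band_proportions
    }
    return ColorMetricsResult(
        intensity=(a.intensity + b.intensity) / 2.0,
        dark_green_proportion=(a.dark_green_proportion + b.dark_green_proportion) / 2.0,
        band_proportions=bands,
        n_green_pixels=a.n_green_pixels + b.n_green_pixels,
        mode=a.mode,
    )
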
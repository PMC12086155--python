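"""Synthetic study generator: canopy images, paired devices, growth records.

No raw photographs are distributed with this package, so every stage of the
pipeline is exercised against generated data whose statistical structure
matches what the analysis assumes:

* **canopy images** — elliptical leaf blobs colored by a categorical mixture
  over a small green palette, on a dark (studio cloth) or soil-colored
  background, with exact ground-truth masks and color metrics;
* **paired devices** — two cameras measure the same targets with a
  systematic offset (one renders more saturated, hence darker-green and
  lower-intensity readings) plus independent measurement noise;
* **growth records** — per-plant endpoints in which the treatment shifts
  the leaf-color distribution (nitrogen: darker, control: paler) and fresh
  weight depends linearly on the dark-green proportion.

Everything is seed-deterministic and uses documented distributions only
(uniform blob placement, normal noise, categorical color mixture, Poisson
leaf counts).  Leaf geometry is decorative; only the color distribution
feeds the statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .agreement import PairedSample
from .errors import ConfigError, InputError
from .histogram import RGBTriple
from .image import build_histogram
from .metrics import (
    REFERENCE_GREEN_PALETTE,
    ColorMetricsResult,
    compute_metrics,
)

# ---------------------------------------------------------------------------
# Canopy images
# ---------------------------------------------------------------------------

#: Dark studio-cloth background used in the single-scene multi-plant protocol.
BLACK_BACKGROUND: RGBTriple = (8, 8, 8)
#: Soil-and-pot background used in the per-plant protocol.
SOIL_BACKGROUND: RGBTriple = (110, 80, 55)


def mixture_for_dark_fraction(
    dark_fraction: float, light_share: float = 0.0
) -> list[tuple[RGBTriple, float]]:
    """Palette mixture whose expected dark-green proportion is ``dark_fraction``.

    The dark weight is split evenly over the four reference dark codes; the
    remainder goes to the medium codes, minus an optional ``light_share``
    routed to the light codes.
    """
    if not 0.0 <= dark_fraction <= 1.0:
        raise InputError(f"dark_fraction must be in [0, 1], got {dark_fraction}")
    rest = 1.0 - dark_fraction
    if not 0.0 <= light_share <= rest + 1e-12:
        raise InputError("light_share cannot exceed the non-dark weight")
    mixture: list[tuple[RGBTriple, float]] = []
    for code in REFERENCE_GREEN_PALETTE["dark"]:
        mixture.append((code, dark_fraction / 4.0))
    for code in REFERENCE_GREEN_PALETTE["medium"]:
        mixture.append((code, (rest - light_share) / 4.0))
    if light_share > 0:
        for code in REFERENCE_GREEN_PALETTE["light"]:
            mixture.append((code, light_share / 4.0))
    return mixture


@dataclass(frozen=True)
class SyntheticImageSpec:
    """Generative description of one synthetic canopy photo."""

    width: int = 192
    height: int = 192
    background: RGBTriple = BLACK_BACKGROUND
    background_noise_sd: float = 3.0
    n_blobs: int = 6
    blob_radius_range: tuple[int, int] = (18, 45)
    leaf_color_mixture: list[tuple[RGBTriple, float]] = field(
        default_factory=lambda: mixture_for_dark_fraction(0.3)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise InputError("image dimensions must be positive")
        w = sum(wgt for _, wgt in self.leaf_color_mixture)
        if abs(w - 1.0) > 1e-9:
            raise InputError(f"mixture weights must sum to 1, got {w}")

    @classmethod
    def for_dark_fraction(cls, dark_fraction: float, **kw) -> "SyntheticImageSpec":
        return cls(leaf_color_mixture=mixture_for_dark_fraction(dark_fraction), **kw)


def gen_canopy_image(
    spec: SyntheticImageSpec,
) -> tuple[np.ndarray, np.ndarray, ColorMetricsResult]:
    """Render a canopy scene; return (image, truth mask, truth metrics).

    Leaf pixels take exact palette colors drawn from the mixture, so the
    returned metrics are the exact color statistics of the emitted leaf
    region.  Background pixels carry normal sensor noise.  Deterministic in
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    r_lo, r_hi = spec.blob_radius_range
    if r_lo < 1 or r_hi < r_lo:
        raise ConfigError(f"bad blob radius range {spec.blob_radius_range}")
    if 2 * r_lo >= min(w, h):
        raise ConfigError(
            f"blobs of radius >= {r_lo} cannot fit a {w}x{h} image"
        )

    bg = np.array(spec.background, dtype=float)
    grid = bg + rng.normal(0.0, spec.background_noise_sd, size=(h, w, 3))
    grid = np.clip(np.rint(grid), 0, 255).astype(np.uint8)

    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.zeros((h, w), dtype=bool)
    for _ in range(spec.n_blobs):
        a = rng.integers(r_lo, r_hi + 1)  # semi-axes
        b = rng.integers(r_lo, r_hi + 1)
        cx = rng.integers(a, w - a + 1)
        cy = rng.integers(b, h - b + 1)
        mask |= ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0

    colors = np.array([c for c, _ in spec.leaf_color_mixture], dtype=np.uint8)
    weights = np.array([p for _, p in spec.leaf_color_mixture], dtype=float)
    n_leaf = int(mask.sum())
    if n_leaf == 0:
        raise ConfigError("no leaf pixels were generated")
    idx = rng.choice(len(colors), size=n_leaf, p=weights / weights.sum())
    grid[mask] = colors[idx]

    truth = compute_metrics(build_histogram(grid, mask))
    return grid, mask, truth


# ---------------------------------------------------------------------------
# Device forward model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DeviceModel:
    """How one camera renders / measures a scene.

    ``intensity_bias`` shifts the measured normalized intensity additively
    (metric level) or all channels by ``255 * bias`` (image level);
    ``saturation_gain`` scales chroma about the per-pixel mean, emulating a
    camera that renders more saturated color; ``noise_sd`` is per-measurement
    noise on the metric scale.
    """

    intensity_bias: float = 0.0
    saturation_gain: float = 1.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise InputError("noise_sd must be >= 0")


def apply_device(grid: np.ndarray, device: DeviceModel) -> np.ndarray:
    """Image-level device rendering: chroma gain about the pixel mean, then
    an additive intensity shift of ``255 * intensity_bias`` per channel."""
    g = np.asarray(grid, dtype=float)
    mean = g.mean(axis=-1, keepdims=True)
    out = mean + device.saturation_gain * (g - mean) + 255.0 * device.intensity_bias
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def gen_paired_device(
    truth,
    device_a: DeviceModel,
    device_b: DeviceModel,
    n: int | None = None,
    seed: int = 0,
    parameter: str = "value",
) -> PairedSample:
    """Metric-level paired measurements of common targets by two devices.

    ``truth`` is a scalar (one target value replicated ``n`` times) or an
    array of per-target true values.  Each device reads
    ``truth + intensity_bias + Normal(0, noise_sd)`` independently, so the
    expected difference y - x equals the difference of the device biases.
    """
    truth = np.atleast_1d(np.asarray(truth, dtype=float))
    if truth.size == 1:
        if n is None or n < 2:
            raise InputError("scalar truth requires n >= 2")
        truth = np.full(n, truth[0])
    elif n is not None and n != truth.size:
        raise InputError(f"n={n} disagrees with {truth.size} truth values")
    rng = np.random.default_rng(seed)
    x = truth + device_a.intensity_bias + rng.normal(0.0, device_a.noise_sd, truth.size)
    y = truth + device_b.intensity_bias + rng.normal(0.0, device_b.noise_sd, truth.size)
    return PairedSample(x=x, y=y, parameter=parameter)


# ---------------------------------------------------------------------------
# Growth experiment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticExperimentConfig:
    """Ground-truth generative parameters of one synthetic fertilizer trial.

    Defaults mirror a small greenhouse trial: four treatments (C control,
    N nitrogen, LV leafy-vegetable, I microelement) with eight plants each;
    nitrogen darkens the canopy most, the control least; normalized
    intensity declines linearly with the dark-green proportion; and fresh
    weight (g) increases linearly with the dark-green proportion on top of
    treatment-specific baselines, with normal measurement noise.
    """

    n_per_treatment: int = 8
    #: mean dark-green proportion per treatment (the color the fertilizer induces)
    dark_mean: dict[str, float] = field(
        default_factory=lambda: {"C": 0.25, "LV": 0.40, "N": 0.55, "I": 0.30}
    )
    dark_sd: float = 0.08
    #: intensity = intercept + slope * dark + noise (negative association)
    intensity_intercept: float = 0.35
    intensity_slope: float = -0.35
    intensity_sd: float = 0.02
    #: fresh_weight = a_t + beta * dark + Normal(0, sigma)
    weight_intercepts: dict[str, float] = field(
        default_factory=lambda: {"C": 10.0, "LV": 20.0, "N": 25.0, "I": 12.0}
    )
    beta: float = 150.0
    sigma: float = 8.0
    #: expected leaf counts (weak treatment effect, as observed in practice)
    leaf_mean: dict[str, float] = field(
        default_factory=lambda: {"C": 10.0, "LV": 10.5, "N": 11.5, "I": 10.0}
    )
    experiment_id: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_treatment < 2:
            raise InputError("n_per_treatment must be >= 2")
        if self.sigma < 0 or self.dark_sd < 0 or self.intensity_sd < 0:
            raise InputError("noise standard deviations must be >= 0")


def gen_experiment(config: SyntheticExperimentConfig) -> pd.DataFrame:
    """Generate one experiment's plant records as a tidy table.

    Per plant: dark-green proportion ~ Normal(treatment mean, dark_sd)
    clipped to (0, 1); intensity from the configured negative linear link
    plus noise, clipped to (0, 1); fresh weight from the linear weight link;
    leaf count ~ Poisson(treatment mean).  Deterministic in ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for treatment, mu_dark in config.dark_mean.items():
        for i in range(config.n_per_treatment):
            dark = float(
                np.clip(rng.normal(mu_dark, config.dark_sd), 0.02, 0.98)
            )
            intensity = float(
                np.clip(
                    config.intensity_intercept
                    + config.intensity_slope * dark
                    + rng.normal(0.0, config.intensity_sd),
                    0.01,
                    0.99,
                )
            )
            weight = float(
                config.weight_intercepts[treatment]
                + config.beta * dark
                + rng.normal(0.0, config.sigma)
            )
            rows.append(
                {
                    "plant_id": f"{config.experiment_id}-{treatment}-{i + 1:02d}",
                    "experiment_id": config.experiment_id,
                    "treatment": treatment,
                    "fresh_weight": max(weight, 1.0),
                    "leaf_count": int(rng.poisson(config.leaf_mean[treatment])),
                    "intensity": intensity,
                    "dark_green_proportion": dark,
                }
            )
    return pd.DataFrame(rows)


def gen_experiment_images(
    config: SyntheticExperimentConfig,
    image_size: int = 128,
) -> tuple[pd.DataFrame, dict[str, tuple[np.ndarray, np.ndarray, ColorMetricsResult]]]:
    """Generate records *and* a canopy image per plant.

    The per-plant image's palette mixture is centred on the record's
    dark-green proportion, so image-derived metrics track the tabulated
    ground truth.  Returns the record table and a mapping from plant_id to
    (image, truth mask, truth metrics).
    """
    records = gen_experiment(config)
    scenes = {}
    for k, row in enumerate(records.itertuples()):
        spec = SyntheticImageSpec(
            width=image_size,
            height=image_size,
            blob_radius_range=(max(8, image_size // 10), max(12, image_size // 4)),
            leaf_color_mixture=mixture_for_dark_fraction(row.dark_green_proportion),
            seed=(config.seed * 100003 + k) % (2**31),
        )
        scenes[row.plant_id] = gen_canopy_image(spec)
    return records, scenes
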
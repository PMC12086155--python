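"""End-to-end orchestration: photos -> metrics -> agreement -> growth stats.

The pipeline mirrors the study workflow: canopy photos from two devices are
palette-reduced, segmented, tallied into color histograms, and summarized
as normalized intensity and dark-green proportion per plant and device;
the two devices are compared by Bland-Altman analysis and their readings
averaged; the averaged metrics are joined with the growth metadata and fed
to the treatment/weight statistics.

Image files are expected to be named ``<plant_id>__<device>.<ext>``; masks,
when supplied, are ``<plant_id>__<device>.png`` under ``mask_dir`` with
nonzero pixels marking vegetation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .agreement import BlandAltman, agreement_table
from .errors import InputError, InsufficientDataError, LeafColorError
from .growth import ExperimentReport, experiment_report, validate_records
from .image import build_histogram, quantize_palette, read_image, read_mask, write_image
from .metrics import ColorMetricsResult, average_metrics, compute_metrics
from .synthetic import (
    DeviceModel,
    SyntheticExperimentConfig,
    apply_device,
    gen_experiment_images,
    gen_paired_device,
)

logger = logging.getLogger(__name__)

IMAGE_EXTENSIONS = (".png", ".jpg", ".jpeg", ".gif")

PARAMETERS = ("intensity", "dark_green_proportion")


@dataclass
class PipelineConfig:
    """Run-time configuration of the full analysis."""

    image_dir: Path | None = None
    metadata_path: Path | None = None
    mask_dir: Path | None = None
    output_dir: Path = Path("leafcolor_out")
    segmentation_mode: str = "black-background"
    segmentation_threshold: float | None = None
    quantize: bool = True
    max_colors: int = 256
    dark_mode: str = "threshold"
    adjust: str | None = None
    device_a: str = "A"
    device_b: str = "B"
    seed: int = 0

    def __post_init__(self) -> None:
        for attr in ("image_dir", "metadata_path", "mask_dir", "output_dir"):
            v = getattr(self, attr)
            if v is not None:
                setattr(self, attr, Path(v))


@dataclass
class ReportBundle:
    """Everything the end-to-end run produced."""

    metrics: pd.DataFrame
    agreement: pd.DataFrame
    records: pd.DataFrame
    report: ExperimentReport
    output_dir: Path
    n_images: int = 0
    n_skipped: int = 0


def parse_image_name(path: Path) -> tuple[str, str]:
    """Split ``<plant_id>__<device>`` out of an image file name."""
    stem = path.stem
    if "__" not in stem:
        raise InputError(
            f"image name {path.name!r} does not follow '<plant_id>__<device>'"
        )
    plant_id, device = stem.rsplit("__", 1)
    return plant_id, device


def analyze_image(
    path: str | Path,
    config: PipelineConfig | None = None,
    mask_path: str | Path | None = None,
) -> ColorMetricsResult:
    """Color metrics of one photo: decode, quantize, segment, tally, summarize."""
    config = config or PipelineConfig()
    grid = read_image(path)
    if config.quantize:
        grid = quantize_palette(grid, config.max_colors)
    if mask_path is not None:
        mask = read_mask(mask_path)
        if mask.shape != grid.shape[:2]:
            raise InputError(
                f"mask {mask_path} shape {mask.shape} does not match image {path}"
            )
    else:
        from .image import segment_vegetation

        mask = segment_vegetation(
            grid, mode=config.segmentation_mode, threshold=config.segmentation_threshold
        )
    hist = build_histogram(grid, mask)
    logger.info(
        "%s: %d/%d pixels masked as vegetation", path, hist.total_pixels, mask.size
    )
    return compute_metrics(hist, mode=config.dark_mode)


def run_batch(config: PipelineConfig) -> tuple[pd.DataFrame, int]:
    """Analyze every image in ``config.image_dir``; skip-and-log failures.

    Returns the per-image metrics table and the number of skipped files.
    """
    if config.image_dir is None or not config.image_dir.is_dir():
        raise InputError(f"image directory not found: {config.image_dir}")
    paths = sorted(
        p
        for p in config.image_dir.iterdir()
        if p.suffix.lower() in IMAGE_EXTENSIONS
    )
    if not paths:
        raise InputError(f"no images found in {config.image_dir}")
    rows, skipped = [], 0
    for p in paths:
        try:
            plant_id, device = parse_image_name(p)
            mask_path = None
            if config.mask_dir is not None:
                candidate = config.mask_dir / f"{p.stem}.png"
                if candidate.exists():
                    mask_path = candidate
            metrics = analyze_image(p, config, mask_path=mask_path)
        except LeafColorError as exc:
            logger.warning("skipping %s: %s", p.name, exc)
            skipped += 1
            continue
        rows.append({"plant_id": plant_id, "device": device, **metrics.as_dict()})
    if not rows:
        raise InputError(f"every image in {config.image_dir} failed to analyze")
    return pd.DataFrame(rows), skipped


def run_agreement(metrics: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Bland-Altman summary per color parameter across the two devices."""
    results = []
    wide = metrics.pivot_table(
        index="plant_id", columns="device", values=list(PARAMETERS)
    )
    for param in PARAMETERS:
        try:
            sub = wide[param][[config.device_a, config.device_b]].dropna()
        except KeyError as exc:
            raise InputError(
                f"metrics table lacks device {exc} for parameter {param!r}"
            ) from exc
        ba = BlandAltman(
            sub[config.device_a].to_numpy(),
            sub[config.device_b].to_numpy(),
            parameter=param,
        )
        results.append(ba.fit())
    return agreement_table(results)


def average_devices(metrics: pd.DataFrame) -> pd.DataFrame:
    """Per-plant device-averaged intensity and dark-green proportion."""
    return (
        metrics.groupby("plant_id", as_index=False)[list(PARAMETERS)]
        .mean()
    )


def run_stats(
    records: pd.DataFrame,
    agreement: pd.DataFrame | None = None,
    adjust: str | None = None,
) -> ExperimentReport:
    validate_records(records, require_metrics=True)
    return experiment_report(records, agreement=agreement)


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute the full workflow and write all tables under ``output_dir``.

    Fails fast when the inputs are missing; partial per-image failures are
    skipped and counted.  Deterministic given the same configuration.
    """
    if config.metadata_path is None or not Path(config.metadata_path).exists():
        raise InputError(f"metadata table not found: {config.metadata_path}")
    metrics, skipped = run_batch(config)
    agreement = run_agreement(metrics, config)
    averaged = average_devices(metrics)

    meta = pd.read_csv(config.metadata_path)
    records = meta.merge(averaged, on="plant_id", how="inner", suffixes=("_meta", ""))
    dropped = len(meta) - len(records)
    if dropped:
        logger.warning("%d metadata record(s) had no matching images", dropped)
    report = run_stats(records, agreement=agreement, adjust=config.adjust)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    metrics.to_csv(out / "metrics.csv", index=False)
    agreement.to_csv(out / "agreement.csv", index=False)
    records.to_csv(out / "records.csv", index=False)
    if not report.empty:
        report.treatment_table.to_csv(out / "treatment_means.csv", index=False)
        pd.DataFrame([f.as_dict() for f in report.fits.values()]).to_csv(
            out / "weight_color_fits.csv", index=False
        )
    (out / "summary.txt").write_text(report.summary())
    return ReportBundle(
        metrics=metrics,
        agreement=agreement,
        records=records,
        report=report,
        output_dir=out,
        n_images=len(metrics),
        n_skipped=skipped,
    )


# ---------------------------------------------------------------------------
# Simulation entry point
# ---------------------------------------------------------------------------

#: Default forward models for the two device classes.  Device B (the more
#: saturated renderer) reads a higher normalized intensity and a lower
#: dark-green proportion than device A for the same scene.
DEFAULT_DEVICE_A = DeviceModel(intensity_bias=0.0, saturation_gain=1.0, noise_sd=0.015)
DEFAULT_DEVICE_B = DeviceModel(intensity_bias=0.03, saturation_gain=1.15, noise_sd=0.015)
#: Device B's additive offset on the dark-green-proportion scale.
DEFAULT_DARK_BIAS_B = -0.10


def simulate_study(
    out_dir: str | Path,
    config: SyntheticExperimentConfig | None = None,
    device_a: DeviceModel = DEFAULT_DEVICE_A,
    device_b: DeviceModel = DEFAULT_DEVICE_B,
    dark_bias_b: float = DEFAULT_DARK_BIAS_B,
    image_size: int = 128,
    write_images: bool = True,
) -> dict[str, Path]:
    """Write a complete synthetic study to disk.

    Produces per-plant canopy PNGs as seen by each device, a ground-truth
    manifest, a per-device metrics table (metric-level device model), and
    the plant-record table ready for the statistics stage.
    """
    config = config or SyntheticExperimentConfig()
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    records, scenes = gen_experiment_images(config, image_size=image_size)

    truth_rows = []
    for plant_id, (grid, mask, truth) in scenes.items():
        if write_images:
            write_image(apply_device(grid, device_a), out / "images" / f"{plant_id}__A.png")
            write_image(apply_device(grid, device_b), out / "images" / f"{plant_id}__B.png")
            from PIL import Image

            # same truth mask applies to both device renderings
            for device in ("A", "B"):
                Image.fromarray((mask * 255).astype(np.uint8), mode="L").save(
                    out / "masks" / f"{plant_id}__{device}.png"
                )
        truth_rows.append({"plant_id": plant_id, **truth.as_dict()})
    pd.DataFrame(truth_rows).to_csv(out / "truth_manifest.csv", index=False)

    # metric-level device readings of the tabulated ground truth
    rng_seed = (config.seed + 1) % (2**31)
    rows = []
    for param, bias_b in (
        ("intensity", device_b.intensity_bias),
        ("dark_green_proportion", dark_bias_b),
    ):
        truth_vals = records[param].to_numpy()
        pair = gen_paired_device(
            truth_vals,
            DeviceModel(0.0, 1.0, device_a.noise_sd),
            DeviceModel(bias_b, 1.0, device_b.noise_sd),
            seed=rng_seed,
            parameter=param,
        )
        rng_seed += 1
        for pid, xv, yv in zip(records["plant_id"], pair.x, pair.y):
            rows.append({"plant_id": pid, "parameter": param, "A": xv, "B": yv})
    wide = pd.DataFrame(rows)
    metrics = []
    for device in ("A", "B"):
        sub = wide.pivot(index="plant_id", columns="parameter", values=device).reset_index()
        sub.insert(1, "device", device)
        metrics.append(sub)
    metrics_df = pd.concat(metrics, ignore_index=True)
    for param in PARAMETERS:
        metrics_df[param] = metrics_df[param].clip(lower=0.0)
    metrics_df.to_csv(out / "device_metrics.csv", index=False)

    records.drop(columns=["intensity", "dark_green_proportion"]).to_csv(
        out / "metadata.csv", index=False
    )
    records.to_csv(out / "records_truth.csv", index=False)
    return {
        "images": out / "images",
        "masks": out / "masks",
        "truth_manifest": out / "truth_manifest.csv",
        "device_metrics": out / "device_metrics.csv",
        "metadata": out / "metadata.csv",
        "records_truth": out / "records_truth.csv",
    }
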
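"""End-to-end batch processing of scene images.

``run_batch`` reads every image matched by the config, segments spikes,
and writes one spike-descriptor table (lengths, geometry, harmonic count,
color battery), one spikelet table, optional annotated images and a
structured run log. Outputs are byte-stable for a fixed config and seed:
files are processed in sorted order, floats are written with six
significant digits, and wall-clock timings go to the log only.
"""
from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import color as colormod
from . import length as lengthmod
from . import shape as shapemod
from .errors import ValidationError
from .segment import SegmentationParams, extract_spike, segment_image, count_rmse
from .spikelets import SpikeletParams, min_distance_sweep, spikelet_segm

FLOAT_FORMAT = "%.6g"


@dataclass
class RunConfig:
    """Configuration of one batch run (JSON-serializable)."""

    input: str = "."                     # directory or glob of images
    output_dir: str = "spykit_out"
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    spikelets: SpikeletParams = field(default_factory=SpikeletParams)
    length_methods: tuple[str, ...] = lengthmod.METHODS
    blur_sigma: float = lengthmod.DEFAULT_BLUR_SIGMA
    prune_px: float = lengthmod.DEFAULT_PRUNE_PX
    efd_threshold: float = shapemod.DEFAULT_POWER_THRESHOLD
    efd_max_harmonics: int = 100
    color_extended: bool = False
    seed: int = 0
    save_overlays: bool = False

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        seg = SegmentationParams(**raw.pop("segmentation", {}))
        spk = SpikeletParams(**raw.pop("spikelets", {}))
        methods = raw.pop("length_methods", None)
        cfg = cls(segmentation=seg, spikelets=spk, **raw)
        if methods:
            cfg = dataclasses.replace(cfg, length_methods=tuple(methods))
        return cfg

    def to_json_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["length_methods"] = list(self.length_methods)
        return d


def _list_images(spec: str) -> list[Path]:
    p = Path(spec)
    exts = {".png", ".tif", ".tiff", ".jpg", ".jpeg"}
    if p.is_dir():
        files = sorted(q for q in p.iterdir() if q.suffix.lower() in exts)
    else:
        files = sorted(Path().glob(spec)) if any(ch in spec for ch in "*?[") \
            else ([p] if p.exists() else [])
    return files


def process_image(image: np.ndarray, config: RunConfig, image_name: str):
    """Run the full per-image pipeline; returns (spike_rows, spikelet_rows,
    overlays) where overlays maps filename stems to annotated rasters."""
    mask, scene, work = segment_image(image, config.segmentation)
    spike_rows, spikelet_rows, overlays = [], [], {}
    for label in range(1, scene.k + 1):
        record = extract_spike(work, scene, label)
        row = {"image": image_name, "spike_id": label}
        r0, c0, r1, c1 = record.bbox
        row.update(bbox_r0=r0, bbox_c0=c0, bbox_r1=r1, bbox_c1=c1,
                   area_px=record.area)
        for res in lengthmod.spk_length(record.mask, config.length_methods,
                                        blur_sigma=config.blur_sigma,
                                        prune_px=config.prune_px,
                                        overlay=config.save_overlays):
            row[f"length_{res.method}_px"] = res.length
            if res.overlay is not None:
                overlays[f"{image_name}_spike{label}_{res.method}"] = res.overlay
        geom = shapemod.region_geometry(record.mask)
        row.update({f"geom_{k}": v for k, v in geom.as_dict().items()})
        contour = shapemod.extract_contour(record.mask)
        row["n_harmonics_9999"] = shapemod.harmonics_for_power(
            contour, config.efd_threshold, config.efd_max_harmonics)
        row.update(colormod.channel_percentiles(record, config.color_extended))
        spike_rows.append(row)

        result = spikelet_segm(record.mask, config.spikelets,
                               annotate=config.save_overlays)
        row["n_spikelets"] = result.count
        if result.annotated is not None:
            overlays[f"{image_name}_spike{label}_spikelets"] = result.annotated
        for rec in result.records:
            spikelet_rows.append({
                "image": image_name, "spike_id": label,
                "spikelet_id": rec.spikelet_id, "area_px": rec.area,
                "major_axis_px": rec.major_axis_length,
                "minor_axis_px": 2.0 * rec.semi_minor,
                "angle_deg": rec.angle,
                "centroid_r": rec.centroid[0], "centroid_c": rec.centroid[1],
            })
    return spike_rows, spikelet_rows, overlays


def run_batch(config: RunConfig) -> dict:
    """Process every input image and write the output tables.

    Unreadable images are logged and skipped; an empty input set is an
    error. Returns a dict with the output paths and the run log.
    """
    import imageio.v3 as iio

    files = _list_images(config.input)
    if not files:
        raise ValidationError(f"no input images under {config.input!r}")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    spike_rows, spikelet_rows = [], []
    log: dict = {"config": config.to_json_dict(), "images": [], "skipped": []}
    for path in files:
        t0 = time.perf_counter()
        try:
            image = iio.imread(path)
            if image.ndim == 3 and image.shape[2] == 4:
                image = image[..., :3]
            srows, krows, overlays = process_image(image, config, path.name)
        except Exception as exc:  # per-image failures are not fatal
            log["skipped"].append({"file": path.name, "error": str(exc)})
            continue
        spike_rows.extend(srows)
        spikelet_rows.extend(krows)
        if overlays:
            for stem, raster in overlays.items():
                iio.imwrite(out / f"{stem}.png", raster)
        log["images"].append({"file": path.name, "n_spikes": len(srows),
                              "elapsed_s": round(time.perf_counter() - t0, 3)})

    spikes_csv = out / "spikes.csv"
    spikelets_csv = out / "spikelets.csv"
    pd.DataFrame(spike_rows).to_csv(spikes_csv, index=False,
                                    float_format=FLOAT_FORMAT)
    cols = ["image", "spike_id", "spikelet_id", "area_px", "major_axis_px",
            "minor_axis_px", "angle_deg", "centroid_r", "centroid_c"]
    pd.DataFrame(spikelet_rows, columns=cols).to_csv(
        spikelets_csv, index=False, float_format=FLOAT_FORMAT)
    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    return {"spikes_csv": spikes_csv, "spikelets_csv": spikelets_csv,
            "log": log}


def sweep_segmentation(images, true_counts, thresholds=(), factors=(),
                       base_params: SegmentationParams = SegmentationParams()):
    """Count RMSE of both segmentation methods over parameter grids.

    Returns a tidy table (method, value, rmse, sd); ``thresholds`` sweeps
    the channel threshold, ``factors`` the Otsu scaling factor.
    """
    thresholds, factors = list(thresholds), list(factors)
    if not thresholds and not factors:
        raise ValidationError("empty sweep grids")
    if len(images) == 0 or len(images) != len(true_counts):
        raise ValidationError("need images with matching true counts")
    rows = []
    for method, values, key in (("channel_thresh", thresholds, "threshold"),
                                ("otsu_scaled", factors, "otsu_factor")):
        for v in values:
            params = dataclasses.replace(base_params, method=method,
                                         **{key: float(v)})
            counts = [segment_image(img, params)[1].k for img in images]
            rmse, sd = count_rmse(counts, true_counts)
            rows.append({"method": method, "value": float(v),
                         "rmse": rmse, "sd": sd})
    return pd.DataFrame(rows)


def sweep_spikelets(masks, true_counts, distances,
                    params: SpikeletParams = SpikeletParams(),
                    out_csv: str | Path | None = None) -> pd.DataFrame:
    """File-emitting wrapper around the spikelet min-distance sweep."""
    table = min_distance_sweep(masks, true_counts, distances, params)
    if out_csv is not None:
        table.to_csv(out_csv, index=False, float_format=FLOAT_FORMAT)
    return table
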
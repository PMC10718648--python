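"""End-to-end preprocessing and evaluation orchestration.

``run_preprocess`` walks an input directory of raw captures and, for each:
registers every band onto the reference band, composes the configured band
order into a three-channel image, applies an enhancement preset, optionally
resizes the composite to a detector-ready square (640 px by default, the
usual detector input size), and writes the aligned bands, the composite and
a JSON transform sidecar under the output directory.  Failures are isolated
per capture: a corrupt capture yields a failure record, not an aborted run.

``run_evaluate`` scores externally produced detection files against ground
truth: YOLO-dialect text files per image in two directories, matched by
file stem.  Predictions pass through confidence filtering and NMS before
the metric suite runs.

Detector inference itself is a file-drop interface — any detector that can
emit YOLO-format boxes with confidences plugs in; this package never runs a
neural network.  ``split_dataset`` is a seeded helper for users who train
their own detector.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml
from skimage.transform import resize

from . import __version__
from .composition import BandOrder, compose
from .detection_eval import EvalReport, confidence_filter, evaluate_detections, nms
from .enhancement import apply_preset
from .io_formats import BoxSet, assemble_capture, read_boxes, write_rgb
from .registration import MetricSettings, OptimizerSettings, register_capture

__all__ = ["PipelineConfig", "RunManifest", "run_preprocess", "run_evaluate",
           "split_dataset", "discover_captures"]

logger = logging.getLogger("lodgekit")


@dataclass
class PipelineConfig:
    """Configuration of the preprocessing / evaluation pipeline."""

    input_dir: str = "."
    output_dir: str = "out"
    reference_band: int = 2
    preset: str = "stretch"
    band_order: BandOrder = (3, 2, 1)
    resize_to: Optional[int] = 640
    bins: int = 64
    pyramid_levels: int = 3
    seed: int = 0
    # evaluation settings
    gt_dir: Optional[str] = None
    pred_dir: Optional[str] = None
    eval_iou: float = 0.5
    eval_conf: float = 0.001
    nms_iou: float = 0.45
    eval_image_size: int = 640
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "band_order" in data:
            data["band_order"] = tuple(data["band_order"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["band_order"] = list(self.band_order)
        return d


@dataclass
class RunManifest:
    """Per-capture records of one preprocessing run (valid JSON)."""

    records: list[dict] = field(default_factory=list)
    version: str = __version__
    config: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"version": self.version, "config": self.config,
             "records": self.records}, indent=2)

    def write(self, path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def discover_captures(input_dir) -> list[str]:
    """Capture ids present in a directory, from the ``<id>_<band>.tif`` naming."""
    input_dir = Path(input_dir)
    ids = set()
    for p in input_dir.iterdir():
        name = p.name
        for ext in (".tif", ".tiff"):
            if name.lower().endswith(ext):
                stem = name[: -len(ext)]
                if len(stem) > 2 and stem[-2] == "_" and stem[-1] in "123456":
                    ids.add(stem[:-2])
    return sorted(ids)


def run_preprocess(config: PipelineConfig) -> RunManifest:
    """Register, enhance and compose every capture under ``input_dir``.

    Returns a manifest with one record per capture: the fitted transforms,
    final metric values and iteration counts, output files, and convergence
    flags.  The manifest is also written to ``<output_dir>/manifest.json``.
    """
    logging.basicConfig(level=config.log_level)
    in_dir = Path(config.input_dir)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    capture_ids = discover_captures(in_dir)
    if not capture_ids:
        raise FileNotFoundError(f"no captures found in {in_dir}")
    manifest = RunManifest(config=config.to_dict())
    metric = MetricSettings(bins=config.bins)
    optimizer = OptimizerSettings(seed=config.seed,
                                  pyramid_levels=config.pyramid_levels)
    for cid in capture_ids:
        try:
            record = _preprocess_one(cid, in_dir, out_dir, config, metric,
                                     optimizer)
        except Exception as exc:  # error isolation: log, record, continue
            logger.error("capture %s failed: %s", cid, exc)
            record = {"capture_id": cid, "status": "failed", "error": str(exc)}
        manifest.records.append(record)
    manifest.write(out_dir / "manifest.json")
    return manifest


def _preprocess_one(cid: str, in_dir: Path, out_dir: Path,
                    config: PipelineConfig, metric: MetricSettings,
                    optimizer: OptimizerSettings) -> dict:
    import tifffile

    capture = assemble_capture(in_dir, cid)
    aligned = register_capture(capture, config.reference_band, metric, optimizer)
    cap_dir = out_dir / cid
    cap_dir.mkdir(exist_ok=True)
    transforms = {}
    for k, band in sorted(aligned.bands.items()):
        codes = np.floor(np.clip(band.pixels, 0, 1) * 65535.0 + 0.5).astype(np.uint16)
        tifffile.imwrite(str(cap_dir / f"{cid}_aligned_{k}.tif"), codes)
        transforms[str(k)] = aligned.transforms[k].as_dict()
    (cap_dir / "transforms.json").write_text(json.dumps(transforms, indent=2))

    rgb = compose(aligned, config.band_order)
    enhanced = apply_preset(rgb, config.preset)
    if config.resize_to:
        n = config.resize_to
        enhanced = resize(enhanced, (n, n, 3), order=1, anti_aliasing=True,
                          preserve_range=True)
    rgb_path = cap_dir / f"{cid}_rgb.png"
    write_rgb(enhanced, rgb_path)

    registration = {
        str(k): {"metric_value": r.metric_value, "iterations": r.iterations,
                 "converged": r.converged}
        for k, r in aligned.registration.items()
    }
    for k, r in aligned.registration.items():
        logger.info("capture %s band %d: metric %.4f after %d iterations",
                    cid, k, r.metric_value, r.iterations)
    return {"capture_id": cid, "status": "ok", "transforms": transforms,
            "registration": registration,
            "outputs": [str(rgb_path)] +
                       [str(cap_dir / f"{cid}_aligned_{k}.tif")
                        for k in sorted(aligned.bands)]}


def _read_box_dir(directory, size: int, with_confidence: bool) -> dict[str, BoxSet]:
    out = {}
    for p in sorted(Path(directory).glob("*.txt")):
        out[p.stem] = read_boxes(p, size, size, with_confidence=with_confidence)
    return out


def run_evaluate(config: PipelineConfig) -> EvalReport:
    """Score a directory of detection files against ground truth.

    Predictions are confidence-filtered at ``eval_conf`` and deduplicated
    with NMS at ``nms_iou`` before the metric suite runs.  The report is
    written to ``<output_dir>/report.json``.
    """
    logging.basicConfig(level=config.log_level)
    if not config.gt_dir or not config.pred_dir:
        raise ValueError("run_evaluate requires gt_dir and pred_dir")
    size = config.eval_image_size
    gts = _read_box_dir(config.gt_dir, size, with_confidence=False)
    preds = _read_box_dir(config.pred_dir, size, with_confidence=True)
    for img in sorted(set(preds) - set(gts)):
        logger.warning("predictions for %s have no ground-truth file; "
                       "all its detections count as false positives", img)
        gts[img] = BoxSet(img, size, size, [])
    preds = {img: nms(confidence_filter(p, config.eval_conf), config.nms_iou)
             for img, p in preds.items()}
    report = evaluate_detections(preds, gts, config.eval_iou)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "report.json").write_text(
        json.dumps(report.to_dict(), indent=2) + "\n")
    return report


def split_dataset(items: Sequence, fractions: tuple[float, float, float] = (0.7, 0.1, 0.2),
                  seed: int = 0) -> tuple[list, list, list]:
    """Seeded shuffle-and-partition into train/validation/test lists."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    rng = np.random.default_rng(seed)
    items = list(items)
    order = rng.permutation(len(items))
    n_train = round(fractions[0] * len(items))
    n_val = round(fractions[1] * len(items))
    train = [items[i] for i in order[:n_train]]
    val = [items[i] for i in order[n_train:n_train + n_val]]
    test = [items[i] for i in order[n_train + n_val:]]
    return train, val, test
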
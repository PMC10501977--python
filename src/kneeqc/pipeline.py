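"""End-to-end QC orchestration: preprocess, detect, measure, report.

The per-image flow mirrors clinical use: read the radiograph (DICOM or
PNG), enhance it with contrast-limited adaptive histogram equalization,
regress the nine landmark heatmaps, decode peaks, call the projection view
from the detected-landmark count, and convert the landmarks into the QC
criteria.  Keypoint files bypass detection, so annotated datasets can be
measured without a model.

Every image yields a :class:`QCRecord` carrying the measurements plus flags
(``clamped_ratio``, ``low_confidence``, ``degenerate_geometry``, ``error``);
per-image failures are recorded, never fatal to the batch.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.exposure import equalize_adapthist

from . import io as kio
from .detector import TrainedModel, predict, prepare_input
from .geometry import (
    GeometryError,
    Keypoint,
    KeypointSet,
    Point2D,
    QCResult,
    compute_qc,
)
from .heatmaps import DEFAULT_TAU, decode_heatmaps

__all__ = ["QCRecord", "preprocess", "run_qc", "records_to_frame"]

CLAHE_CLIP_LIMIT = 0.01
CLAHE_TILES = 8  # tiles per image side


@dataclass
class QCRecord:
    """Result of QC on a single image."""

    image_id: str
    view_call: str | None = None
    keypoints: KeypointSet | None = None
    scores: dict[str, float] | None = None
    qc: QCResult | None = None
    flags: list[str] = field(default_factory=list)
    error: str | None = None

    def to_row(self) -> dict:
        return {
            "image_id": self.image_id,
            "view": self.view_call,
            "overlap_ratio": self.qc.overlap_ratio if self.qc else np.nan,
            "flexion_angle_deg": (
                self.qc.flexion_angle_deg if self.qc and self.qc.flexion_angle_deg is not None else np.nan
            ),
            "normalized_flexion": (
                self.qc.normalized_flexion if self.qc and self.qc.normalized_flexion is not None else np.nan
            ),
            "flags": ";".join(self.flags),
            "error": self.error or "",
        }


def _load_dicom(path: Path) -> np.ndarray:
    import pydicom

    ds = pydicom.dcmread(path)
    if int(getattr(ds, "NumberOfFrames", 1)) > 1:
        raise ValueError(f"{path}: multi-frame DICOM not supported")
    if int(getattr(ds, "SamplesPerPixel", 1)) != 1:
        raise ValueError(f"{path}: color DICOM not supported")
    arr = ds.pixel_array.astype(np.float64)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    arr = arr * slope + intercept
    if str(getattr(ds, "PhotometricInterpretation", "")) == "MONOCHROME1":
        arr = arr.max() - arr  # invert so bone is bright
    return arr


def preprocess(
    image: str | Path | np.ndarray,
    clip_limit: float = CLAHE_CLIP_LIMIT,
    tiles: int = CLAHE_TILES,
) -> np.ndarray:
    """Grayscale array in [0, 1] after CLAHE contrast enhancement.

    Accepts a DICOM path, a PNG path or an array.  DICOM rescale
    slope/intercept is applied and MONOCHROME1 images are inverted before
    equalization; a zero-contrast (constant) image passes through unchanged.
    """
    if isinstance(image, (str, Path)):
        path = Path(image)
        if not path.exists():
            raise FileNotFoundError(path)
        suffix = path.suffix.lower()
        if suffix in {".dcm", ".dicom", ""}:
            arr = _load_dicom(path)
        elif suffix == ".png":
            arr = kio.read_image_png(path)
        else:
            raise ValueError(f"unsupported image format: {path}")
    else:
        arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected a single-frame grayscale image, got shape {arr.shape}")
    lo, hi = float(arr.min()), float(arr.max())
    if hi - lo < 1e-12:
        return np.clip(arr, 0.0, 1.0)
    arr = (arr - lo) / (hi - lo)
    kernel = max(1, min(arr.shape) // tiles)
    return np.clip(equalize_adapthist(arr, kernel_size=kernel, clip_limit=clip_limit), 0.0, 1.0)


def _detect(
    image: np.ndarray, model: TrainedModel, tau: float, refine: bool
) -> tuple[KeypointSet, dict[str, float], str]:
    net_img, scale = prepare_input(image, model.config)
    stack = predict(model, net_img)
    decoded = decode_heatmaps(stack, tau=tau, refine=refine)
    kps = decoded.keypoints
    if scale != 1.0:  # map detections back to original pixels
        kps = KeypointSet(
            view=kps.view,
            keypoints={
                lab: Keypoint(
                    lab,
                    Point2D(kp.position.x / scale, kp.position.y / scale),
                    kp.visible,
                )
                for lab, kp in kps.keypoints.items()
            },
        )
    return kps, decoded.scores, decoded.view_call.value


def _measure(record: QCRecord, kps: KeypointSet) -> None:
    try:
        qc = compute_qc(kps)
    except GeometryError as exc:
        record.flags.append("degenerate_geometry")
        record.error = str(exc)
        return
    record.qc = qc
    if qc.ratio_clamped:
        record.flags.append("clamped_ratio")


def run_qc(
    inputs: Sequence[str | Path],
    model: TrainedModel | None = None,
    out: str | Path | None = None,
    tau: float = DEFAULT_TAU,
    refine: bool = False,
    seed: int | None = None,
) -> list[QCRecord]:
    """QC a batch of images and/or keypoint files; optionally write reports.

    Image inputs require a model; ``.json``/``.csv`` keypoint files bypass
    detection.  When ``out`` is given, ``<out>.csv`` and ``<out>.json`` are
    written (the JSON carries provenance: model checksum and settings).
    """
    records: list[QCRecord] = []
    for item in inputs:
        path = Path(item)
        if path.suffix.lower() in {".json", ".csv"}:
            reader = kio.read_keypoints_json if path.suffix.lower() == ".json" else kio.read_keypoints_csv
            for iid, kps in reader(path).items():
                rec = QCRecord(image_id=iid, view_call=kps.view.value, keypoints=kps)
                _measure(rec, kps)
                records.append(rec)
            continue
        rec = QCRecord(image_id=path.stem)
        try:
            if model is None:
                raise ValueError("image inputs require a trained model")
            img = preprocess(path)
            kps, scores, view = _detect(img, model, tau, refine)
            rec.keypoints, rec.scores, rec.view_call = kps, scores, view
            needed = (
                ("A", "B", "C", "D", "E")
                if view == "AP"
                else ("A", "B", "C", "D", "E", "F", "G", "H", "I")
            )
            if any(not kps.keypoints[lab].visible for lab in needed if lab in kps.keypoints):
                rec.flags.append("low_confidence")
            _measure(rec, kps)
        except Exception as exc:  # per-image failure stays in the report
            rec.error = str(exc)
            if "error" not in rec.flags:
                rec.flags.append("error")
        records.append(rec)

    if out is not None:
        out = Path(out)
        out.parent.mkdir(parents=True, exist_ok=True)
        records_to_frame(records).to_csv(out.with_suffix(".csv"), index=False)
        payload = {
            "provenance": _provenance(model, tau=tau, refine=refine, seed=seed),
            "records": [rec.to_row() for rec in records],
        }
        out.with_suffix(".json").write_text(json.dumps(payload, indent=1))
    return records


def records_to_frame(records: Sequence[QCRecord]) -> pd.DataFrame:
    return pd.DataFrame([rec.to_row() for rec in records])


def _provenance(model: TrainedModel | None, **settings) -> dict:
    prov: dict = {"settings": settings}
    if model is not None:
        h = hashlib.sha256()
        for name in sorted(model.params):
            h.update(name.encode())
            h.update(model.params[name].data.tobytes())
        prov["model_checksum"] = h.hexdigest()[:16]
        prov["network"] = model.config.scale_preset
    return prov
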
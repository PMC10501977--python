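"""Readers and writers for keypoint files, QC reports and phantom images.

Keypoint files come in two dialects:

* JSON — a list of objects, one per image:
  ``{"image_id": ..., "view": "AP"|"LAT",
  "keypoints": [{"label","x","y","visible"}, ...]}``
* CSV — long format with columns ``image_id,label,x,y,visible`` and an
  optional ``view`` column; when ``view`` is absent it is inferred from the
  visible-label set (all nine visible → LAT, otherwise AP).

All coordinates are 0-based pixel centers, ``x`` = column, ``y`` = row.
Phantom images are written as 16-bit grayscale PNG with [0, 1] mapped onto
the full integer range.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .geometry import LABELS, LAT_ONLY_LABELS, Keypoint, KeypointSet, Point2D, View

__all__ = [
    "keypoints_to_record",
    "record_to_keypoints",
    "write_keypoints_json",
    "read_keypoints_json",
    "write_keypoints_csv",
    "read_keypoints_csv",
    "write_image_png",
    "read_image_png",
]


def keypoints_to_record(image_id: str, kps: KeypointSet) -> dict:
    """JSON-ready record for one image's keypoints."""
    return {
        "image_id": image_id,
        "view": kps.view.value,
        "keypoints": [
            {
                "label": kp.label,
                "x": kp.position.x,
                "y": kp.position.y,
                "visible": bool(kp.visible),
            }
            for kp in (kps.keypoints[lab] for lab in LABELS if lab in kps.keypoints)
        ],
    }


def _infer_view(visible: set[str]) -> View:
    return View.LAT if set(LAT_ONLY_LABELS) <= visible else View.AP


def record_to_keypoints(record: Mapping) -> tuple[str, KeypointSet]:
    view = record.get("view")
    kps = {
        d["label"]: Keypoint(
            d["label"],
            Point2D(float(d["x"]), float(d["y"])),
            visible=bool(d.get("visible", True)),
        )
        for d in record["keypoints"]
    }
    if view is None:
        view = _infer_view({lab for lab, kp in kps.items() if kp.visible}).value
    return str(record["image_id"]), KeypointSet(view=View(view), keypoints=kps)


def write_keypoints_json(path: str | Path, records: Mapping[str, KeypointSet]) -> None:
    payload = [keypoints_to_record(iid, kps) for iid, kps in records.items()]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_keypoints_json(path: str | Path) -> dict[str, KeypointSet]:
    payload = json.loads(Path(path).read_text())
    if isinstance(payload, Mapping):  # single-image file
        payload = [payload]
    return dict(record_to_keypoints(rec) for rec in payload)


def write_keypoints_csv(path: str | Path, records: Mapping[str, KeypointSet]) -> None:
    rows = []
    for iid, kps in records.items():
        for lab in LABELS:
            if lab not in kps.keypoints:
                continue
            kp = kps.keypoints[lab]
            rows.append(
                {
                    "image_id": iid,
                    "view": kps.view.value,
                    "label": lab,
                    "x": kp.position.x,
                    "y": kp.position.y,
                    "visible": int(kp.visible),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_keypoints_csv(path: str | Path) -> dict[str, KeypointSet]:
    df = pd.read_csv(path, dtype={"image_id": str})
    out: dict[str, KeypointSet] = {}
    for iid, grp in df.groupby("image_id", sort=False):
        kps = {
            str(r.label): Keypoint(
                str(r.label),
                Point2D(float(r.x), float(r.y)),
                visible=bool(int(r.visible)),
            )
            for r in grp.itertuples()
        }
        if "view" in grp.columns:
            view = View(str(grp["view"].iloc[0]))
        else:
            view = _infer_view({lab for lab, kp in kps.items() if kp.visible})
        out[str(iid)] = KeypointSet(view=view, keypoints=kps)
    return out


def write_image_png(path: str | Path, image: np.ndarray) -> None:
    """Write a float image in [0, 1] as 16-bit grayscale PNG."""
    arr = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
    iio.imwrite(Path(path), np.round(arr * 65535.0).astype(np.uint16))


def read_image_png(path: str | Path) -> np.ndarray:
    """Read an 8/16-bit grayscale PNG back to float64 in [0, 1]."""
    raw = iio.imread(Path(path))
    if raw.ndim == 3:
        raise ValueError(f"{path}: expected a grayscale image, got shape {raw.shape}")
    info = np.iinfo(raw.dtype) if raw.dtype.kind in "ui" else None
    arr = raw.astype(np.float64)
    return arr / info.max if info else arr
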
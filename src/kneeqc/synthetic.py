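"""Synthetic knee-phantom generator with exact ground-truth landmarks.

The phantoms are stylized, not anatomically realistic: bones are bright
capsules and rectangles on a dark background, the fibular head is an
ellipse, and a tibial edge crosses it at a controllable overlap ratio.  The
point of the generator is that every rendered case carries *exact* landmark
coordinates and the true generative QC values, so the geometry, codec,
detector and evaluation layers can be exercised end-to-end without patient
radiographs.

Layout (fractions of the short image side ``S``):

* AP — a near-vertical fibula (shaft axis through landmarks ``A``/``B``,
  elliptical head with transverse extremes ``C``/``D``) partially covered by
  a tibia whose edge runs parallel to the fibular shaft and crosses the head
  transverse line at ``E``.  By construction the signed-distance overlap
  ratio of the landmarks equals ``true_overlap_ratio`` exactly.
* LAT — femoral and tibial shafts (landmarks ``F``/``G`` and ``H``/``I``)
  meeting at the knee with the requested flexion angle, plus a fibula
  parallel to the tibia whose head is covered by the tibia's posterior edge
  at the requested ratio.

Corruptions (Gaussian noise, Gaussian blur, an occlusion band) are applied
after landmark placement and never move the ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .geometry import KeypointSet, QCResult, View, compute_qc
from . import io as kio

__all__ = [
    "OcclusionBand",
    "PhantomSpec",
    "SyntheticCase",
    "DatasetRanges",
    "InfeasibleLayoutError",
    "generate_case",
    "generate_dataset",
    "save_dataset",
]

MARGIN = 8  # minimum landmark distance (px) from every image border


class InfeasibleLayoutError(ValueError):
    """The requested bones do not fit the canvas with the required margin."""


@dataclass(frozen=True)
class OcclusionBand:
    """A horizontal band overlaying the image (e.g., a cast or marker).

    ``position`` is the band-center row as a fraction of image height,
    ``width`` its height in pixels, ``opacity`` the blend factor in [0, 1].
    """

    position: float = 0.5
    width: float = 10.0
    opacity: float = 0.6


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters of one phantom radiograph.

    ``fibula_head_radius`` and ``shaft_width`` default to fractions of the
    short image side (9% and 6%) when left as ``None``.
    ``true_flexion_deg`` is only meaningful for LAT phantoms.
    """

    view: View = View.AP
    image_size: tuple[int, int] = (64, 64)
    true_overlap_ratio: float = 0.5
    true_flexion_deg: float = 170.0
    fibula_head_radius: float | None = None
    shaft_width: float | None = None
    noise_sd: float = 0.01
    occlusion: OcclusionBand | None = None
    blur_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_overlap_ratio <= 1.0:
            raise ValueError(f"true_overlap_ratio {self.true_overlap_ratio} outside [0, 1]")
        if not 0.0 < self.true_flexion_deg <= 180.0:
            raise ValueError(f"true_flexion_deg {self.true_flexion_deg} outside (0, 180]")
        if min(self.image_size) < 6 * MARGIN:
            raise ValueError(f"image_size {self.image_size} too small for a phantom")

    @property
    def short_side(self) -> int:
        return min(self.image_size)

    @property
    def head_radius(self) -> float:
        return self.fibula_head_radius if self.fibula_head_radius is not None else 0.09 * self.short_side

    @property
    def bone_width(self) -> float:
        return self.shaft_width if self.shaft_width is not None else 0.06 * self.short_side


@dataclass
class SyntheticCase:
    """A rendered phantom, its exact landmarks and its true QC values."""

    image: np.ndarray
    keypoints: KeypointSet
    truth: QCResult
    spec: PhantomSpec


# ---------------------------------------------------------------------------
# rendering primitives (soft-edged densities on a pixel grid)

_EDGE = 0.8  # soft-edge width in pixels


def _grid(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    ys, xs = np.mgrid[0 : shape[0], 0 : shape[1]].astype(np.float64)
    return xs, ys


def _soft(d: np.ndarray) -> np.ndarray:
    """Map a signed distance (negative inside) to a [0, 1] coverage value."""
    return np.clip(0.5 - d / _EDGE, 0.0, 1.0)


def _capsule(xs, ys, p0, p1, halfwidth) -> np.ndarray:
    vx, vy = p1[0] - p0[0], p1[1] - p0[1]
    seg2 = vx * vx + vy * vy
    t = ((xs - p0[0]) * vx + (ys - p0[1]) * vy) / max(seg2, 1e-12)
    t = np.clip(t, 0.0, 1.0)
    dx, dy = xs - (p0[0] + t * vx), ys - (p0[1] + t * vy)
    return _soft(np.hypot(dx, dy) - halfwidth)


def _ellipse(xs, ys, center, u, a, b) -> np.ndarray:
    # u: unit vector of the semi-axis a; b along the perpendicular
    rx, ry = xs - center[0], ys - center[1]
    lon = rx * u[0] + ry * u[1]
    tra = -rx * u[1] + ry * u[0]
    q = np.sqrt((lon / a) ** 2 + (tra / b) ** 2)
    # approximate signed distance for the soft edge
    return _soft((q - 1.0) * min(a, b))


def _slab(xs, ys, anchor, u, t, lo, hi, half_len) -> np.ndarray:
    """Rotated rectangle: transverse coordinate in [lo, hi], |longitudinal| <= half_len."""
    rx, ry = xs - anchor[0], ys - anchor[1]
    lon = rx * u[0] + ry * u[1]
    tra = rx * t[0] + ry * t[1]
    d = np.maximum.reduce([lo - tra, tra - hi, np.abs(lon) - half_len])
    return _soft(d)


def _rot(v: tuple[float, float], deg: float) -> tuple[float, float]:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return (c * v[0] - s * v[1], s * v[0] + c * v[1])


def _perp(v: tuple[float, float]) -> tuple[float, float]:
    return (-v[1], v[0])


def _add(p, v, s=1.0) -> tuple[float, float]:
    return (p[0] + s * v[0], p[1] + s * v[1])


# ---------------------------------------------------------------------------
# layouts


def _center_points(
    points: dict[str, tuple[float, float]], shape: tuple[int, int]
) -> tuple[float, float]:
    """Translation that centers the landmark bounding box on the canvas.

    A rigid translation changes neither the overlap ratio nor the flexion
    angle, so layouts are built in a local frame and shifted here.
    """
    rows, cols = shape
    xs = [p[0] for p in points.values()]
    ys = [p[1] for p in points.values()]
    dx = (cols - 1) / 2 - (min(xs) + max(xs)) / 2
    dy = (rows - 1) / 2 - (min(ys) + max(ys)) / 2
    return dx, dy


def _layout_ap(spec: PhantomSpec, rng: np.random.Generator):
    S = spec.short_side
    b = spec.head_radius
    tilt = float(rng.uniform(-8.0, 8.0))
    u = _rot((0.0, 1.0), tilt)  # fibular shaft axis, pointing distal (down)
    t = _perp(u)  # transverse; choose sign pointing toward the tibia (image left)
    if t[0] > 0:
        t = (-t[0], -t[1])
    head = (0.0, 0.0)  # local frame; centered on the canvas afterwards
    # shaft landmarks; jitter along the axis leaves L1 (and the ratio) unchanged
    e_off = b * (1.0 - 2.0 * spec.true_overlap_ratio)
    pts = {
        "A": _add(head, u, 0.28 * S + float(rng.uniform(-2, 2))),
        "B": _add(head, u, 0.48 * S + float(rng.uniform(-2, 2))),
        "C": _add(head, t, b),
        "D": _add(head, t, -b),
        "E": _add(head, t, e_off),
    }
    dx, dy = _center_points(pts, spec.image_size)
    pts = {lab: (p[0] + dx, p[1] + dy) for lab, p in pts.items()}
    head = (head[0] + dx, head[1] + dy)

    xs, ys = _grid(spec.image_size)
    w = spec.bone_width
    densities = [
        # fibula: shaft capsule + elliptical head
        _capsule(xs, ys, _add(head, u, 0.5 * b), _add(head, u, 0.56 * S), w / 2),
        _ellipse(xs, ys, head, u, 1.25 * b, b),
        # tibia: wide slab whose near edge passes through E, parallel to the shaft
        _slab(xs, ys, head, u, t, e_off, e_off + 0.42 * S, 0.75 * S),
    ]
    return KeypointSet.from_points(View.AP, pts), densities


def _layout_lat(spec: PhantomSpec, rng: np.random.Generator):
    S = spec.short_side
    b = spec.head_radius
    tilt = float(rng.uniform(-6.0, 6.0))
    v = _rot((0.0, 1.0), tilt)  # tibial shaft axis, pointing distal
    joint = (0.0, 0.0)  # local frame
    # femur: distal->proximal direction w at the requested flexion angle to I-H
    bend = 180.0 - spec.true_flexion_deg
    w_dir = _rot((-v[0], -v[1]), bend)
    # fibula parallel to the tibia, posterior; its head sits behind the tibia edge
    p = _perp(v)  # posterior direction: away from the femur's bend side
    if (p[0] * w_dir[0] + p[1] * w_dir[1]) > 0:
        p = (-p[0], -p[1])
    t = (-p[0], -p[1])  # transverse toward the tibia
    wt = 0.13 * S  # tibia half-width
    e_off = b * (1.0 - 2.0 * spec.true_overlap_ratio)
    head = _add(_add(joint, v, 0.15 * S), p, wt + e_off)
    pts = {
        "H": _add(joint, v, 0.08 * S + float(rng.uniform(-1, 1))),
        "I": _add(joint, v, 0.36 * S + float(rng.uniform(-1.5, 1.5))),
        "G": _add(joint, w_dir, 0.10 * S + float(rng.uniform(-1, 1))),
        "F": _add(joint, w_dir, 0.32 * S + float(rng.uniform(-1.5, 1.5))),
        "A": _add(head, v, 0.12 * S + float(rng.uniform(-1, 1))),
        "B": _add(head, v, 0.21 * S + float(rng.uniform(-1, 1))),
        "C": _add(head, t, b),
        "D": _add(head, t, -b),
        "E": _add(head, t, e_off),
    }
    dx, dy = _center_points(pts, spec.image_size)
    pts = {lab: (p0[0] + dx, p0[1] + dy) for lab, p0 in pts.items()}
    head = (head[0] + dx, head[1] + dy)
    joint = (joint[0] + dx, joint[1] + dy)

    xs, ys = _grid(spec.image_size)
    w = spec.bone_width
    densities = [
        _capsule(xs, ys, _add(head, v, 0.5 * b), _add(head, v, 0.28 * S), 0.8 * w / 2),
        _ellipse(xs, ys, head, v, 1.2 * b, b),
        # tibia slab: transverse edge exactly at distance wt on the fibular side
        _slab(xs, ys, joint, v, p, -wt, wt, 0.46 * S),
        _capsule(xs, ys, _add(joint, w_dir, 0.04 * S), _add(joint, w_dir, 0.40 * S), w / 2),
        _ellipse(xs, ys, joint, w_dir, 1.6 * b, 1.3 * b),  # condylar mass
    ]
    return KeypointSet.from_points(View.LAT, pts), densities


def generate_case(spec: PhantomSpec) -> SyntheticCase:
    """Render one phantom; deterministic given ``spec`` (including its seed)."""
    rng = np.random.default_rng(spec.seed)
    if spec.view is View.AP:
        kps, densities = _layout_ap(spec, rng)
    else:
        kps, densities = _layout_lat(spec, rng)

    rows, cols = spec.image_size
    for lab in kps.keypoints:
        pt = kps.keypoints[lab].position
        if not (MARGIN <= pt.x <= cols - 1 - MARGIN and MARGIN <= pt.y <= rows - 1 - MARGIN):
            raise InfeasibleLayoutError(
                f"keypoint {lab} at ({pt.x:.1f}, {pt.y:.1f}) violates the "
                f"{MARGIN}-px margin on a {rows}x{cols} canvas"
            )

    image = np.full(spec.image_size, 0.08, dtype=np.float64)
    for dens in densities:
        image = image + 0.38 * dens
    image = np.clip(image, 0.0, 1.0)
    if spec.blur_sigma > 0:
        image = gaussian_filter(image, spec.blur_sigma)
    if spec.occlusion is not None:
        occ = spec.occlusion
        r0 = int(round(occ.position * rows - occ.width / 2))
        r1 = int(round(occ.position * rows + occ.width / 2))
        band = slice(max(r0, 0), min(r1, rows))
        image[band] = (1 - occ.opacity) * image[band] + occ.opacity * 0.85
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
    image = np.clip(image, 0.0, 1.0)

    return SyntheticCase(image=image, keypoints=kps, truth=compute_qc(kps), spec=spec)


# ---------------------------------------------------------------------------
# datasets


@dataclass(frozen=True)
class DatasetRanges:
    """Uniform sampling ranges for dataset generation."""

    overlap_ratio: tuple[float, float] = (0.0, 1.0)
    flexion_deg: tuple[float, float] = (90.0, 180.0)
    noise_sd: tuple[float, float] = (0.005, 0.02)
    blur_sigma: tuple[float, float] = (0.3, 0.8)
    ap_fraction: float = 0.5
    image_size: tuple[int, int] = (64, 64)
    occlusion_prob: float = 0.0


def _case_seed(dataset_seed: int, index: int) -> int:
    # one stream per case, reproducible under any generation order
    ss = np.random.SeedSequence(entropy=dataset_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] % (2**31))


def generate_dataset(
    n: int, ranges: DatasetRanges | None = None, seed: int = 0
) -> tuple[list[SyntheticCase], pd.DataFrame]:
    """Draw ``n`` phantoms with parameters uniform over ``ranges``.

    Returns the cases plus a manifest with one row per case recording the
    spec and the true QC values.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ranges = ranges or DatasetRanges()
    rng = np.random.default_rng(seed)
    cases: list[SyntheticCase] = []
    rows = []
    for i in range(n):
        view = View.AP if rng.uniform() < ranges.ap_fraction else View.LAT
        spec = PhantomSpec(
            view=view,
            image_size=ranges.image_size,
            true_overlap_ratio=float(rng.uniform(*ranges.overlap_ratio)),
            true_flexion_deg=float(rng.uniform(*ranges.flexion_deg)),
            noise_sd=float(rng.uniform(*ranges.noise_sd)),
            blur_sigma=float(rng.uniform(*ranges.blur_sigma)),
            occlusion=(
                OcclusionBand(position=float(rng.uniform(0.2, 0.8)))
                if rng.uniform() < ranges.occlusion_prob
                else None
            ),
            seed=_case_seed(seed, i),
        )
        case = generate_case(spec)
        cases.append(case)
        rows.append(
            {
                "case_id": f"case_{i:04d}",
                "view": view.value,
                "true_overlap_ratio": spec.true_overlap_ratio,
                "true_flexion_deg": spec.true_flexion_deg if view is View.LAT else np.nan,
                "noise_sd": spec.noise_sd,
                "blur_sigma": spec.blur_sigma,
                "occluded": spec.occlusion is not None,
                "seed": spec.seed,
            }
        )
    return cases, pd.DataFrame(rows)


def save_dataset(
    cases: Sequence[SyntheticCase], manifest: pd.DataFrame, outdir: str | Path
) -> None:
    """Write images (16-bit PNG), the manifest (CSV) and ground truth (JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = {}
    for row, case in zip(manifest.itertuples(), cases):
        kio.write_image_png(outdir / f"{row.case_id}.png", case.image)
        records[row.case_id] = case.keypoints
    manifest.to_csv(outdir / "manifest.csv", index=False)
    kio.write_keypoints_json(outdir / "keypoints.json", records)
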
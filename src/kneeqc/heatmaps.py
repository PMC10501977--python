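"""Gaussian heatmap encoding/decoding and projection-view classification.

Each of the nine landmarks owns one heatmap channel, in the fixed order
``A``–``I``.  Encoding writes an amplitude-1 isotropic Gaussian (the
standard pose-estimation target; default sigma 2 heatmap pixels) at the
landmark's strided position; channels of absent or invisible landmarks are
identically zero — in particular, AP images produce all-zero targets for the
four LAT-only channels ``F``–``I``, which is what lets a single network
handle both projections and lets the view be read off the detected-keypoint
count afterwards.

Decoding takes the per-channel maximum activation: position = argmax x
stride, score = peak value, visible iff score >= the detection threshold
``tau``.  Ties resolve to the lexicographically smallest (row, col).  An
optional sub-pixel refinement (off by default) sharpens the peak position by
a log-space Taylor expansion around the argmax cell, exploiting the fact
that well-trained channels approximate the Gaussian training targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import (
    AP_LABELS,
    LABELS,
    LAT_ONLY_LABELS,
    Keypoint,
    KeypointSet,
    Point2D,
    View,
)

__all__ = [
    "HeatmapStack",
    "DecodedKeypoints",
    "DEFAULT_SIGMA",
    "DEFAULT_TAU",
    "encode_heatmaps",
    "decode_heatmaps",
    "classify_view",
]

DEFAULT_SIGMA = 2.0  # Gaussian target sd, heatmap pixels
DEFAULT_TAU = 0.1  # detection threshold on the peak activation


@dataclass
class HeatmapStack:
    """9 x h x w nonnegative maps plus the stride tying them to input pixels."""

    maps: np.ndarray
    stride: int = 1

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=np.float64)
        if self.maps.ndim != 3 or self.maps.shape[0] != len(LABELS):
            raise ValueError(f"expected ({len(LABELS)}, h, w) maps, got {self.maps.shape}")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.maps.shape[1:]

    def channel(self, label: str) -> np.ndarray:
        return self.maps[LABELS.index(label)]


@dataclass
class DecodedKeypoints:
    """Decoded landmark set, per-label peak scores and the view call."""

    keypoints: KeypointSet
    scores: dict[str, float]
    view_call: View


def encode_heatmaps(
    kps: KeypointSet,
    shape: tuple[int, int],
    stride: int = 1,
    sigma: float = DEFAULT_SIGMA,
) -> HeatmapStack:
    """Gaussian target heatmaps for a keypoint set.

    Visible keypoints must land inside the (h, w) map after division by
    ``stride``; absent/invisible ones yield all-zero channels.
    """
    h, w = shape
    maps = np.zeros((len(LABELS), h, w), dtype=np.float64)
    ys = np.arange(h, dtype=np.float64)[:, None]
    xs = np.arange(w, dtype=np.float64)[None, :]
    for ci, lab in enumerate(LABELS):
        kp = kps.keypoints.get(lab)
        if kp is None or not kp.visible:
            continue
        cx, cy = kp.position.x / stride, kp.position.y / stride
        if not (0 <= cx <= w - 1 and 0 <= cy <= h - 1):
            raise ValueError(
                f"keypoint {lab} strided position ({cx:.2f}, {cy:.2f}) "
                f"outside a {h}x{w} map"
            )
        maps[ci] = np.exp(-((xs - cx) ** 2 + (ys - cy) ** 2) / (2.0 * sigma**2))
    return HeatmapStack(maps=maps, stride=stride)


def _refine_peak(chan: np.ndarray, r: int, c: int) -> tuple[float, float]:
    """Sub-pixel peak offset by a log-space Taylor expansion.

    Treats the channel near its peak as a sampled Gaussian: after a light
    smoothing, the log-heatmap is locally quadratic and the mode offset is
    ``-H^{-1} g`` from the gradient and Hessian at the argmax cell (the
    distribution-aware decoding used in heatmap pose estimation).  Falls
    back to the integer cell at borders or when the local Hessian is not
    negative definite.
    """
    from scipy.ndimage import gaussian_filter

    h, w = chan.shape
    if not (1 <= r < h - 1 and 1 <= c < w - 1):
        return float(r), float(c)
    hm = np.log(np.maximum(gaussian_filter(np.maximum(chan, 1e-10), 0.9), 1e-10))
    gx = 0.5 * (hm[r, c + 1] - hm[r, c - 1])
    gy = 0.5 * (hm[r + 1, c] - hm[r - 1, c])
    dxx = hm[r, c + 1] - 2.0 * hm[r, c] + hm[r, c - 1]
    dyy = hm[r + 1, c] - 2.0 * hm[r, c] + hm[r - 1, c]
    dxy = 0.25 * (hm[r + 1, c + 1] - hm[r + 1, c - 1] - hm[r - 1, c + 1] + hm[r - 1, c - 1])
    det = dxx * dyy - dxy * dxy
    if det <= 0 or dxx >= 0:
        return float(r), float(c)
    ox = -(dyy * gx - dxy * gy) / det
    oy = -(-dxy * gx + dxx * gy) / det
    if abs(ox) > 1.0 or abs(oy) > 1.0:  # expansion left the peak cell: distrust it
        return float(r), float(c)
    return r + oy, c + ox


def decode_heatmaps(
    stack: HeatmapStack, tau: float = DEFAULT_TAU, refine: bool = False
) -> DecodedKeypoints:
    """Maximum-activation decoding of a heatmap stack.

    Per channel the peak position (times stride) becomes the keypoint and the
    peak value its score; the keypoint is visible iff score >= ``tau``.
    ``refine=True`` applies sub-pixel refinement at heatmap resolution.
    """
    kps: dict[str, Keypoint] = {}
    scores: dict[str, float] = {}
    for ci, lab in enumerate(LABELS):
        chan = stack.maps[ci]
        flat = int(np.argmax(chan))  # first occurrence = smallest (row, col)
        r, c = divmod(flat, chan.shape[1])
        score = float(chan[r, c])
        rr, cc = _refine_peak(chan, r, c) if refine else (float(r), float(c))
        kps[lab] = Keypoint(
            lab,
            Point2D(cc * stack.stride, rr * stack.stride),
            visible=score >= tau,
        )
        scores[lab] = score
    view = _view_from_visible({lab for lab, kp in kps.items() if kp.visible})
    kpset = KeypointSet(view=view, keypoints=kps)
    return DecodedKeypoints(keypoints=kpset, scores=scores, view_call=view)


def _view_from_visible(visible: set[str]) -> View:
    n_lat_only = len(visible & set(LAT_ONLY_LABELS))
    return View.LAT if n_lat_only >= 3 else View.AP


def classify_view(decoded: DecodedKeypoints) -> View:
    """View call from the detected-keypoint count.

    LAT iff at least 3 of the 4 LAT-only channels (``F``–``I``) are visible;
    the majority rule tolerates one missed landmark.
    """
    visible = {lab for lab, kp in decoded.keypoints.keypoints.items() if kp.visible}
    return _view_from_visible(visible)
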
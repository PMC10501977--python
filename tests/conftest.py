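"""Shared fixtures: canonical keypoint sets and easy phantom conditions."""

import numpy as np
import pytest

from kneeqc.geometry import KeypointSet, View
from kneeqc.synthetic import DatasetRanges


@pytest.fixture
def ap_keypoints() -> KeypointSet:
    """AP set with axis-aligned shaft: Sc=10, Sd=-6, Se=2 => ratio 0.5."""
    return KeypointSet.from_points(
        View.AP,
        {"A": (0, 0), "B": (0, 100), "C": (10, 50), "D": (-6, 50), "E": (2, 50)},
    )


@pytest.fixture
def lat_keypoints(ap_keypoints) -> KeypointSet:
    """LAT set: same fibular geometry plus collinear femoral/tibial shafts."""
    pts = {lab: (kp.position.x, kp.position.y) for lab, kp in ap_keypoints.keypoints.items()}
    pts.update({"F": (0, 0), "G": (0, 100), "H": (0, 120), "I": (0, 220)})
    return KeypointSet.from_points(View.LAT, pts)


@pytest.fixture(scope="session")
def easy_lat_ranges() -> DatasetRanges:
    """Easy LAT-only phantom conditions: low noise, mild blur, no occlusion."""
    return DatasetRanges(
        ap_fraction=0.0,
        flexion_deg=(140.0, 175.0),
        overlap_ratio=(0.2, 0.8),
        noise_sd=(0.003, 0.008),
        blur_sigma=(0.3, 0.5),
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
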
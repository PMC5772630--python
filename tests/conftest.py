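"""Shared fixtures: planted-bump images and their detection results.

Session-scoped because the 256x256 multi-scale runs are the expensive part
of the suite and several test modules interrogate the same results.
"""
from __future__ import annotations

import numpy as np
import pytest

import hessianblob as hb

#: the four planted scales used by the scale-selection / boundary oracles
PLANTED_SCALES = (4.0, 8.0, 16.0, 32.0)


def four_bump_image() -> tuple[hb.HeightImage, hb.GroundTruth]:
    """One 3 nm bump per planted scale, quadrant layout, 256x256, 1 nm/px."""
    blobs = [
        (64.0, 64.0, 3.0, 4.0),
        (192.0, 64.0, 3.0, 8.0),
        (64.0, 192.0, 3.0, 16.0),
        (192.0, 192.0, 3.0, 32.0),
    ]
    return hb.gaussian_blob_image((256, 256), 1.0, blobs)


@pytest.fixture(scope="session")
def four_bumps():
    return four_bump_image()


@pytest.fixture(scope="session")
def four_bump_result(four_bumps):
    img, gt = four_bumps
    return hb.detect(img, min_strength=0.0)


@pytest.fixture(scope="session")
def single_bump_volume():
    """128x128 image with one bump (t0=8, A=3) plus its detector volume."""
    img, gt = hb.gaussian_blob_image((128, 128), 1.0, [(64.0, 64.0, 3.0, 8.0)])
    ss = hb.build_scale_space(img)
    vol = hb.detector_volumes(ss)
    return img, gt, vol


def blob_for_scale(result: hb.DetectionResult, t0: float) -> hb.HessianBlob:
    """The detected blob whose refined scale is nearest a planted t0."""
    return min(result.blobs, key=lambda b: abs(np.log(b.t_hat_px2 / t0)))


def match_errors(result: hb.DetectionResult, gt: hb.GroundTruth) -> np.ndarray:
    """Distance from each planted center to the nearest detection (px)."""
    got = np.array(
        [[b.center.col, b.center.row] for b in result.blobs]
    ).reshape(-1, 2)
    errs = []
    for x, y in gt.centers:
        if len(got) == 0:
            errs.append(np.inf)
        else:
            errs.append(float(np.hypot(got[:, 0] - x, got[:, 1] - y).min()))
    return np.array(errs)
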
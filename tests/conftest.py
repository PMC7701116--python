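"""Shared fixtures: tiny synthetic projects and volumes, generated fresh."""

import numpy as np
import pytest

from voxpipe import fixtures as fx
from voxpipe.volume import RoiMask, ScanVolume


@pytest.fixture
def small_cohort(tmp_path):
    """2 subjects x 3 timepoints x 10 sequences (60 scans) + 6 session ROIs."""
    spec = fx.CohortSpec(seed=11, roi_per_session=True)
    return fx.make_cohort(spec, tmp_path / "cohort")


@pytest.fixture
def empty_project(tmp_path):
    from voxpipe.project import create_project
    return create_project(tmp_path / "empty")


@pytest.fixture
def ellipsoid_scan():
    vol, truth = fx.make_volume("ellipsoid_brain", shape=(24, 24, 18), seed=3)
    return vol, truth


@pytest.fixture
def constant_scan():
    return ScanVolume(array=np.full((8, 8, 6), 7.0), affine=np.eye(4))


def make_roi(mask, affine=None):
    return RoiMask(array=np.asarray(mask, dtype=np.uint8),
                   affine=np.eye(4) if affine is None else affine)
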
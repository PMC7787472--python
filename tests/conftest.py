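"""Shared fixtures: a canonical noiseless phantom and a full pipeline run.

The phantom is the package's example scene (straight bundle, one
ellipsoidal lesion at f = 0.4, m = 1) with a reduced streamline count so
the suite stays fast; geometry and tissue values are unchanged.
"""

from __future__ import annotations

import numpy as np
import pytest
import yaml

from lesionprof import matching, phantom
from lesionprof.pipeline import RunConfig, run_pipeline

PHANTOM_F = 0.4
PHANTOM_SEED = 7
PHANTOM_N_STREAMLINES = 300


@pytest.fixture(scope="session")
def phantom_data():
    spec = phantom.example_spec(
        seed=PHANTOM_SEED, n_streamlines=PHANTOM_N_STREAMLINES, f=PHANTOM_F
    )
    return phantom.generate_phantom(spec)


@pytest.fixture(scope="session")
def fiber_pairs(phantom_data):
    pairs, discards = matching.build_fiber_pairs(
        phantom_data.tracts[0],
        phantom_data.lesions,
        csf_mask=phantom_data.tissues.csf,
        gm_mask=phantom_data.tissues.gm,
    )
    assert pairs, "phantom produced no fiber pairs"
    return pairs, discards


def make_run_config(phantom_dir, **overrides) -> RunConfig:
    kwargs = dict(
        ad_path=str(phantom_dir / "ad.nii.gz"),
        rd_path=str(phantom_dir / "rd.nii.gz"),
        md_path=str(phantom_dir / "md.nii.gz"),
        t1_path=str(phantom_dir / "t1.nii.gz"),
        lesion_mask_path=str(phantom_dir / "lesion_labels.nii.gz"),
        csf_mask_path=str(phantom_dir / "csf.nii.gz"),
        gm_mask_path=str(phantom_dir / "gm.nii.gz"),
        nawm_roi_path=str(phantom_dir / "nawm_rois.nii.gz"),
        csf_roi_path=str(phantom_dir / "csf_rois.nii.gz"),
        tracts_dir=str(phantom_dir / "tracts"),
        seed=PHANTOM_SEED,
    )
    kwargs.update(overrides)
    return RunConfig(**kwargs)


@pytest.fixture(scope="session")
def phantom_dir(tmp_path_factory, phantom_data):
    out = tmp_path_factory.mktemp("phantom")
    phantom.write_phantom(phantom_data, out)
    return out


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory, phantom_dir):
    out = tmp_path_factory.mktemp("pipeline_out")
    config = make_run_config(phantom_dir)
    run_pipeline(config, out)
    return out


@pytest.fixture(scope="session")
def run_config_yaml(tmp_path_factory, phantom_dir):
    from dataclasses import asdict

    path = tmp_path_factory.mktemp("cfg") / "run.yaml"
    path.write_text(yaml.safe_dump(asdict(make_run_config(phantom_dir))))
    return path


def rigid_transform(angle_deg: float, axis: int, translation) -> np.ndarray:
    """4x4 rigid transform used by symmetry tests."""
    theta = np.deg2rad(angle_deg)
    c, s = np.cos(theta), np.sin(theta)
    rot3 = np.eye(3)
    i, j = [(1, 2), (0, 2), (0, 1)][axis]
    rot3[i, i] = rot3[j, j] = c
    rot3[i, j], rot3[j, i] = -s, s
    out = np.eye(4)
    out[:3, :3] = rot3
    out[:3, 3] = translation
    return out
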
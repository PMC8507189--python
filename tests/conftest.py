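import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import canopyphen as cp

settings.register_profile(
    "ci", derandomize=True, max_examples=60,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def gei_params():
    """GEI-scale seasonal curve shaped like an oak canopy year: dormant ~8,
    peak ~45, green-up inflection day 67, senescence inflection day 337."""
    return cp.DoubleLogisticParams(w_min=8.0, w_max=45.0, s=67.0, a=337.0,
                                   m_s=0.15, m_a=0.10)


@pytest.fixture(scope="session")
def gcc_params():
    """GCC-scale curve within the synthetic color ramp's attainable range."""
    return cp.DoubleLogisticParams(w_min=0.35, w_max=0.50, s=67.0, a=337.0,
                                   m_s=0.15, m_a=0.10)


@pytest.fixture(scope="session")
def tiny_archive(tmp_path_factory, gcc_params):
    """10-day jitter-free archive, 3 frames/day, with its manifest."""
    out = tmp_path_factory.mktemp("archive")
    traj = cp.TrajectorySpec(gcc_params, doy_start=60, doy_end=69,
                             noise_sd=0.0, seed=7)
    scene = cp.SceneSpec(images_per_day=3)
    manifest = cp.generate_image_archive(scene, traj, out)
    return out, traj, scene, manifest


def rois_from_manifest(manifest):
    from canopyphen.roi import ROISpec
    return [ROISpec(d["name"], d["type"], tuple(d["coords"]))
            for d in manifest["rois"]]
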
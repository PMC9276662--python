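import numpy as np
import pytest

import vesselfrac as vf


@pytest.fixture(scope="session")
def tube_volume():
    """A single straight noiseless-free tube volume (axial-plane trunk)."""
    spec = vf.VesselVolumeSpec(n_generations=1, tortuosity=0.0, seed=1)
    vol, centerline = vf.make_vessel_volume(spec)
    return vol, centerline


@pytest.fixture(scope="session")
def tree_mip():
    """MIP of the default bifurcating-tree volume plus its ground-truth
    2D tube footprint (projection of the noiseless vessel voxels)."""
    spec = vf.VesselVolumeSpec(seed=7)
    vol, _ = vf.make_vessel_volume(spec)
    noiseless, _ = vf.make_vessel_volume(
        vf.VesselVolumeSpec(seed=7, background_noise_sd=0.0))
    truth2d = (vf.max_intensity_project(noiseless).intensities > 0).astype(np.uint8)
    return vf.max_intensity_project(vol), truth2d


@pytest.fixture(scope="session")
def sierpinski_512():
    return vf.make_fractal_phantom(
        vf.FractalPhantomSpec("sierpinski_triangle", size_px=512, order=7))


def run_imaging(vol, min_component=50, seed=0):
    """volume -> MIP -> isodata mask -> cleanup -> skeleton -> estimate."""
    mip = vf.max_intensity_project(vol)
    mask = vf.clean_mask(vf.threshold_isodata(mip), min_component)
    skel = vf.skeletonize(mask)
    return vf.estimate_df(skel, vf.BoxCountConfig(seed=seed))
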
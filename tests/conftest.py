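"""Shared fixtures: calibrated sensor, dynamic range and a rendered
two-state ALEX movie reused by the pipeline-level tests."""

import numpy as np
import pytest

from forcefret.calibration import default_params
from forcefret.dynrange import assemble_dynamic_range
from forcefret.fret import CorrectionFactors
from forcefret.pipeline import analyze_movie, register_from_fiducials
from forcefret.registration import AffineTransform
from forcefret.simulate import (CameraParams, TimingParams, random_scene,
                                render_fiducial_pair, render_movie)

# study conditions of the synthetic two-state experiment (collapsed
# sensors at E=0.87, force-loaded at E=0.42 with 21% weight, as on
# gel-phase bilayers under activating conditions)
MOVIE_SHAPE = (128, 128)
N_MOLECULES = 50
N_PAIRS = 160
E_STATES = (0.87, 0.42)
STATE_FRACTIONS = (0.79, 0.21)
FACTORS = CorrectionFactors(alpha=0.05, delta=0.03, gamma=0.95, beta=1.0)


@pytest.fixture(scope="session")
def params():
    return default_params()          # linker calibrated at E0 = 0.87


@pytest.fixture(scope="session")
def dyn_range(params):
    return assemble_dynamic_range(params, e_max=0.8)


def _channel_affine() -> AffineTransform:
    th = np.deg2rad(0.3)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    return AffineTransform(1.004 * rot, [2.3, -1.7])


@pytest.fixture(scope="session")
def channel_affine():
    return _channel_affine()


@pytest.fixture(scope="session")
def two_state_movie(channel_affine):
    """Rendered movie with ground truth, plus its generating factors."""
    camera = CameraParams()
    timing = TimingParams(n_frame_pairs=N_PAIRS)   # 50 fps doublets
    scene = random_scene(
        N_MOLECULES, shape=MOVIE_SHAPE, camera=camera,
        e_states=E_STATES, state_fractions=STATE_FRACTIONS,
        acceptor_bleach_window_s=(0.9, 2.9),
        donor_bleach_window_s=(4.0, 10.0), seed=11)
    yy, xx = np.mgrid[0:MOVIE_SHAPE[0], 0:MOVIE_SHAPE[1]]
    profile = np.exp(-((xx - 64) ** 2 + (yy - 64) ** 2) / (2 * 150.0 ** 2))
    profile /= profile.max()
    movie = render_movie(scene, camera, timing, shape=MOVIE_SHAPE,
                         factors=FACTORS, donor_transform=channel_affine,
                         laser_profile_g=profile, laser_profile_r=profile,
                         seed=12)
    return movie


@pytest.fixture(scope="session")
def fitted_transform(channel_affine):
    """Channel transform recovered from rendered fiducial beads."""
    donor_img, acceptor_img, _, _ = render_fiducial_pair(
        20, channel_affine, shape=MOVIE_SHAPE, seed=13)
    return register_from_fiducials(donor_img, acceptor_img)


@pytest.fixture(scope="session")
def two_state_result(two_state_movie, fitted_transform, params):
    """Full pipeline output for the two-state movie."""
    return analyze_movie(two_state_movie, transform=fitted_transform,
                         factors=FACTORS, params=params, e_max=0.8, seed=0)
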
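"""Shared fixtures: small phantom tilt series generated at test time."""

import numpy as np
import pytest

from tiltrefine.geometry import AlignmentParams
from tiltrefine.objective import ContrastConfig, central_slab_range
from tiltrefine.recon import TiledProjector, make_tile_grid
from tiltrefine.synthetic import PhantomSpec, make_phantom, project_phantom


def build_case(**kwargs):
    """Phantom + tilt series + truth in one dict."""
    spec = PhantomSpec(**kwargs)
    volume, particles, meta = make_phantom(spec)
    ts, truth, true_motion = project_phantom(volume, spec)
    return {
        "spec": spec,
        "volume": volume,
        "particles": particles,
        "meta": meta,
        "ts": ts,
        "truth": truth,
        "true_motion": true_motion,
    }


@pytest.fixture(scope="session")
def small_clean_case():
    """Noiseless, perfectly aligned 15-tilt phantom (64^2 footprint, z=32)."""
    return build_case(volume_size=(32, 64, 64), slab_z_fraction=0.4,
                      n_particles=12, particle_radius=2.5, n_fiducials=4,
                      noise_sigma=0.0, tilt_scheme=np.arange(-56.0, 56.1, 8.0),
                      misalignment_px=0.0, seed=3)


@pytest.fixture(scope="session")
def small_noisy_case():
    """15-tilt phantom with noise and injected shifts (64^2 footprint, z=32)."""
    return build_case(volume_size=(32, 64, 64), slab_z_fraction=0.4,
                      n_particles=12, particle_radius=2.5, n_fiducials=4,
                      target_snr=0.3, tilt_scheme=np.arange(-56.0, 56.1, 8.0),
                      misalignment_px=3.0, seed=5)


@pytest.fixture(scope="session")
def grad_fixture():
    """Noiseless 15-tilt fixture for gradient checks on 32^3 tiles."""
    case = build_case(volume_size=(32, 64, 64), slab_z_fraction=0.2,
                      n_particles=12, particle_radius=2.5, n_fiducials=4,
                      noise_sigma=0.0, tilt_scheme=np.arange(-56.0, 56.1, 8.0),
                      misalignment_px=2.0, seed=5)
    grid = make_tile_grid((64, 64), 32, 0.0)
    projector = TiledProjector(case["ts"], case["truth"], grid)
    ccfg = ContrastConfig()
    case.update(grid=grid, projector=projector, ccfg=ccfg,
                zrange=central_slab_range(32, ccfg))
    return case


def identity_like(truth: AlignmentParams) -> AlignmentParams:
    return AlignmentParams.identity(truth.theta_deg)
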
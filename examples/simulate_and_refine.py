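"""Refine the alignment of a misaligned phantom tilt series.

Builds a small lamella phantom with known per-tilt shifts, refines the
alignment by contrast maximization and reports how much of the injected
misalignment was recovered.
"""

import numpy as np

from tiltrefine import AlignmentParams, RefinementConfig, refine
from tiltrefine.metrics import translation_rmse_modulo_origin
from tiltrefine.synthetic import PhantomSpec, make_phantom, project_phantom


def main():
    spec = PhantomSpec(volume_size=(64, 128, 128), slab_z_fraction=0.4,
                       n_particles=80, particle_radius=3.0, n_fiducials=12,
                       target_snr=0.3, tilt_scheme=np.arange(-56.0, 56.1, 8.0),
                       misalignment_px=4.0, seed=0)
    volume, particles, _ = make_phantom(spec)
    ts, truth, _ = project_phantom(volume, spec)
    print(f"phantom: {ts.n_tilts} tilts of {ts.shape[2]}x{ts.shape[1]} px, "
          f"injected shifts up to +-{spec.misalignment_px} px")

    init = AlignmentParams.identity(truth.theta_deg)
    cfg = RefinementConfig(tile_size=64, overlap_fraction=0.0, seed=0)
    params, _, trace = refine(ts, init, cfg)

    rmse0 = translation_rmse_modulo_origin(init, truth)
    rmse1 = translation_rmse_modulo_origin(params, truth)
    print(f"translation RMSE vs ground truth (tomogram-origin gauge removed): "
          f"{rmse0:.2f} px -> {rmse1:.2f} px")
    print(f"contrast loss: {trace.losses[0]:.4f} -> "
          f"{trace.losses[trace.best_index]:.4f} "
          f"(lower = higher central-slab contrast)")
    print("the loss cannot see a global shift of the reconstruction origin, "
          "so recovery is measured modulo that 3-mode gauge.")


if __name__ == "__main__":
    main()
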
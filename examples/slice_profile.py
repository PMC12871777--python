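"""Before/after slice-std contrast profile of a reconstruction.

Reconstructs the same phantom under a misaligned and the true alignment,
and prints the slice-wise standard deviation along z: the central slab
(where the sample lives) scores higher under the correct alignment, while
the outer noise slabs stay at their normalized level of ~1.
"""

import numpy as np

from tiltrefine import AlignmentParams, RefinementConfig, contrast_report
from tiltrefine.synthetic import PhantomSpec, make_phantom, project_phantom


def main():
    spec = PhantomSpec(volume_size=(32, 64, 64), slab_z_fraction=0.4,
                       n_particles=12, particle_radius=2.5, n_fiducials=4,
                       target_snr=0.3, tilt_scheme=np.arange(-56.0, 56.1, 8.0),
                       misalignment_px=3.0, seed=5)
    volume, _, _ = make_phantom(spec)
    ts, truth, _ = project_phantom(volume, spec)
    misaligned = AlignmentParams.identity(truth.theta_deg)

    cfg = RefinementConfig(tile_size=32, overlap_fraction=0.0)
    report = contrast_report(ts, misaligned, truth, cfg)
    z0, z1 = report.zrange
    print(" z | misaligned | true alignment")
    for z in range(cfg.tile_size):
        marker = " <- central slab" if z0 <= z <= z1 else ""
        print(f"{z:2d} | {report.profile_before[z]:10.3f} | "
              f"{report.profile_after[z]:10.3f}{marker}")
    print(f"\ncentral-slab contrast score: {report.score_before:.3f} "
          f"(misaligned) vs {report.score_after:.3f} (true)")
    print("misalignment blurs the particles, so the central slices lose "
          "standard deviation; the outer slabs are noise either way.")


if __name__ == "__main__":
    main()
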
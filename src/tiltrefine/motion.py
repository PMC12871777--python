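"""First-order polynomial local-motion (lamella deformation) model.

Within one tilt image, apparent drift varies with position: the drift a
tile experiences is modeled as a first-order polynomial of the tile-center
X-Y coordinate,

    drift_a(x, y) = c0_a + cx_a * x_hat + cy_a * y_hat,   a in {x, y},

with ``(x_hat, y_hat)`` the tomogram coordinate normalized to [-1, 1] over
the footprint half-extent. Normalizing conditions the optimizer: raw pixel
coordinates of order 10^3 would give the linear terms gradients 10^3 times
larger than the constant term. The constant terms are redundant with the
per-tilt translations (tx, ty); for identifiability the refinement keeps
c0 frozen at zero and global translation lives exclusively in (tx, ty).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import AlignmentParams, project_point

__all__ = ["MotionModel", "drift_at", "map_particle_to_micrographs",
           "write_drift_field_csv"]


@dataclass
class MotionModel:
    """Per-tilt first-order drift coefficients.

    ``coeff_x[i] = (c0, cx, cy)`` for the x-drift of tilt ``i`` and
    ``coeff_y[i]`` likewise for the y-drift, in pixels at the working
    scale, evaluated at normalized footprint coordinates.
    """

    coeff_x: np.ndarray  # (n_tilts, 3)
    coeff_y: np.ndarray  # (n_tilts, 3)

    def __post_init__(self) -> None:
        self.coeff_x = np.atleast_2d(np.asarray(self.coeff_x, dtype=np.float64))
        self.coeff_y = np.atleast_2d(np.asarray(self.coeff_y, dtype=np.float64))
        if self.coeff_x.shape != self.coeff_y.shape or self.coeff_x.shape[1] != 3:
            raise ValueError("motion coefficients must be (n_tilts, 3) per axis")
        if not (np.all(np.isfinite(self.coeff_x)) and np.all(np.isfinite(self.coeff_y))):
            raise ValueError("non-finite motion coefficient")

    @property
    def n_tilts(self) -> int:
        return self.coeff_x.shape[0]

    @classmethod
    def zeros(cls, n_tilts: int) -> "MotionModel":
        return cls(np.zeros((n_tilts, 3)), np.zeros((n_tilts, 3)))

    def copy(self) -> "MotionModel":
        return MotionModel(self.coeff_x.copy(), self.coeff_y.copy())


def normalized_xy(xy, footprint: tuple[int, int]) -> np.ndarray:
    """Map center-origin tomogram (x, y) to [-1, 1] over the footprint."""
    xy = np.asarray(xy, dtype=np.float64)
    half = np.asarray(footprint, dtype=np.float64) / 2.0
    return xy / half


def drift_at(motion: MotionModel, tilt_index: int, xy,
             footprint: tuple[int, int]) -> np.ndarray:
    """Evaluate the drift polynomials of one tilt at a tomogram (x, y).

    ``footprint`` is the (nx, ny) tomogram extent used for normalization.
    Returns (dx, dy) in pixels. Linear in all six coefficients.
    """
    if not 0 <= tilt_index < motion.n_tilts:
        raise IndexError(f"tilt index {tilt_index} out of range")
    xh, yh = normalized_xy(xy, footprint)
    cx = motion.coeff_x[tilt_index]
    cy = motion.coeff_y[tilt_index]
    return np.array([cx[0] + cx[1] * xh + cx[2] * yh,
                     cy[0] + cy[1] * xh + cy[2] * yh])


def write_drift_field_csv(motion: MotionModel, footprint: tuple[int, int],
                          path, spacing: int = 32) -> None:
    """Export per-tilt drift vectors on a regular grid as CSV
    (tilt_index, x, y, dx_px, dy_px) — the raw material for quiver plots
    of the local-motion field."""
    nx, ny = footprint
    xs = np.arange(-nx // 2 + spacing // 2, nx // 2, spacing)
    ys = np.arange(-ny // 2 + spacing // 2, ny // 2, spacing)
    with open(path, "w") as fh:
        fh.write("tilt_index,x,y,dx_px,dy_px\n")
        for i in range(motion.n_tilts):
            for y in ys:
                for x in xs:
                    dx, dy = drift_at(motion, i, (x, y), footprint)
                    fh.write(f"{i},{x},{y},{dx:.5f},{dy:.5f}\n")


def map_particle_to_micrographs(particle, params: AlignmentParams,
                                motion: MotionModel | None,
                                footprint: tuple[int, int]) -> np.ndarray:
    """Per-tilt 2D micrograph coordinates of one 3D particle.

    Projects the particle under each tilt's parameters, then adds the local
    drift evaluated at the particle's own (x, y); with ``motion=None`` this
    reduces exactly to the bare projection. Returns an (n_tilts, 2) array
    ordered by tilt index.
    """
    p = np.asarray(particle, dtype=np.float64)
    out = np.empty((params.n_tilts, 2))
    for i in range(params.n_tilts):
        uv = project_point(p, params.tx[i], params.ty[i],
                           params.theta_deg[i], params.rot_deg[i])
        if motion is not None:
            uv = uv + drift_at(motion, i, p[:2], footprint)
        out[i] = uv
    return out
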
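"""Gauge-aware evaluation metrics for synthetic-recovery experiments.

The contrast loss determines the alignment only up to a re-parameterization
of the tomogram frame: a global displacement of the reconstruction origin
(three modes: (dx cos t - dz sin t) in image x and dy in image y), and —
once the first-order local-motion field is active — a global affine remap
of the volume (scales and shears show up as drift coefficients modulated
by 1, cos t and sin t across tilts). Such modes move nothing relative to
the reconstructed tomogram: particles picked in it carry the same remap,
so every downstream quantity is invariant. Comparing refined parameters
against simulation ground truth therefore quotients these families out;
otherwise the metric would be dominated by an arbitrary frame choice.
"""

from __future__ import annotations

import numpy as np

from .geometry import AlignmentParams, detector_axes
from .io_formats import ParticleSet
from .motion import MotionModel, map_particle_to_micrographs

__all__ = [
    "translation_residual_modulo_origin",
    "translation_rmse_modulo_origin",
    "track_errors_modulo_affine",
]


def translation_residual_modulo_origin(params: AlignmentParams,
                                       truth: AlignmentParams,
                                       ) -> tuple[np.ndarray, np.ndarray]:
    """Per-tilt translation residual with the origin gauge projected out.

    Fits (a cos t + b sin t) to the x residual and a constant to the y
    residual and removes the fits. Returns ``(residual, gauge)`` arrays of
    shape (n_tilts, 2).
    """
    th = np.deg2rad(truth.theta_deg)
    rx = params.tx - truth.tx
    ry = params.ty - truth.ty
    A = np.stack([np.cos(th), np.sin(th)], axis=1)
    coef, *_ = np.linalg.lstsq(A, rx, rcond=None)
    gauge = np.stack([A @ coef, np.full_like(ry, ry.mean())], axis=1)
    resid = np.stack([rx, ry], axis=1) - gauge
    return resid, gauge


def translation_rmse_modulo_origin(params: AlignmentParams,
                                   truth: AlignmentParams) -> float:
    resid, _ = translation_residual_modulo_origin(params, truth)
    return float(np.sqrt(np.mean(resid ** 2)))


def track_errors_modulo_affine(particles: ParticleSet,
                               params: AlignmentParams,
                               motion: MotionModel | None,
                               truth: AlignmentParams,
                               true_motion: MotionModel | None,
                               footprint: tuple[int, int],
                               ) -> np.ndarray:
    """Per-(particle, tilt) track errors after removing a global affine
    remap of the tomogram frame.

    The remap (M = I + E, d) displaces the predicted micrograph position
    of a particle p on tilt i by ``r_axis . (E p + d)`` with r_axis the
    detector axes; the twelve (E, d) parameters are fit by least squares
    over all particles and tilts and removed. Returns the residual error
    matrix of shape (n_particles, n_tilts).
    """
    n_t = params.n_tilts
    n_p = len(particles)
    rows = np.zeros((n_p * n_t * 2, 12))
    resid = np.zeros(n_p * n_t * 2)
    axes = [detector_axes(truth.theta_deg[i], truth.rot_deg[i])
            for i in range(n_t)]
    k = 0
    for p in particles.coords:
        t_true = map_particle_to_micrographs(p, truth, true_motion, footprint)
        t_est = map_particle_to_micrographs(p, params, motion, footprint)
        for i in range(n_t):
            for rvec, comp in zip(axes[i], (0, 1)):
                rows[k, :9] = np.outer(rvec, p).ravel()
                rows[k, 9:] = rvec
                resid[k] = t_est[i, comp] - t_true[i, comp]
                k += 1
    coef, *_ = np.linalg.lstsq(rows, resid, rcond=None)
    res = (resid - rows @ coef).reshape(n_p, n_t, 2)
    return np.linalg.norm(res, axis=2)
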
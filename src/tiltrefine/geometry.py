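"""Single-axis tilt geometry and band-limiting.

Conventions used throughout the package:

* Math coordinates are ``(x, y, z)`` with the origin at the volume/image
  center; arrays are indexed ``(z, y, x)`` (images ``(y, x)``).
* Right-handed axes, electron beam along ``+z``; the tilt axis lies along
  ``y`` after the in-plane rotation; positive tilt rotates ``+x`` toward
  ``+z``.
* Image pixel centers are 0-based; the center-origin pixel ``(0, 0)`` maps
  to array index ``(ny // 2, nx // 2)`` (the FFT-shift center for even
  dimensions, which all geometry math assumes).

A 3D point ``p`` seen on tilt ``i`` is mapped to micrograph coordinates by
rotating about the beam axis (``rot_i``), rotating about the tilt axis
(``theta_i``), projecting orthographically along the beam and translating
by ``(tx_i, ty_i)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AlignmentParams",
    "rotation_matrix",
    "detector_axes",
    "project_point",
    "project_point_jacobian",
    "downsample_to_nyquist",
]


@dataclass
class AlignmentParams:
    """Per-tilt geometric parameters; the variables the optimizer updates.

    ``tx``/``ty`` are translations in pixels at the working (downsampled)
    scale, ``theta_deg`` the stage tilt angles and ``rot_deg`` the in-plane
    tilt-axis rotation, one entry per tilt image.
    """

    tx: np.ndarray
    ty: np.ndarray
    theta_deg: np.ndarray
    rot_deg: np.ndarray
    refine_rotation: bool = field(default=False)

    def __post_init__(self) -> None:
        self.tx = np.atleast_1d(np.asarray(self.tx, dtype=np.float64))
        self.ty = np.atleast_1d(np.asarray(self.ty, dtype=np.float64))
        self.theta_deg = np.atleast_1d(np.asarray(self.theta_deg, dtype=np.float64))
        self.rot_deg = np.atleast_1d(np.asarray(self.rot_deg, dtype=np.float64))
        n = len(self.theta_deg)
        if not (len(self.tx) == len(self.ty) == len(self.rot_deg) == n):
            raise ValueError("alignment parameter arrays must share one length per tilt")
        for name in ("tx", "ty", "theta_deg", "rot_deg"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite values in {name}")
        if np.any(np.abs(self.theta_deg) >= 90.0):
            raise ValueError("tilt angles must lie strictly within (-90, 90) degrees")

    @property
    def n_tilts(self) -> int:
        return len(self.theta_deg)

    def copy(self) -> "AlignmentParams":
        return AlignmentParams(
            self.tx.copy(), self.ty.copy(), self.theta_deg.copy(),
            self.rot_deg.copy(), self.refine_rotation,
        )

    @classmethod
    def identity(cls, tilt_angles_deg) -> "AlignmentParams":
        """Zero translations and in-plane rotations at the given tilt angles."""
        th = np.atleast_1d(np.asarray(tilt_angles_deg, dtype=np.float64))
        z = np.zeros_like(th)
        return cls(z.copy(), z.copy(), th, z.copy())


def rotation_matrix(theta_deg: float, rot_deg: float) -> np.ndarray:
    """3x3 rotation ``R = Ry(theta) @ Rz(rot)`` acting on (x, y, z) vectors.

    ``Ry`` rotates +x toward +z for positive theta; ``Rz`` rotates +x
    toward +y for positive rot.
    """
    th = np.deg2rad(theta_deg)
    r = np.deg2rad(rot_deg)
    ct, st = np.cos(th), np.sin(th)
    cr, sr = np.cos(r), np.sin(r)
    ry = np.array([[ct, 0.0, -st], [0.0, 1.0, 0.0], [st, 0.0, ct]])
    rz = np.array([[cr, -sr, 0.0], [sr, cr, 0.0], [0.0, 0.0, 1.0]])
    return ry @ rz


def detector_axes(theta_deg: float, rot_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """First two rows of the rotation: the detector (u, v) axes in volume
    coordinates. By the central-slice theorem these rows also span the
    Fourier plane a projection occupies."""
    R = rotation_matrix(theta_deg, rot_deg)
    return R[0], R[1]


def project_point(p, tx: float, ty: float, theta_deg: float, rot_deg: float = 0.0):
    """Map a center-origin 3D point to center-origin 2D micrograph coords."""
    p = np.asarray(p, dtype=np.float64)
    r1, r2 = detector_axes(theta_deg, rot_deg)
    return np.array([p @ r1 + tx, p @ r2 + ty])


def project_point_jacobian(p, tx: float, ty: float, theta_deg: float,
                           rot_deg: float = 0.0) -> np.ndarray:
    """Closed-form Jacobian of :func:`project_point`.

    Returns the 2x4 matrix d(u, v)/d(tx, ty, rot_deg, theta_deg); angular
    derivatives are per degree.
    """
    x, y, z = np.asarray(p, dtype=np.float64)
    th = np.deg2rad(theta_deg)
    r = np.deg2rad(rot_deg)
    ct, st = np.cos(th), np.sin(th)
    cr, sr = np.cos(r), np.sin(r)
    deg = np.pi / 180.0
    # u = ct*(x cr - y sr) - st*z + tx ; v = x sr + y cr + ty
    du_drot = ct * (-x * sr - y * cr) * deg
    du_dth = (-st * (x * cr - y * sr) - ct * z) * deg
    dv_drot = (x * cr - y * sr) * deg
    dv_dth = 0.0
    return np.array([[1.0, 0.0, du_drot, du_dth],
                     [0.0, 1.0, dv_drot, dv_dth]])


def _even_floor(n: int) -> int:
    return n - (n % 2)


def downsample_to_nyquist(ts, target_resolution_A: float = 50.0):
    """Fourier-crop a tilt series so Nyquist sits at ``target_resolution_A``.

    The new pixel size is ``target_resolution_A / 2``. Cropping happens in
    Fourier space (exact band limit, no aliasing); amplitudes of retained
    frequencies are preserved, so in-band power is unchanged. Output
    dimensions are forced even. A no-op when the target equals the input
    Nyquist.
    """
    from .io_formats import TiltSeries  # local import to avoid a cycle

    new_ps = target_resolution_A / 2.0
    n_tilts, ny, nx = ts.images.shape
    scale = ts.pixel_size / new_ps
    nyd, nxd = _even_floor(int(round(ny * scale))), _even_floor(int(round(nx * scale)))
    if nyd > ny or nxd > nx:
        raise ValueError(
            f"target resolution {target_resolution_A} A is finer than the input "
            f"Nyquist ({2.0 * ts.pixel_size} A)")
    if (nyd, nxd) == (ny, nx):
        return TiltSeries(ts.images.copy(), ts.pixel_size, ts.tilt_angles.copy())

    out = np.empty((n_tilts, nyd, nxd), dtype=np.float64)
    ry, rx = nyd // 2, nxd // 2
    amp = (nyd * nxd) / (ny * nx)  # keeps per-frequency amplitudes fixed
    for i in range(n_tilts):
        F = np.fft.fftshift(np.fft.fft2(ts.images[i]))
        cy, cx = ny // 2, nx // 2
        crop = F[cy - ry: cy + ry, cx - rx: cx + rx]
        out[i] = np.fft.ifft2(np.fft.ifftshift(crop)).real * amp
    # the even-floor rounding can make the realized pixel size differ
    # marginally from target/2; report the exact value for the x axis
    real_ps = ts.pixel_size * nx / nxd
    return TiltSeries(out, real_ps, ts.tilt_angles.copy())
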
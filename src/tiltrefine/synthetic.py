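"""Phantom lamella tilt series with known ground truth.

The phantom emulates a cryo-FIB-milled lamella imaged at the working
(50 A Nyquist) scale: a central z slab containing dark (negative
contrast) globular particles, optional strongly dark fiducial-like
particles sitting on the slab surfaces, empty vacuum above and below,
white Gaussian noise, per-tilt misalignment shifts and an optional
position-dependent linear drift field.

The forward model projects in real space (rotate with spline
interpolation, then sum along the beam), *not* via Fourier slicing, so
reconstruction tests against these fixtures exercise an independent
implementation of the same geometry. Noise is white and there is no CTF
or dose damage: at the 50 A band the contrast objective operates on,
those effects are secondary, and their absence is what keeps the
parameter-recovery tests interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import AlignmentParams, rotation_matrix
from .io_formats import ParticleSet, TiltSeries
from .motion import MotionModel

__all__ = [
    "PhantomSpec",
    "PhantomFixture",
    "make_phantom",
    "project_phantom",
    "make_fixture",
    "standard_suite",
    "write_fixture",
]


@dataclass
class PhantomSpec:
    """Study conditions for one synthetic lamella tilt series.

    ``volume_size`` is either a cube side or an explicit (nz, ny, nx).
    ``slab_z_fraction`` is the lamella thickness as a fraction of nz.
    Negative contrasts follow the density convention (protein is dark).
    ``noise_sigma`` overrides ``target_snr`` when given; otherwise the
    noise level is set so the projection-domain SNR (signal variance over
    noise variance) equals ``target_snr``. ``misalignment_px`` scales the
    injected per-tilt shifts (uniform half-width or Gaussian sigma).
    ``motion_gradient`` is None, a magnitude (per-tilt linear drift
    coefficients drawn uniformly within it, in pixels at the footprint
    edge), or an explicit (n_tilts, 4) coefficient array
    (cx_x, cy_x, cx_y, cy_y).
    """

    volume_size: int | tuple[int, int, int] = 64
    slab_z_fraction: float = 0.4
    n_particles: int = 40
    particle_radius: float = 3.0
    particle_contrast: float = -1.0
    n_fiducials: int = 8
    fiducial_contrast: float = -4.0
    noise_sigma: float | None = None
    target_snr: float = 0.3
    pixel_size_A: float = 25.0
    tilt_scheme: np.ndarray | None = None
    misalignment_px: float = 4.0
    misalignment_dist: str = "uniform"  # "uniform" | "gaussian"
    motion_gradient: float | np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.volume_size, (int, np.integer)):
            self.volume_size = (int(self.volume_size),) * 3
        if self.tilt_scheme is None:
            self.tilt_scheme = np.arange(-60.0, 60.1, 3.0)
        self.tilt_scheme = np.asarray(self.tilt_scheme, dtype=np.float64)
        if not 0.0 < self.slab_z_fraction <= 1.0:
            raise ValueError("slab_z_fraction must lie in (0, 1]")
        if self.particle_contrast > 0 or self.fiducial_contrast > 0:
            raise ValueError("contrasts must be negative (protein is dark)")
        if self.misalignment_dist not in ("uniform", "gaussian"):
            raise ValueError("misalignment_dist must be 'uniform' or 'gaussian'")

    @property
    def n_tilts(self) -> int:
        return len(self.tilt_scheme)


def _add_sphere(volume: np.ndarray, center_xyz, radius: float,
                contrast: float) -> None:
    """Rasterize a sphere with a one-voxel linear edge (band-limit friendly)."""
    nz, ny, nx = volume.shape
    ctr = np.array([nx // 2, ny // 2, nz // 2], dtype=np.float64)
    cx, cy, cz = np.asarray(center_xyz, dtype=np.float64) + ctr
    r = radius + 0.5
    x0, x1 = max(0, int(cx - r - 1)), min(nx, int(cx + r + 2))
    y0, y1 = max(0, int(cy - r - 1)), min(ny, int(cy + r + 2))
    z0, z1 = max(0, int(cz - r - 1)), min(nz, int(cz + r + 2))
    zz, yy, xx = np.mgrid[z0:z1, y0:y1, x0:x1]
    d = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2 + (zz - cz) ** 2)
    volume[z0:z1, y0:y1, x0:x1] += contrast * np.clip(radius + 0.5 - d, 0.0, 1.0)


def make_phantom(spec: PhantomSpec) -> tuple[np.ndarray, ParticleSet, dict]:
    """Build the phantom volume; returns (volume, particle set, metadata).

    Particles are confined to the slab with non-overlapping centers;
    fiducials sit on the slab faces. Deterministic given ``spec.seed``.
    """
    nz, ny, nx = spec.volume_size
    rng = np.random.default_rng(spec.seed)
    volume = np.zeros((nz, ny, nx))
    half_slab = 0.5 * spec.slab_z_fraction * nz
    r = spec.particle_radius
    zlim = max(half_slab - r, 0.0)
    xlim, ylim = nx / 2.0 - r - 1.0, ny / 2.0 - r - 1.0

    coords: list[np.ndarray] = []
    for _ in range(spec.n_particles):
        for _attempt in range(1000):
            p = np.array([rng.uniform(-xlim, xlim), rng.uniform(-ylim, ylim),
                          rng.uniform(-zlim, zlim)])
            if all(np.linalg.norm(p - q) >= 2.0 * r for q in coords):
                coords.append(p)
                break
        else:
            raise RuntimeError("could not place particles without overlap")
    for p in coords:
        _add_sphere(volume, p, r, spec.particle_contrast)

    fid_coords: list[np.ndarray] = []
    for _ in range(spec.n_fiducials):
        for _attempt in range(1000):
            side = 1.0 if rng.uniform() < 0.5 else -1.0
            p = np.array([rng.uniform(-xlim, xlim), rng.uniform(-ylim, ylim),
                          side * half_slab])
            if all(np.linalg.norm(p - q) >= 2.0 * r for q in fid_coords):
                fid_coords.append(p)
                break
        else:
            raise RuntimeError("could not place fiducials without overlap")
    for p in fid_coords:
        _add_sphere(volume, p, r, spec.fiducial_contrast)

    particles = ParticleSet(np.asarray(coords).reshape(-1, 3))
    meta = {"half_slab": half_slab, "fiducials": np.asarray(fid_coords).reshape(-1, 3)}
    return volume, particles, meta


def _rotate_and_sum(volume: np.ndarray, theta_deg: float, rot_deg: float = 0.0,
                    ) -> np.ndarray:
    """Real-space orthographic projection along the beam after rotation."""
    nz, ny, nx = volume.shape
    R = rotation_matrix(theta_deg, rot_deg)
    st, ct = abs(np.sin(np.deg2rad(theta_deg))), abs(np.cos(np.deg2rad(theta_deg)))
    nz_out = int(np.ceil(nx * st + nz * ct)) + 4
    nz_out += nz_out % 2
    # index (z, y, x) <-> coord (x, y, z): conjugate R^T by the axis reversal
    A = R.T[::-1, ::-1]
    ctr_in = np.array([nz // 2, ny // 2, nx // 2], dtype=np.float64)
    ctr_out = np.array([nz_out // 2, ny // 2, nx // 2], dtype=np.float64)
    offset = ctr_in - A @ ctr_out
    rot = ndimage.affine_transform(volume, A, offset=offset,
                                   output_shape=(nz_out, ny, nx), order=1,
                                   mode="constant", cval=0.0)
    return rot.sum(axis=0)


def _warp_image(image: np.ndarray, shift_xy, drift_row, theta_deg: float,
                ) -> np.ndarray:
    """Apply a global shift plus the position-dependent linear drift.

    ``drift_row`` is (cx_x, cy_x, cx_y, cy_y): drift evaluated at the
    normalized tomogram coordinate the micrograph position maps back to
    (x divided by cos(theta) to undo tilt foreshortening).
    """
    ny, nx = image.shape
    tx, ty = shift_xy
    yy, xx = np.mgrid[0:ny, 0:nx].astype(np.float64)
    ct = np.cos(np.deg2rad(theta_deg))
    xh = np.clip(((xx - nx // 2) - tx) / ct / (nx / 2.0), -1.0, 1.0)
    yh = np.clip(((yy - ny // 2) - ty) / (ny / 2.0), -1.0, 1.0)
    cxx, cyx, cxy, cyy = drift_row
    dx = cxx * xh + cyx * yh
    dy = cxy * xh + cyy * yh
    src_y = yy - ty - dy
    src_x = xx - tx - dx
    return ndimage.map_coordinates(image, [src_y, src_x], order=1,
                                   mode="constant", cval=0.0)


def project_phantom(volume: np.ndarray, spec: PhantomSpec,
                    ) -> tuple[TiltSeries, AlignmentParams, MotionModel | None]:
    """Project the phantom at the tilt scheme with injected misalignment,
    optional linear drift and Gaussian noise; returns the tilt series plus
    the true alignment parameters (and true motion model, if any)."""
    rng = np.random.default_rng(spec.seed + 1)
    angles = spec.tilt_scheme
    n = len(angles)
    nz, ny, nx = volume.shape

    if spec.misalignment_dist == "uniform":
        shifts = rng.uniform(-spec.misalignment_px, spec.misalignment_px, (n, 2))
    else:
        shifts = rng.normal(0.0, spec.misalignment_px, (n, 2))

    if spec.motion_gradient is None:
        coeffs = np.zeros((n, 4))
        true_motion = None
    else:
        if np.isscalar(spec.motion_gradient):
            coeffs = rng.uniform(-spec.motion_gradient, spec.motion_gradient, (n, 4))
        else:
            coeffs = np.asarray(spec.motion_gradient, dtype=np.float64)
        true_motion = MotionModel(
            np.concatenate([np.zeros((n, 1)), coeffs[:, 0:2]], axis=1),
            np.concatenate([np.zeros((n, 1)), coeffs[:, 2:4]], axis=1))

    clean = np.empty((n, ny, nx))
    for i, th in enumerate(angles):
        proj = _rotate_and_sum(volume, th)
        clean[i] = _warp_image(proj, shifts[i], coeffs[i], th)

    sigma = spec.noise_sigma
    if sigma is None:
        sig_var = clean.var(axis=(1, 2)).mean()
        sigma = float(np.sqrt(sig_var / spec.target_snr)) if sig_var > 0 else 0.0
    images = clean + rng.normal(0.0, sigma, clean.shape) if sigma > 0 else clean.copy()

    ts = TiltSeries(images, spec.pixel_size_A, angles.copy())
    true_params = AlignmentParams(shifts[:, 0].copy(), shifts[:, 1].copy(),
                                  angles.copy(), np.zeros(n))
    return ts, true_params, true_motion


@dataclass
class PhantomFixture:
    """A named phantom configuration; materialized lazily and cached."""

    name: str
    spec: PhantomSpec
    _data: dict | None = field(default=None, repr=False)

    def materialize(self) -> dict:
        if self._data is None:
            volume, particles, meta = make_phantom(self.spec)
            ts, true_params, true_motion = project_phantom(volume, self.spec)
            self._data = {
                "volume": volume,
                "particles": particles,
                "meta": meta,
                "tiltseries": ts,
                "true_params": true_params,
                "true_motion": true_motion,
            }
        return self._data


def make_fixture(name: str, **kwargs) -> PhantomFixture:
    return PhantomFixture(name, PhantomSpec(**kwargs))


def standard_suite(level: str = "smoke") -> list[PhantomFixture]:
    """Named fixture sets: ``smoke`` is one small fast phantom; ``full``
    is three seeds times {translation-only, translation+motion} at full
    size for the acceptance suite."""
    if level == "smoke":
        return [make_fixture("smoke", volume_size=64,
                             tilt_scheme=np.arange(-56.0, 56.1, 8.0), seed=0)]
    if level == "full":
        out = []
        for seed in (0, 1, 2):
            for mode, grad in (("trans", None), ("motion", 2.0)):
                out.append(make_fixture(
                    f"full-s{seed}-{mode}", volume_size=128,
                    tilt_scheme=np.arange(-60.0, 60.1, 3.0),
                    motion_gradient=grad, seed=seed))
        return out
    raise ValueError(f"unknown suite level {level!r}")


def write_fixture(fixture: PhantomFixture, outdir) -> dict:
    """Write one fixture as MRC + .tlt + ground-truth JSON + particle text."""
    import os

    from .io_formats import write_alignment, write_particles, write_tiltseries

    data = fixture.materialize()
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "mrc": os.path.join(outdir, f"{fixture.name}.mrc"),
        "tlt": os.path.join(outdir, f"{fixture.name}.tlt"),
        "truth": os.path.join(outdir, f"{fixture.name}_truth.json"),
        "particles": os.path.join(outdir, f"{fixture.name}_particles.txt"),
    }
    write_tiltseries(data["tiltseries"], paths["mrc"], paths["tlt"])
    write_alignment(data["true_params"], data["true_motion"], paths["truth"],
                    pixel_size_A=data["tiltseries"].pixel_size,
                    meta={"fixture": fixture.name, "seed": fixture.spec.seed})
    write_particles(data["particles"], paths["particles"])
    return paths
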
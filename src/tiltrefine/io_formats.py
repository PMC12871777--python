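"""Readers and writers for tilt series, alignments and particle tables.

Supported formats:

* MRC2014 image stacks / volumes (mode-2 float, sections along z), via
  gemmi with explicit axis bookkeeping so files keep the conventional
  x-fastest layout readable by IMOD/EMAN2/RELION.
* IMOD ``.tlt`` (one tilt angle per line, degrees) and ``.xf``
  (``a11 a12 a21 a22 dx dy`` per line) alignment files.
* A self-describing native JSON dialect for refined alignments, including
  optional local-motion coefficients and refinement metadata.
* Plain-text / JSON particle coordinate tables in downsampled-tomogram
  voxels with a center origin (the package's internal frame).

Tilt angles are always taken from a ``.tlt`` file, never from the MRC
extended header, whose dialects are inconsistent across packages.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .geometry import AlignmentParams
from .motion import MotionModel

__all__ = [
    "TiltSeries",
    "ParticleSet",
    "read_mrc",
    "write_mrc",
    "read_tlt",
    "write_tlt",
    "read_tiltseries",
    "write_tiltseries",
    "read_alignment",
    "write_alignment",
    "read_particles",
    "write_particles",
]


@dataclass
class TiltSeries:
    """A stack of 2D micrographs with pixel size and tilt angles.

    Images are stored sorted by tilt angle; ``original_order`` maps the
    sorted position back to the position in the source file.
    """

    images: np.ndarray  # (n_tilts, ny, nx) float
    pixel_size: float  # Angstrom per pixel
    tilt_angles: np.ndarray  # degrees, one per image, sorted ascending
    original_order: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float64)
        self.tilt_angles = np.atleast_1d(np.asarray(self.tilt_angles, dtype=np.float64))
        if self.images.ndim != 3:
            raise ValueError("images must be a 3D (n_tilts, ny, nx) array")
        if self.images.shape[0] != len(self.tilt_angles):
            raise ValueError(
                f"angle/image count mismatch: {len(self.tilt_angles)} angles for "
                f"{self.images.shape[0]} images")
        if self.images.shape[0] < 3:
            raise ValueError("a tilt series needs at least 3 images")
        if not np.all(np.isfinite(self.images)):
            raise ValueError("non-finite pixel values in tilt series")
        if not (np.isfinite(self.pixel_size) and self.pixel_size > 0):
            raise ValueError(f"non-finite or non-positive pixel size {self.pixel_size}")
        if np.any(np.abs(self.tilt_angles) >= 90.0):
            raise ValueError("tilt angles must lie strictly within (-90, 90)")
        order = np.argsort(self.tilt_angles, kind="stable")
        if np.any(np.diff(self.tilt_angles[order]) <= 0):
            raise ValueError("tilt angles must be distinct (strictly monotone once sorted)")
        if self.original_order is None:
            self.original_order = order
            if not np.array_equal(order, np.arange(len(order))):
                self.images = self.images[order]
                self.tilt_angles = self.tilt_angles[order]
        else:
            self.original_order = np.asarray(self.original_order, dtype=np.intp)

    @property
    def n_tilts(self) -> int:
        return self.images.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.images.shape


@dataclass
class ParticleSet:
    """3D particle coordinates in downsampled-tomogram voxels, center origin."""

    coords: np.ndarray  # (n, 3) columns x, y, z

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=np.float64))
        if self.coords.size == 0:
            self.coords = self.coords.reshape(0, 3)
        if self.coords.shape[1] != 3:
            raise ValueError("particle coordinates must have three columns (x y z)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite particle coordinate")

    def __len__(self) -> int:
        return self.coords.shape[0]


# ---------------------------------------------------------------------------
# MRC2014 via gemmi.  gemmi maps the first numpy axis to the fastest (x)
# file axis, so arrays are transposed on the way in and out to keep the
# package's (z, y, x) indexing and the file's standard section layout.
# ---------------------------------------------------------------------------

def read_mrc(path: str | os.PathLike) -> tuple[np.ndarray, float]:
    """Read an MRC2014 file; returns ((nz, ny, nx) float array, pixel size in A)."""
    if not os.path.exists(path):
        raise FileNotFoundError(str(path))
    m = gemmi.read_ccp4_map(str(path))
    arr = np.array(m.grid, copy=True)  # (nx, ny, nz), x fastest
    data = np.ascontiguousarray(arr.transpose(2, 1, 0)).astype(np.float64)
    nx = data.shape[2]
    pixel = m.grid.unit_cell.a / nx if nx else 1.0
    if not (math.isfinite(pixel) and pixel > 0):
        raise ValueError(f"non-finite or zero pixel size in MRC header of {path}")
    return data, float(pixel)


def write_mrc(path: str | os.PathLike, data: np.ndarray, pixel_size: float) -> None:
    """Write a (nz, ny, nx) array as a mode-2 MRC2014 stack/volume."""
    data = np.asarray(data, dtype=np.float32)
    if data.ndim != 3:
        raise ValueError("write_mrc expects a 3D array")
    nz, ny, nx = data.shape
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(data.transpose(2, 1, 0)))
    m.grid.unit_cell = gemmi.UnitCell(
        nx * pixel_size, ny * pixel_size, nz * pixel_size, 90.0, 90.0, 90.0)
    m.update_ccp4_header()
    m.set_header_i32(23, 0)  # ISPG 0: image stack, not a crystallographic map
    m.write_ccp4_map(str(path))


def read_tlt(path: str | os.PathLike) -> np.ndarray:
    if not os.path.exists(path):
        raise FileNotFoundError(str(path))
    angles = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                angles.append(float(line.split()[0]))
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: malformed tilt angle {line!r}") from exc
    return np.asarray(angles, dtype=np.float64)


def write_tlt(path: str | os.PathLike, angles_deg) -> None:
    with open(path, "w") as fh:
        for a in np.atleast_1d(angles_deg):
            fh.write(f"{float(a):.4f}\n")


def read_tiltseries(path: str | os.PathLike, angles_path: str | os.PathLike) -> TiltSeries:
    """Read an MRC/MRCS stack plus an IMOD-style .tlt angle file."""
    data, pixel = read_mrc(path)
    angles = read_tlt(angles_path)
    if len(angles) != data.shape[0]:
        raise ValueError(
            f"angle/image count mismatch: {len(angles)} angles in {angles_path}, "
            f"{data.shape[0]} images in {path}")
    return TiltSeries(data, pixel, angles)


def write_tiltseries(ts: TiltSeries, path: str | os.PathLike,
                     angles_path: str | os.PathLike) -> None:
    write_mrc(path, ts.images, ts.pixel_size)
    write_tlt(angles_path, ts.tilt_angles)


# ---------------------------------------------------------------------------
# Alignment parameters
# ---------------------------------------------------------------------------

def _xf_to_params(xf_rows: np.ndarray, tilt_angles: np.ndarray) -> AlignmentParams:
    n = xf_rows.shape[0]
    tx = xf_rows[:, 4].copy()
    ty = xf_rows[:, 5].copy()
    rot = np.empty(n)
    for i, (a11, a12, a21, a22, _, _) in enumerate(xf_rows):
        det = a11 * a22 - a12 * a21
        if abs(det) < 1e-12:
            raise ValueError(f"singular 2x2 matrix in .xf line {i + 1}")
        # polar-decomposition rotation angle of the 2x2 block
        rot[i] = math.degrees(math.atan2(a21 - a12, a11 + a22))
    return AlignmentParams(tx, ty, tilt_angles, rot)


def read_alignment(path: str | os.PathLike, dialect: str = "native_json",
                   tlt_path: str | os.PathLike | None = None,
                   ) -> tuple[AlignmentParams, MotionModel | None]:
    """Read alignment parameters.

    ``dialect="imod_xf_tlt"`` expects ``path`` to be the ``.xf`` file and
    ``tlt_path`` the matching ``.tlt``; ``dialect="native_json"`` reads the
    package's own schema (and any motion model stored with it).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(str(path))
    if dialect == "imod_xf_tlt":
        if tlt_path is None:
            raise ValueError("imod_xf_tlt dialect requires tlt_path")
        rows = []
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line:
                    continue
                parts = line.split()
                if len(parts) != 6:
                    raise ValueError(f"{path}:{ln}: expected 6 numbers, got {len(parts)}")
                try:
                    rows.append([float(p) for p in parts])
                except ValueError as exc:
                    raise ValueError(f"{path}:{ln}: malformed .xf line") from exc
        angles = read_tlt(tlt_path)
        rows = np.asarray(rows, dtype=np.float64)
        if rows.shape[0] != len(angles):
            raise ValueError(".xf/.tlt line count mismatch")
        return _xf_to_params(rows, angles), None
    if dialect == "native_json":
        with open(path) as fh:
            try:
                doc = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path} is not valid JSON (wrong dialect?)") from exc
        if not isinstance(doc, dict) or "tilts" not in doc:
            raise ValueError(f"{path}: missing 'tilts' section (wrong dialect?)")
        tilts = doc["tilts"]
        params = AlignmentParams(
            np.array([t["tx_px"] for t in tilts]),
            np.array([t["ty_px"] for t in tilts]),
            np.array([t["angle_deg"] for t in tilts]),
            np.array([t["rot_deg"] for t in tilts]),
        )
        motion = None
        if doc.get("motion") is not None:
            motion = MotionModel(
                coeff_x=np.array([m["ax"] for m in doc["motion"]], dtype=np.float64),
                coeff_y=np.array([m["ay"] for m in doc["motion"]], dtype=np.float64),
            )
        return params, motion
    raise ValueError(f"unknown alignment dialect {dialect!r}")


def write_alignment(params: AlignmentParams, motion: MotionModel | None,
                    path: str | os.PathLike, pixel_size_A: float = 0.0,
                    meta: dict | None = None) -> None:
    """Write the native JSON alignment file (refined output format)."""
    for name, arr in (("tx", params.tx), ("ty", params.ty),
                      ("theta", params.theta_deg), ("rot", params.rot_deg)):
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"refusing to write non-finite {name} values")
    doc = {
        "pixel_size_A": float(pixel_size_A),
        "tilts": [
            {
                "angle_deg": float(params.theta_deg[i]),
                "tx_px": float(params.tx[i]),
                "ty_px": float(params.ty[i]),
                "rot_deg": float(params.rot_deg[i]),
            }
            for i in range(params.n_tilts)
        ],
        "motion": None,
        "meta": dict(meta or {}),
    }
    if motion is not None:
        if not (np.all(np.isfinite(motion.coeff_x)) and np.all(np.isfinite(motion.coeff_y))):
            raise ValueError("refusing to write non-finite motion coefficients")
        doc["motion"] = [
            {"ax": [float(v) for v in motion.coeff_x[i]],
             "ay": [float(v) for v in motion.coeff_y[i]]}
            for i in range(motion.n_tilts)
        ]
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Particle tables
# ---------------------------------------------------------------------------

def read_particles(path: str | os.PathLike) -> ParticleSet:
    """Read x y z rows (whitespace/comma separated) or a JSON list of triples."""
    if not os.path.exists(path):
        raise FileNotFoundError(str(path))
    with open(path) as fh:
        text = fh.read()
    stripped = text.lstrip()
    if stripped.startswith("[") or stripped.startswith("{"):
        doc = json.loads(text)
        coords = np.asarray(doc, dtype=np.float64)
        if coords.size == 0:
            coords = coords.reshape(0, 3)
        return ParticleSet(coords)
    rows = []
    for ln, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        if len(parts) != 3:
            raise ValueError(f"{path}:{ln}: expected 3 columns, got {len(parts)}")
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise ValueError(f"{path}:{ln}: non-numeric token") from exc
    return ParticleSet(np.asarray(rows, dtype=np.float64).reshape(-1, 3))


def write_particles(particles: ParticleSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for x, y, z in particles.coords:
            fh.write(f"{x:.4f} {y:.4f} {z:.4f}\n")
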
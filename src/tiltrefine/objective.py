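"""Slab-contrast loss computed on reconstructed tiles.

The sample in a lamella occupies a central z slab of the tomogram while
the top and bottom are mostly noise, so the contrast of the sample region
can be scored as the slice-wise standard deviation of the central slab.
Per tile the pipeline is: normalize (zero mean, unit outer-slab std),
apply an inverted leaky ReLU that passes negative (protein-density)
contrast at full weight while attenuating positive excursions, square the
voxels to further up-weight high-contrast ones, take the standard
deviation of every X-Y slice along z, and average over the central slab
and over tiles. The refinement engine minimizes the negated value; users
see the positive "contrast score".

The ordering (normalize -> inverted leaky ReLU -> square -> slice std)
and the closed-form gradient of the whole chain with respect to the raw
tile voxels live here; :func:`loss_and_volume_grad` is what the engine
backpropagates through the reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import ParticleSet
from .recon import TomogramTile, normalize_tile

__all__ = [
    "ContrastConfig",
    "SliceProfile",
    "inverted_leaky_relu",
    "slice_std_profile",
    "central_slab_range",
    "contrast_loss",
    "contrast_score",
    "loss_and_volume_grad",
]


@dataclass
class ContrastConfig:
    """Tunable pieces of the contrast objective.

    ``central_slab_fraction`` defaults to the middle 40% of z;
    ``outer_slab_fraction`` (per side) sets the normalization slabs,
    leaving a 10% guard band between slab and sample on each side;
    ``leaky_slope_positive`` is the attenuation of positive contrast.
    """

    central_slab_fraction: float = 0.4
    outer_slab_fraction: float = 0.2
    leaky_slope_positive: float = 0.2
    square_voxels: bool = True
    particle_z_pad: int = 2

    def __post_init__(self) -> None:
        if not 0.0 < self.central_slab_fraction <= 1.0:
            raise ValueError("central_slab_fraction must lie in (0, 1]")
        if not 0.0 < self.outer_slab_fraction <= 0.5:
            raise ValueError("outer_slab_fraction must lie in (0, 0.5]")
        if self.central_slab_fraction + 2 * self.outer_slab_fraction > 1.0 + 1e-9:
            raise ValueError("central + 2*outer slab fractions exceed 1")
        if not 0.0 < self.leaky_slope_positive <= 1.0:
            raise ValueError("leaky_slope_positive must lie in (0, 1]")


@dataclass
class SliceProfile:
    """Per-z-slice standard deviations of one processed tile."""

    std_per_z: np.ndarray

    def __post_init__(self) -> None:
        self.std_per_z = np.asarray(self.std_per_z, dtype=np.float64)
        if np.any(self.std_per_z < 0):
            raise ValueError("negative slice standard deviation")


def inverted_leaky_relu(x, slope_positive: float = 0.2):
    """Identity for x <= 0, ``slope_positive * x`` for x > 0.

    The inversion (relative to the usual leaky ReLU) keeps the negative
    branch at full weight because protein density is dark (negative
    contrast) in tomograms.
    """
    x = np.asarray(x, dtype=np.float64)
    return np.where(x <= 0.0, x, slope_positive * x)


def _processed(tile: TomogramTile, cfg: ContrastConfig) -> np.ndarray:
    if not tile.normalized:
        raise ValueError("tile must be normalized before computing slice stds")
    a = inverted_leaky_relu(tile.volume, cfg.leaky_slope_positive)
    return a * a if cfg.square_voxels else a


def slice_std_profile(tile: TomogramTile, cfg: ContrastConfig | None = None,
                      ) -> SliceProfile:
    """Standard deviation of each X-Y slice along z, after the inverted
    leaky ReLU and (optionally) voxel squaring."""
    cfg = cfg or ContrastConfig()
    b = _processed(tile, cfg)
    return SliceProfile(b.std(axis=(1, 2)))


def central_slab_range(tile_size: int, cfg: ContrastConfig | None = None,
                       particles: ParticleSet | None = None,
                       ) -> tuple[int, int]:
    """Inclusive z-slice range the loss averages over.

    Default: a symmetric central window of ``round(central_slab_fraction *
    tile_size)`` slices. When particles are given, the range of z slices
    containing particles (plus a 2-voxel pad) is used instead, so bright
    artifacts above and below the sample cannot dominate the loss.
    """
    cfg = cfg or ContrastConfig()
    if tile_size % 2:
        raise ValueError("tile_size must be even")
    if particles is not None and len(particles) > 0:
        zs = particles.coords[:, 2] + tile_size // 2
        z0 = int(np.floor(zs.min())) - cfg.particle_z_pad
        z1 = int(np.ceil(zs.max())) + cfg.particle_z_pad
        z0, z1 = max(0, z0), min(tile_size - 1, z1)
        if z1 < z0:
            raise ValueError("particle z range empty after clipping")
        return z0, z1
    n = int(round(cfg.central_slab_fraction * tile_size))
    z0 = tile_size // 2 - n // 2
    return z0, z0 + n - 1


def contrast_loss(tiles: list[TomogramTile], cfg: ContrastConfig | None = None,
                  particles: ParticleSet | None = None) -> float:
    """Negative mean central-slab slice std across tiles (minimize to
    maximize contrast)."""
    cfg = cfg or ContrastConfig()
    if not tiles:
        raise ValueError("empty tile list")
    N = tiles[0].volume.shape[0]
    z0, z1 = central_slab_range(N, cfg, particles)
    total = 0.0
    for tile in tiles:
        prof = slice_std_profile(tile, cfg).std_per_z
        total += prof[z0:z1 + 1].mean()
    return -total / len(tiles)


def contrast_score(tiles: list[TomogramTile], cfg: ContrastConfig | None = None,
                   particles: ParticleSet | None = None) -> float:
    """Positive contrast score reported to users (= minus the loss)."""
    return -contrast_loss(tiles, cfg, particles)


def loss_and_volume_grad(volumes: list[np.ndarray], cfg: ContrastConfig,
                         zrange: tuple[int, int],
                         ) -> tuple[float, list[np.ndarray]]:
    """Loss and its gradient w.r.t. each raw (unnormalized) tile volume.

    Forward matches ``contrast_loss`` applied to ``normalize_tile`` of each
    volume; the backward pass carries the chain through slice std, voxel
    squaring, the leaky ReLU, and the mean/outer-std normalization
    (including the dependence of the normalizing statistics on every
    voxel).
    """
    z0, z1 = zrange
    T = len(volumes)
    n_central = z1 - z0 + 1
    loss = 0.0
    grads = []
    for v in volumes:
        N = v.shape[0]
        M = N * N
        n_out = max(1, int(round(cfg.outer_slab_fraction * N)))
        outer_idx = np.r_[0:n_out, N - n_out:N]
        mu = v.mean()
        outer = v[outer_idx]
        mu_o = outer.mean()
        s = np.sqrt(np.mean((outer - mu_o) ** 2))
        if s <= 0.0 or not np.isfinite(s):
            raise ValueError("outer-slab standard deviation is zero")
        vn = (v - mu) / s
        pos = vn > 0.0
        a = np.where(pos, cfg.leaky_slope_positive * vn, vn)
        b = a * a if cfg.square_voxels else a
        bc = b[z0:z1 + 1]
        mean_b = bc.mean(axis=(1, 2), keepdims=True)
        var_b = ((bc - mean_b) ** 2).mean(axis=(1, 2))
        sigma = np.sqrt(var_b)
        loss += -sigma.mean() / T

        # reverse pass
        g_sigma = -1.0 / (T * n_central)
        gb = np.zeros_like(v)
        safe = sigma > 0.0
        coef = np.where(safe, g_sigma / (M * np.maximum(sigma, 1e-300)), 0.0)
        gb[z0:z1 + 1] = coef[:, None, None] * (bc - mean_b)
        ga = gb * 2.0 * a if cfg.square_voxels else gb
        gvn = np.where(pos, cfg.leaky_slope_positive, 1.0) * ga
        G = gvn
        Gbar = G.mean()
        A = float((G * (v - mu)).sum())
        gv = (G - Gbar) / s
        ds = np.zeros_like(v)
        ds[outer_idx] = (v[outer_idx] - mu_o) / (outer.size * s)
        gv -= (A / (s * s)) * ds
        grads.append(gv)
    return loss, grads
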
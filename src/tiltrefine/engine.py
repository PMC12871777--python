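"""Iterative gradient-based refinement of tilt-series alignment.

Starting from a classical (landmark/patch-tracking) alignment, each
iteration reconstructs all tiles through :class:`~tiltrefine.recon.
TiledProjector`, evaluates the slab-contrast loss, backpropagates the
analytic adjoint to per-tilt translation gradients and takes one Adam
step. A dropout-style stabilizer transiently resets a random subset of
the parameters to their original values for each evaluation — a stronger
fraction during an initial capture stage, the baseline 5% while
polishing — and between stages tilts that diverged far from the
consensus gauge trend are deterministically re-anchored onto it. When
local motion is refined, a second phase optimizes the first-order drift
coefficients with the translations frozen at the phase-one optimum (the
constant drift terms stay at zero; global translation lives in tx/ty).

Randomness comes from a counter-based Philox generator keyed by
``(seed, phase, iteration)``, so dropout draws are reproducible
independent of evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import AlignmentParams
from .io_formats import ParticleSet, TiltSeries
from .motion import MotionModel
from .objective import ContrastConfig, central_slab_range, loss_and_volume_grad
from .recon import TiledProjector, TomogramTile, make_tile_grid, normalize_tile

__all__ = [
    "RefinementConfig",
    "LossTrace",
    "ContrastReport",
    "RefinementError",
    "dropout_reset",
    "refine",
    "contrast_report",
]


class RefinementError(RuntimeError):
    """Raised when the optimization diverges (non-finite loss)."""


@dataclass
class RefinementConfig:
    """Optimizer and reconstruction settings for one refinement run."""

    n_iterations: int = 300
    learning_rate: float = 0.3  # pixels per step
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    dropout_fraction: float = 0.05
    capture_dropout_fraction: float = 0.25  # used during the capture stage
    capture_stage_fraction: float = 2.0 / 3.0  # first part of the iterations
    dropout_mode: str = "transient"  # "transient" | "persistent"
    dropout_per_tilt: bool = False
    fix_origin: bool = False  # optionally freeze the tomogram-origin modes
    reanchor_outliers: bool = True  # reset runaway tilts onto the gauge trend
    seed: int = 0
    refine_motion: bool = False
    motion_iterations: int | None = None  # defaults to n_iterations
    tile_size: int = 64
    overlap_fraction: float = 0.25
    w_floor: float = 1e-3
    margin: int = 8
    contrast: ContrastConfig = field(default_factory=ContrastConfig)

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not 0.0 <= self.dropout_fraction < 1.0:
            raise ValueError("dropout_fraction must lie in [0, 1)")
        if not 0.0 <= self.capture_dropout_fraction < 1.0:
            raise ValueError("capture_dropout_fraction must lie in [0, 1)")
        if not 0.0 <= self.capture_stage_fraction <= 1.0:
            raise ValueError("capture_stage_fraction must lie in [0, 1]")
        if self.dropout_mode not in ("transient", "persistent"):
            raise ValueError(f"unknown dropout_mode {self.dropout_mode!r}")

    def dropout_schedule(self, n_iter: int) -> np.ndarray:
        """Per-iteration dropout fractions for the translation phase: the
        stronger capture fraction first (escapes per-tilt local minima),
        then the baseline fraction to polish. Disabled entirely when
        ``dropout_fraction`` is zero."""
        frac = np.full(n_iter, self.dropout_fraction)
        if self.dropout_fraction > 0.0:
            n_capture = int(round(self.capture_stage_fraction * n_iter))
            frac[:n_capture] = self.capture_dropout_fraction
        return frac


@dataclass
class LossTrace:
    """Per-iteration optimization record for one refinement phase."""

    losses: np.ndarray  # loss of the running parameters, per iteration
    dropout_losses: np.ndarray  # loss of the dropout-perturbed evaluation
    reset_indices: list  # per iteration: indices reset to original
    best_index: int
    final_params: AlignmentParams
    phase: str = "translation"
    motion_trace: "LossTrace | None" = None

    def __len__(self) -> int:
        return len(self.losses)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("iteration,loss,n_reset\n")
            for i, (l, idx) in enumerate(zip(self.losses, self.reset_indices)):
                fh.write(f"{i},{l:.8g},{len(idx)}\n")


@dataclass
class ContrastReport:
    """Before/after slice-std profiles and central-slab contrast scores."""

    profile_before: np.ndarray
    profile_after: np.ndarray
    score_before: float
    score_after: float
    zrange: tuple[int, int]

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("z_index,std_before,std_after\n")
            for z, (b, a) in enumerate(zip(self.profile_before, self.profile_after)):
                fh.write(f"{z},{b:.8g},{a:.8g}\n")


def _rng(seed: int, phase: int, iteration: int) -> np.random.Generator:
    key = [(seed & 0xFFFFFFFF) | (phase << 32), iteration]
    return np.random.Generator(np.random.Philox(key=key))


def _dropout_vector(current: np.ndarray, original: np.ndarray, fraction: float,
                    rng: np.random.Generator, per_tilt: bool = False,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Reset exactly round(fraction * N) scalars (or tilts) to original."""
    if current.shape != original.shape:
        raise ValueError("current/original parameter structure mismatch")
    out = current.copy()
    if per_tilt:
        n = current.shape[0]
        k = int(round(fraction * n))
        rows = np.sort(rng.choice(n, size=k, replace=False)) if k else np.empty(0, int)
        out[rows] = original[rows]
        idx = np.concatenate([rows * current.shape[1] + j
                              for j in range(current.shape[1])]) if k else rows
        return out, np.sort(idx.astype(int))
    flat = out.reshape(-1)
    n = flat.size
    k = int(round(fraction * n))
    idx = np.sort(rng.choice(n, size=k, replace=False)) if k else np.empty(0, int)
    flat[idx] = original.reshape(-1)[idx]
    return out, idx


def dropout_reset(current: AlignmentParams, original: AlignmentParams,
                  fraction: float, rng: np.random.Generator,
                  per_tilt: bool = False) -> tuple[AlignmentParams, np.ndarray]:
    """Reset a random ``round(fraction * N)`` of the translation scalars to
    their original values (N = 2 * n_tilts). Deterministic given the
    generator state. Returns the new parameters and the reset indices."""
    if current.n_tilts != original.n_tilts:
        raise ValueError("current/original parameter structure mismatch")
    cur = np.stack([current.tx, current.ty], axis=1)
    orig = np.stack([original.tx, original.ty], axis=1)
    vec, idx = _dropout_vector(cur, orig, fraction, rng, per_tilt)
    out = current.copy()
    out.tx, out.ty = vec[:, 0].copy(), vec[:, 1].copy()
    return out, idx


def origin_gauge_basis(theta_deg: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the tomogram-origin gauge in translation space.

    A global displacement (dx, dy, dz) of the reconstruction origin moves
    every projection by (dx cos t - dz sin t, dy): three modes of the
    (n_tilts, 2) translation vector that carry no alignment information
    (the contrast loss is nearly flat along them, and what little gradient
    they do carry comes from slab-window edge effects). Freezing them pins
    the tomogram origin to the initial alignment's origin.
    """
    th = np.deg2rad(theta_deg)
    n = len(th)
    modes = np.zeros((3, n, 2))
    modes[0, :, 0] = np.cos(th)  # origin shift along x
    modes[1, :, 0] = -np.sin(th)  # origin shift along z
    modes[2, :, 1] = 1.0  # origin shift along y
    flat = modes.reshape(3, -1)
    q, _ = np.linalg.qr(flat.T)
    return q.T.reshape(3, n, 2)


def _remove_gauge_component(vec: np.ndarray, basis: np.ndarray) -> np.ndarray:
    out = vec.copy()
    for b in basis:
        out -= (out * b).sum() * b
    return out


def _gauge_trend(residual: np.ndarray, theta_deg: np.ndarray,
                 mask: np.ndarray) -> np.ndarray:
    """Fit the origin-gauge family (a cos t + b sin t in x, constant in y)
    to a translation residual, using only the tilts in ``mask``."""
    th = np.deg2rad(theta_deg)
    A = np.stack([np.cos(th), np.sin(th)], axis=1)
    coef, *_ = np.linalg.lstsq(A[mask], residual[mask, 0], rcond=None)
    fit = np.zeros_like(residual)
    fit[:, 0] = A @ coef
    fit[:, 1] = residual[mask, 1].mean()
    return fit


def reanchor_outlier_tilts(trans: np.ndarray, trans_init: np.ndarray,
                           theta_deg: np.ndarray,
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Reset catastrophically diverged tilts onto the consensus trend.

    Individual tilt images can latch onto a wrong feature several pixels
    away (a local minimum of the contrast loss) while the remaining tilts
    converge coherently, possibly including a smooth origin-gauge drift.
    The displacement from the initial alignment is robustly fit to the
    gauge family; tilts whose residual from the fit is far outside the
    bulk distribution (median + 4 scaled MADs, at least 2 px) are reset to
    the fitted trend, which puts them back inside the capture range of the
    loss for the following polish iterations. Deterministic.

    Returns the adjusted translations and the boolean outlier mask.
    """
    r = trans - trans_init
    n = len(r)
    mask = np.ones(n, dtype=bool)
    fit = _gauge_trend(r, theta_deg, mask)
    for _ in range(2):  # trim-and-refit so outliers do not skew the trend
        norms = np.linalg.norm(r - fit, axis=1)
        med = np.median(norms)
        mad = 1.4826 * np.median(np.abs(norms - med))
        thr = max(med + 4.0 * mad, 2.0)
        new_mask = norms <= thr
        if new_mask.sum() < 4 or np.array_equal(new_mask, mask):
            mask = new_mask if new_mask.sum() >= 4 else mask
            break
        mask = new_mask
        fit = _gauge_trend(r, theta_deg, mask)
    norms = np.linalg.norm(r - fit, axis=1)
    med = np.median(norms[mask]) if mask.any() else 0.0
    mad = 1.4826 * np.median(np.abs(norms[mask] - med)) if mask.any() else 0.0
    thr = max(med + 4.0 * mad, 2.0)
    outliers = norms > thr
    out = trans.copy()
    out[outliers] = trans_init[outliers] + fit[outliers]
    return out, outliers


class _Adam:
    def __init__(self, shape, lr, beta1, beta2, eps):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = np.zeros(shape)
        self.v = np.zeros(shape)
        self.t = 0

    def step(self, x: np.ndarray, grad: np.ndarray) -> np.ndarray:
        self.t += 1
        self.m = self.b1 * self.m + (1.0 - self.b1) * grad
        self.v = self.b2 * self.v + (1.0 - self.b2) * grad * grad
        mhat = self.m / (1.0 - self.b1 ** self.t)
        vhat = self.v / (1.0 - self.b2 ** self.t)
        return x - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _loss_only(projector: TiledProjector, deltas, cfg: ContrastConfig,
               zrange) -> float:
    vols = projector.forward(deltas)
    loss, _ = loss_and_volume_grad(vols, cfg, zrange)
    return loss


def _loss_and_ddeltas(projector: TiledProjector, deltas, cfg: ContrastConfig,
                      zrange) -> tuple[float, np.ndarray]:
    vols = projector.forward(deltas)
    loss, gv = loss_and_volume_grad(vols, cfg, zrange)
    return loss, projector.backward(deltas, gv)


def _optimize(projector, cfg: RefinementConfig, zrange, n_iter: int, phase: int,
              x0: np.ndarray, orig: np.ndarray, per_tilt: bool,
              deltas_of, grad_of, dropout_schedule=None, it_offset: int = 0,
              ) -> tuple[np.ndarray, LossTrace]:
    """Shared Adam/dropout loop over one flattened parameter block.

    ``deltas_of(x)`` maps the parameter block to per-(tilt, tile) shifts
    and ``grad_of(d_deltas)`` chains shift gradients back to the block.
    """
    x = x0.copy()
    adam = _Adam(x.shape, cfg.learning_rate, cfg.beta1, cfg.beta2, cfg.eps)
    losses = np.empty(n_iter)
    drop_losses = np.empty(n_iter)
    resets: list[np.ndarray] = []
    best_loss, best_x, best_it = np.inf, x.copy(), 0
    ccfg = cfg.contrast
    if dropout_schedule is None:
        dropout_schedule = np.full(n_iter, cfg.dropout_fraction)
    for it in range(n_iter):
        rng = _rng(cfg.seed, phase, it_offset + it)
        frac = float(dropout_schedule[it])
        if frac > 0.0 and cfg.dropout_mode == "transient":
            x_eval, idx = _dropout_vector(x, orig, frac, rng, per_tilt)
        else:
            x_eval, idx = x, np.empty(0, int)
        loss_eval, dd = _loss_and_ddeltas(projector, deltas_of(x_eval), ccfg, zrange)
        if np.array_equal(x_eval, x):
            loss_clean = loss_eval
        else:
            loss_clean = _loss_only(projector, deltas_of(x), ccfg, zrange)
        if not (np.isfinite(loss_eval) and np.isfinite(loss_clean)):
            raise RefinementError(
                f"non-finite loss at iteration {it} (phase {phase}); "
                "check input scaling / learning rate")
        losses[it] = loss_clean
        drop_losses[it] = loss_eval
        if loss_clean < best_loss:
            best_loss, best_x, best_it = loss_clean, x.copy(), it
        x = adam.step(x, grad_of(dd))
        if frac > 0.0 and cfg.dropout_mode == "persistent":
            x, idx = _dropout_vector(x, orig, frac, rng, per_tilt)
        resets.append(idx)
    trace = LossTrace(losses, drop_losses, resets, best_it, None)
    return best_x, x, trace


def refine(ts: TiltSeries, init: AlignmentParams, cfg: RefinementConfig,
           particles: ParticleSet | None = None,
           ) -> tuple[AlignmentParams, MotionModel | None, LossTrace]:
    """Refine per-tilt translations (and optionally local motion) by
    maximizing central-slab contrast.

    The tilt series must already be downsampled to the working resolution.
    Returns the parameters achieving the minimum recorded loss, the motion
    model (None unless ``cfg.refine_motion``) and the optimization trace.
    """
    if ts.n_tilts != init.n_tilts:
        raise ValueError("tilt series / alignment length mismatch")
    if init.refine_rotation:
        raise NotImplementedError(
            "rotation refinement is not implemented; only translations and "
            "first-order local motion are optimized")
    n, ny, nx = ts.images.shape
    grid = make_tile_grid((nx, ny), cfg.tile_size, cfg.overlap_fraction)
    if grid.n_tiles == 0:
        raise ValueError("empty tile grid")
    zrange = central_slab_range(cfg.tile_size, cfg.contrast, particles)
    projector = TiledProjector(ts, init, grid, w_floor=cfg.w_floor,
                               margin=cfg.margin)

    x0 = np.stack([init.tx, init.ty], axis=1)
    basis = origin_gauge_basis(init.theta_deg) if cfg.fix_origin else None

    def grad_trans(dd: np.ndarray) -> np.ndarray:
        g = projector.grad_trans(dd)
        return _remove_gauge_component(g, basis) if basis is not None else g

    # the translation phase runs in segments: a capture stage with strong
    # dropout, then polish stages at the baseline dropout; between segments
    # catastrophically diverged tilts are re-anchored onto the gauge trend
    schedule = cfg.dropout_schedule(cfg.n_iterations)
    if cfg.dropout_fraction > 0.0:
        n_cap = int(round(cfg.capture_stage_fraction * cfg.n_iterations))
        n_rest = cfg.n_iterations - n_cap
        bounds = [n_cap, n_cap + n_rest // 2, cfg.n_iterations]
    else:  # nothing stochastic to escape: one transparent segment
        bounds = [cfg.n_iterations]
    segments, prev = [], 0
    for b in bounds:
        if b > prev:
            segments.append((prev, b))
            prev = b

    x_seg = x0
    all_losses, all_drop, all_resets = [], [], []
    best_x, best_loss, best_idx = x0.copy(), np.inf, 0
    for si, (i0, i1) in enumerate(segments):
        seg_best_x, seg_final_x, seg_trace = _optimize(
            projector, cfg, zrange, i1 - i0, phase=0,
            x0=x_seg, orig=x0.copy(), per_tilt=cfg.dropout_per_tilt,
            deltas_of=lambda x: projector.deltas(x),
            grad_of=grad_trans,
            dropout_schedule=schedule[i0:i1], it_offset=i0,
        )
        all_losses.append(seg_trace.losses)
        all_drop.append(seg_trace.dropout_losses)
        all_resets.extend(seg_trace.reset_indices)
        seg_best = seg_trace.losses[seg_trace.best_index]
        # with re-anchoring active, select from the final (post-anchor)
        # segment only: a tilt trapped on a wrong feature can score a
        # *deeper* loss than the honest optimum, and a global argmin would
        # resurrect the trapped iterate the re-anchor just repaired
        is_last = si == len(segments) - 1
        if (seg_best < best_loss) if not cfg.reanchor_outliers else is_last:
            best_loss, best_x = seg_best, seg_best_x
            best_idx = i0 + seg_trace.best_index
        x_seg = seg_best_x if cfg.reanchor_outliers else seg_final_x
        if cfg.reanchor_outliers and si < len(segments) - 1:
            x_seg, _ = reanchor_outlier_tilts(x_seg, x0, init.theta_deg)
    losses = np.concatenate(all_losses)
    trace = LossTrace(losses, np.concatenate(all_drop), all_resets,
                      best_idx, None)
    params_out = AlignmentParams(best_x[:, 0].copy(), best_x[:, 1].copy(),
                                 init.theta_deg.copy(), init.rot_deg.copy())
    trace.final_params = params_out
    trace.phase = "translation"

    motion_out: MotionModel | None = None
    if cfg.refine_motion:
        trans_fixed = best_x

        def motion_of(y: np.ndarray) -> MotionModel:
            # y columns: (cx_x, cy_x, cx_y, cy_y); constant terms frozen at 0
            cx = np.concatenate([np.zeros((n, 1)), y[:, 0:2]], axis=1)
            cy = np.concatenate([np.zeros((n, 1)), y[:, 2:4]], axis=1)
            return MotionModel(cx, cy)

        def grad_motion(dd: np.ndarray) -> np.ndarray:
            gx, gy = projector.grad_motion(dd)
            return np.concatenate([gx[:, 1:3], gy[:, 1:3]], axis=1)

        y0 = np.zeros((n, 4))
        n_iter2 = cfg.motion_iterations or cfg.n_iterations
        best_y, _, mtrace = _optimize(
            projector, cfg, zrange, n_iter2, phase=1,
            x0=y0, orig=y0.copy(), per_tilt=cfg.dropout_per_tilt,
            deltas_of=lambda y: projector.deltas(trans_fixed, motion_of(y)),
            grad_of=grad_motion,
        )
        motion_out = motion_of(best_y)
        mtrace.final_params = params_out
        mtrace.phase = "motion"
        trace.motion_trace = mtrace
    return params_out, motion_out, trace


def _mean_profile(projector: TiledProjector, params: AlignmentParams,
                  motion: MotionModel | None, cfg: ContrastConfig) -> np.ndarray:
    trans = np.stack([params.tx, params.ty], axis=1)
    vols = projector.forward(projector.deltas(trans, motion))
    from .objective import slice_std_profile

    profs = []
    for v, c in zip(vols, projector.grid.centers):
        tile = normalize_tile(TomogramTile(v, tuple(c)), cfg.outer_slab_fraction)
        profs.append(slice_std_profile(tile, cfg).std_per_z)
    return np.mean(profs, axis=0)


def contrast_report(ts: TiltSeries, params_before: AlignmentParams,
                    params_after: AlignmentParams, cfg: RefinementConfig,
                    motion_before: MotionModel | None = None,
                    motion_after: MotionModel | None = None,
                    particles: ParticleSet | None = None) -> ContrastReport:
    """Slice-std profiles and contrast scores under two parameter sets.

    Reconstructs the full footprint under both alignments with the same
    tile grid, averages slice-std profiles over tiles and scores the
    central slab; the paired profiles are the numerical analog of a
    before/after contrast plot along z.
    """
    n, ny, nx = ts.images.shape
    grid = make_tile_grid((nx, ny), cfg.tile_size, cfg.overlap_fraction)
    zrange = central_slab_range(cfg.tile_size, cfg.contrast, particles)
    prof_b = _mean_profile(TiledProjector(ts, params_before, grid, cfg.w_floor,
                                          cfg.margin),
                           params_before, motion_before, cfg.contrast)
    prof_a = _mean_profile(TiledProjector(ts, params_after, grid, cfg.w_floor,
                                          cfg.margin),
                           params_after, motion_after, cfg.contrast)
    z0, z1 = zrange
    return ContrastReport(prof_b, prof_a,
                          float(prof_b[z0:z1 + 1].mean()),
                          float(prof_a[z0:z1 + 1].mean()), zrange)
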
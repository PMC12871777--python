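"""Refinement engine: dropout, Adam stepping, determinism, convergence."""

import numpy as np
import pytest

from tiltrefine.engine import (RefinementConfig, _loss_and_ddeltas,
                               _loss_only, _rng, dropout_reset, refine)
from tiltrefine.geometry import AlignmentParams
from tiltrefine.objective import ContrastConfig, central_slab_range
from tiltrefine.recon import TiledProjector, make_tile_grid


def small_cfg(**kw):
    base = dict(n_iterations=5, learning_rate=0.3, tile_size=32,
                overlap_fraction=0.0, seed=0)
    base.update(kw)
    return RefinementConfig(**base)


class TestDropoutReset:
    def _params(self, n=41, seed=0):
        rng = np.random.default_rng(seed)
        th = np.linspace(-60, 60, n)
        cur = AlignmentParams(rng.normal(size=n), rng.normal(size=n), th,
                              np.zeros(n))
        orig = AlignmentParams.identity(th)
        return cur, orig

    def test_five_percent_of_82_scalars_resets_four(self):
        cur, orig = self._params(41)
        out, idx = dropout_reset(cur, orig, 0.05, _rng(0, 0, 0))
        assert len(idx) == 4  # round(0.05 * 82)
        flat_out = np.stack([out.tx, out.ty], axis=1).reshape(-1)
        flat_cur = np.stack([cur.tx, cur.ty], axis=1).reshape(-1)
        changed = np.nonzero(flat_out != flat_cur)[0]
        assert set(changed) <= set(idx)
        assert np.all(flat_out[idx] == 0.0)

    def test_fraction_zero_unchanged(self):
        cur, orig = self._params(10)
        out, idx = dropout_reset(cur, orig, 0.0, _rng(0, 0, 1))
        assert len(idx) == 0
        assert np.array_equal(out.tx, cur.tx)

    def test_fixed_point_when_current_equals_original(self):
        _, orig = self._params(10)
        out, _ = dropout_reset(orig.copy(), orig, 0.05, _rng(0, 0, 2))
        assert np.array_equal(out.tx, orig.tx)
        assert np.array_equal(out.ty, orig.ty)

    def test_deterministic_given_rng_key(self):
        cur, orig = self._params(41)
        _, i1 = dropout_reset(cur, orig, 0.1, _rng(7, 0, 3))
        _, i2 = dropout_reset(cur, orig, 0.1, _rng(7, 0, 3))
        assert np.array_equal(i1, i2)

    def test_structure_mismatch(self):
        cur, _ = self._params(10)
        _, orig = self._params(12)
        with pytest.raises(ValueError, match="mismatch"):
            dropout_reset(cur, orig, 0.05, _rng(0, 0, 4))

    def test_per_tilt_mode_resets_whole_tilts(self):
        cur, orig = self._params(40)
        out, idx = dropout_reset(cur, orig, 0.1, _rng(1, 0, 5), per_tilt=True)
        # 4 tilts reset -> 8 scalar indices
        assert len(idx) == 8
        reset_rows = np.nonzero(out.tx != cur.tx)[0]
        assert np.all(out.ty[reset_rows] == 0.0)


class TestRefine:
    def test_single_adam_step_matches_hand_oracle(self, grad_fixture):
        """n_iterations=1, dropout 0: the output equals init plus exactly
        one hand-computed Adam step on the analytic gradient."""
        ts = grad_fixture["ts"]
        init = grad_fixture["truth"].copy()
        cfg = small_cfg(n_iterations=1, dropout_fraction=0.0, learning_rate=0.1)
        params, motion, trace = refine(ts, init, cfg)
        assert motion is None

        # independent oracle: same gradient, textbook Adam arithmetic
        grid = make_tile_grid((64, 64), cfg.tile_size, cfg.overlap_fraction)
        proj = TiledProjector(ts, init, grid, cfg.w_floor, cfg.margin)
        zr = central_slab_range(cfg.tile_size, cfg.contrast)
        x0 = np.stack([init.tx, init.ty], axis=1)
        _, dd = _loss_and_ddeltas(proj, proj.deltas(x0), cfg.contrast, zr)
        g = proj.grad_trans(dd)
        m = (1 - cfg.beta1) * g
        v = (1 - cfg.beta2) * g * g
        mhat = m / (1 - cfg.beta1)
        vhat = v / (1 - cfg.beta2)
        expected = x0 - cfg.learning_rate * mhat / (np.sqrt(vhat) + cfg.eps)
        # with one iteration the best (pre-step) iterate is init itself, so
        # inspect the final snapshot of the trace instead
        assert np.allclose(trace.losses[0], trace.losses.min())
        got = np.stack([params.tx, params.ty], axis=1)
        # returned params are the best-loss iterate (= init here)
        assert np.allclose(got, x0)
        # and one hand Adam step from init reproduces the engine's update
        x1 = np.stack([init.tx, init.ty], axis=1)
        cfg2 = small_cfg(n_iterations=2, dropout_fraction=0.0, learning_rate=0.1)
        params2, _, trace2 = refine(ts, init, cfg2)
        # the second iterate the engine evaluated must be the oracle step
        l1 = _loss_only(proj, proj.deltas(expected), cfg.contrast, zr)
        assert trace2.losses[1] == pytest.approx(l1, rel=1e-10)

    def test_determinism_bitwise(self, small_noisy_case):
        ts = small_noisy_case["ts"]
        init = AlignmentParams.identity(small_noisy_case["truth"].theta_deg)
        cfg = small_cfg(n_iterations=4, dropout_fraction=0.2, seed=11)
        p1, _, t1 = refine(ts, init, cfg)
        p2, _, t2 = refine(ts, init, cfg)
        for a, b in zip(t1.reset_indices, t2.reset_indices):
            assert np.array_equal(a, b)
        assert np.max(np.abs(p1.tx - p2.tx)) <= 1e-6
        assert np.max(np.abs(p1.ty - p2.ty)) <= 1e-6
        assert np.array_equal(t1.losses, t2.losses)

    def test_best_loss_selection_reproducible(self, small_noisy_case):
        ts = small_noisy_case["ts"]
        truth = small_noisy_case["truth"]
        init = AlignmentParams.identity(truth.theta_deg)
        cfg = small_cfg(n_iterations=6, dropout_fraction=0.1, seed=2)
        params, _, trace = refine(ts, init, cfg)
        assert len(trace) == 6
        assert trace.losses.min() <= trace.losses[0]
        # re-evaluate returned params: must reproduce the recorded minimum
        grid = make_tile_grid((64, 64), cfg.tile_size, cfg.overlap_fraction)
        proj = TiledProjector(ts, init, grid, cfg.w_floor, cfg.margin)
        zr = central_slab_range(cfg.tile_size, cfg.contrast)
        x = np.stack([params.tx, params.ty], axis=1)
        assert _loss_only(proj, proj.deltas(x), cfg.contrast, zr) == pytest.approx(
            trace.losses[trace.best_index], rel=1e-9)

    def test_dropout_count_exact_every_iteration(self, small_noisy_case):
        ts = small_noisy_case["ts"]
        init = AlignmentParams.identity(small_noisy_case["truth"].theta_deg)
        n_scalars = 2 * init.n_tilts  # 30
        cfg = small_cfg(n_iterations=4, dropout_fraction=0.05,
                        capture_dropout_fraction=0.05, seed=3)
        _, _, trace = refine(ts, init, cfg)
        for idx in trace.reset_indices:
            assert len(idx) == round(0.05 * n_scalars)

    def test_persistent_mode_also_counts_exactly(self, small_noisy_case):
        ts = small_noisy_case["ts"]
        init = AlignmentParams.identity(small_noisy_case["truth"].theta_deg)
        cfg = small_cfg(n_iterations=3, dropout_fraction=0.2,
                        capture_dropout_fraction=0.2, seed=4,
                        dropout_mode="persistent")
        _, _, trace = refine(ts, init, cfg)
        for idx in trace.reset_indices:
            assert len(idx) == round(0.2 * 2 * init.n_tilts)

    def test_loss_decreases_on_misaligned_fixture(self, small_noisy_case):
        ts = small_noisy_case["ts"]
        init = AlignmentParams.identity(small_noisy_case["truth"].theta_deg)
        cfg = small_cfg(n_iterations=40, dropout_fraction=0.05, seed=5)
        _, _, trace = refine(ts, init, cfg)
        assert trace.losses[trace.best_index] < trace.losses[0]

    def test_mismatched_lengths_error(self, small_noisy_case):
        ts = small_noisy_case["ts"]
        init = AlignmentParams.identity([-30.0, 0.0, 30.0])
        with pytest.raises(ValueError, match="mismatch"):
            refine(ts, init, small_cfg())

    def test_rotation_refinement_not_implemented(self, small_noisy_case):
        ts = small_noisy_case["ts"]
        init = AlignmentParams.identity(small_noisy_case["truth"].theta_deg)
        init.refine_rotation = True
        with pytest.raises(NotImplementedError):
            refine(ts, init, small_cfg())

    def test_motion_disabled_matches_translation_only_path(self, small_noisy_case):
        """refine_motion only appends a second phase; the translation result
        is bit-identical to the translation-only run."""
        ts = small_noisy_case["ts"]
        init = AlignmentParams.identity(small_noisy_case["truth"].theta_deg)
        cfg_a = small_cfg(n_iterations=3, seed=6)
        cfg_b = small_cfg(n_iterations=3, seed=6, refine_motion=True,
                          motion_iterations=2)
        pa, ma, _ = refine(ts, init, cfg_a)
        pb, mb, tb = refine(ts, init, cfg_b)
        assert ma is None and mb is not None
        assert np.array_equal(pa.tx, pb.tx) and np.array_equal(pa.ty, pb.ty)
        assert tb.motion_trace is not None and len(tb.motion_trace) == 2
        # constant drift terms stay frozen at zero
        assert np.all(mb.coeff_x[:, 0] == 0) and np.all(mb.coeff_y[:, 0] == 0)


def test_trace_csv_round_trip(tmp_path, small_noisy_case):
    ts = small_noisy_case["ts"]
    init = AlignmentParams.identity(small_noisy_case["truth"].theta_deg)
    _, _, trace = refine(ts, init, small_cfg(n_iterations=3))
    p = tmp_path / "trace.csv"
    trace.to_csv(p)
    lines = p.read_text().strip().splitlines()
    assert lines[0] == "iteration,loss,n_reset"
    assert len(lines) == 4
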